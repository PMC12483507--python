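import numpy as np
import pytest

from hoverscale.synthgen import synth_wing_outline
from hoverscale.trees import simulate_yule_tree, star_tree, vcv_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def yule_tree():
    """Fixed 16-tip pure-birth tree, unit depth."""
    return simulate_yule_tree(16, 1.0, np.random.default_rng(7))


@pytest.fixture
def star8():
    return star_tree([f"t{i}" for i in range(8)], depth=1.0)


@pytest.fixture
def rect_wing():
    """Rectangular wing (uniform chord): S2* = 1/3 in closed form."""
    return synth_wing_outline(R=1.0, c_bar=1.0, beta_p=1.0, beta_q=1.0, n_points=400)


@pytest.fixture
def tri_wing():
    """Triangular wing with chord proportional to r: S2* = 1/2."""
    return synth_wing_outline(R=1.0, c_bar=0.5, beta_p=2.0, beta_q=1.0, n_points=400)


@pytest.fixture
def chol16(yule_tree):
    C = vcv_matrix(yule_tree)
    return list(C.index), np.linalg.cholesky(C.to_numpy())
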