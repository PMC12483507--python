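"""Morphometrics: closed-form outline metrics, invariances, semi-landmark
resampling, Procrustes alignment, and phylogenetic PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hoverscale.errors import GeometryError, InvalidParameterError, LabelMismatchError
from hoverscale.synthgen import synth_wing_outline
from hoverscale.trees import star_tree, vcv_matrix
from hoverscale.wingmorph import (
    GeneralizedProcrustes,
    PhylogeneticPCA,
    WingOutline,
    morphology_from_outline,
    phylo_pca,
    procrustes_align,
    resample_semilandmarks,
)


def _transform(outline: WingOutline, scale=1.0, angle=0.0, shift=(0.0, 0.0)):
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    pts = scale * (outline.points @ R.T) + np.asarray(shift)
    return WingOutline(points=pts, hinge_index=outline.hinge_index)


class TestMorphologyFromOutline:
    def test_unit_rectangle_closed_form(self, rect_wing):
        m = morphology_from_outline(rect_wing, mass=8.0, n_strips=1000)
        assert m.S == pytest.approx(1.0, rel=1e-3)
        assert m.R == pytest.approx(1.0, rel=1e-6)
        assert m.c_bar == pytest.approx(1.0, rel=1e-3)
        assert m.S2 == pytest.approx(1.0 / 3.0, abs=1e-3)
        assert m.S2_star == pytest.approx(1.0 / 3.0, abs=1e-3)
        assert m.R_star == pytest.approx(1.0 / 2.0, rel=1e-3)

    def test_triangle_closed_form(self, tri_wing):
        m = morphology_from_outline(tri_wing, n_strips=1000)
        assert m.S2_star == pytest.approx(0.5, abs=1e-3)

    def test_elliptic_profile_matches_quadrature(self):
        # half-ellipse chord c(r) = c0 sqrt(1 - r^2): S2* known by quadrature
        r = np.linspace(0.0, 1.0, 400)
        c = 0.6 * np.sqrt(np.clip(1.0 - r**2, 0.0, None))
        pts = np.vstack([
            [[0.0, 0.0]],
            np.column_stack([r, 0.5 * c]),
            np.column_stack([r, -0.5 * c])[::-1],
        ])
        o = WingOutline(points=pts, hinge_index=0)
        m = morphology_from_outline(o, n_strips=5000)
        from scipy.integrate import quad
        num = quad(lambda x: np.sqrt(1 - x**2) * x**2, 0, 1)[0]
        den = quad(lambda x: np.sqrt(1 - x**2), 0, 1)[0]
        assert m.S2_star == pytest.approx(num / den, rel=2e-3)

    def test_scale_equivariance(self, tri_wing):
        m1 = morphology_from_outline(tri_wing, n_strips=500)
        m2 = morphology_from_outline(_transform(tri_wing, scale=3.0), n_strips=500)
        assert m2.S == pytest.approx(9.0 * m1.S, rel=1e-6)
        assert m2.S2 == pytest.approx(81.0 * m1.S2, rel=1e-6)
        assert m2.S2_star == pytest.approx(m1.S2_star, rel=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(angle=st.floats(-np.pi, np.pi), dx=st.floats(-5, 5), dy=st.floats(-5, 5))
    def test_rigid_motion_invariance(self, angle, dx, dy):
        base = synth_wing_outline(R=4.0, c_bar=1.5, beta_p=3.0, beta_q=2.0)
        m1 = morphology_from_outline(base, n_strips=300)
        m2 = morphology_from_outline(
            _transform(base, angle=angle, shift=(dx, dy)), n_strips=300)
        assert m2.S == pytest.approx(m1.S, rel=1e-9)
        assert m2.R == pytest.approx(m1.R, rel=1e-9)
        assert m2.S2 == pytest.approx(m1.S2, rel=1e-6)

    def test_s2star_bounded(self):
        for p, q in [(1.0, 1.0), (1.5, 4.0), (6.0, 1.5), (2.0, 2.0)]:
            o = synth_wing_outline(R=5.0, c_bar=2.0, beta_p=p, beta_q=q)
            m = morphology_from_outline(o, n_strips=300)
            assert 0.0 < m.S2_star < 1.0

    def test_strip_integration_error_decreases(self):
        o = synth_wing_outline(R=5.0, c_bar=2.0, beta_p=3.0, beta_q=2.0,
                               n_points=600)
        ref = morphology_from_outline(o, n_strips=20000).S2
        errs = [abs(morphology_from_outline(o, n_strips=n).S2 - ref)
                for n in (100, 1000, 10000)]
        assert errs[0] > errs[1] > errs[2]

    def test_self_intersecting_outline_rejected(self):
        t = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        # figure-eight
        pts = np.column_stack([np.sin(2 * t), np.sin(t)])
        with pytest.raises(GeometryError):
            WingOutline(points=pts, hinge_index=0)

    def test_too_few_points_rejected(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        with pytest.raises(GeometryError):
            WingOutline(points=sq, hinge_index=0)


class TestResampleSemilandmarks:
    @staticmethod
    def _circle(n=3000, r=2.0):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return WingOutline(points=np.column_stack([r * np.cos(t), r * np.sin(t)]),
                           hinge_index=0)

    def test_circle_spacing_uniform(self):
        o = self._circle()
        cfg = resample_semilandmarks(o, n=300)
        ring = np.vstack([cfg.points, cfg.points[:1]])
        d = np.hypot(*np.diff(ring, axis=0).T)
        L = 2 * np.pi * 2.0
        assert np.all(np.abs(d - d.mean()) < 1e-6 * L)
        assert len(cfg.points) == 301

    def test_idempotent_on_equidistant_points(self):
        o = self._circle()
        cfg1 = resample_semilandmarks(o, n=300)
        o2 = WingOutline(points=cfg1.points, hinge_index=0)
        cfg2 = resample_semilandmarks(o2, n=300)
        assert np.allclose(cfg1.points, cfg2.points, atol=1e-6)

    def test_square_corners_recovered(self):
        # analytic arc-length parameterisation of a unit square
        side = np.linspace(0, 1, 200, endpoint=False)
        pts = np.vstack([
            np.column_stack([side, np.zeros_like(side)]),
            np.column_stack([np.ones_like(side), side]),
            np.column_stack([1 - side, np.ones_like(side)]),
            np.column_stack([np.zeros_like(side), 1 - side]),
        ])
        o = WingOutline(points=pts, hinge_index=0)
        cfg = resample_semilandmarks(o, n=300)
        spacing = 4.0 / 301
        for corner in [(1, 0), (1, 1), (0, 1), (0, 0)]:
            dmin = np.min(np.hypot(cfg.points[:, 0] - corner[0],
                                   cfg.points[:, 1] - corner[1]))
            assert dmin <= spacing

    def test_base_landmark_at_hinge(self):
        o = self._circle()
        cfg = resample_semilandmarks(o, n=100)
        assert np.allclose(cfg.points[0], o.points[0], atol=1e-9)


class TestGeneralizedProcrustes:
    def test_removable_transform_aligned_exactly(self, rng):
        shape = rng.normal(size=(40, 2))
        th = np.deg2rad(37.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        other = 3.0 * (shape @ R.T) + np.array([10.0, -4.0])
        aligned, _ = procrustes_align([shape, other])
        assert np.sqrt(np.sum((aligned[0] - aligned[1]) ** 2)) < 1e-8

    def test_alignment_idempotent(self, rng):
        configs = rng.normal(size=(5, 25, 2))
        aligned, mean = procrustes_align(list(configs))
        aligned2, mean2 = procrustes_align(list(aligned))
        assert np.allclose(aligned, aligned2, atol=1e-7)
        assert np.allclose(mean, mean2, atol=1e-7)

    def test_gpa_beats_naive_reference_alignment(self, rng):
        # GPA minimises summed squared distance to the mean shape; aligning
        # everything to an arbitrary first specimen cannot do better
        for _ in range(20):
            configs = rng.normal(size=(6, 15, 2))
            gpa = GeneralizedProcrustes().fit(list(configs))
            aligned = gpa.transform(list(configs))
            ss_gpa = np.sum((aligned - aligned.mean(axis=0)) ** 2)

            from hoverscale.wingmorph import _center_scale, _rotate_to
            ref = _center_scale(configs[0])
            naive = np.stack([_rotate_to(_center_scale(c), ref) for c in configs])
            ss_naive = np.sum((naive - naive.mean(axis=0)) ** 2)
            assert ss_gpa <= ss_naive + 1e-9

    def test_degenerate_configuration_rejected(self):
        flat = np.ones((10, 2))
        with pytest.raises(GeometryError):
            procrustes_align([flat, flat])

    def test_mismatched_landmark_counts_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            procrustes_align([rng.normal(size=(10, 2)), rng.normal(size=(12, 2))])


class TestPhylogeneticPCA:
    def test_star_tree_equals_ordinary_pca_up_to_sign(self, rng):
        labels = [f"t{i}" for i in range(8)]
        X = pd.DataFrame(rng.normal(size=(8, 5)), index=labels)
        scores = PhylogeneticPCA(tree=star_tree(labels)).fit(X).transform(X)
        from sklearn.decomposition import PCA
        ref = PCA(n_components=scores.shape[1]).fit_transform(X.to_numpy())
        for j in range(scores.shape[1]):
            col = scores.to_numpy()[:, j]
            assert (np.allclose(col, ref[:, j], atol=1e-8)
                    or np.allclose(col, -ref[:, j], atol=1e-8))

    def test_single_axis_variation_explains_everything(self, yule_tree):
        labels = [leaf.taxon.label for leaf in yule_tree.leaf_node_iter()]
        t = np.linspace(-1, 1, len(labels))
        X = pd.DataFrame(np.outer(t, [1.0, 2.0, -0.5]), index=labels)
        est = PhylogeneticPCA(tree=yule_tree).fit(X)
        assert est.percent_variance_[0] == pytest.approx(100.0, abs=1e-8)

    def test_percent_variance_sums_to_100(self, yule_tree, rng):
        labels = [leaf.taxon.label for leaf in yule_tree.leaf_node_iter()]
        X = pd.DataFrame(rng.normal(size=(len(labels), 6)), index=labels)
        est = PhylogeneticPCA(tree=yule_tree).fit(X)
        assert est.percent_variance_.sum() == pytest.approx(100.0)

    def test_species_mismatch_rejected(self, yule_tree, rng):
        X = pd.DataFrame(rng.normal(size=(4, 3)),
                         index=["nope1", "nope2", "nope3", "nope4"])
        with pytest.raises(LabelMismatchError):
            PhylogeneticPCA(tree=yule_tree).fit(X)

    def test_recovers_generative_deformation_axis(self, yule_tree, chol16):
        # shapes deform along one axis with BM-correlated magnitudes; PC1
        # scores must track the generative axis position
        labels, L = chol16
        k = 20
        master = np.random.default_rng(99)
        base = master.normal(size=(k, 2))
        direction = master.normal(size=(k, 2))
        direction /= np.sqrt(np.sum(direction**2))
        good = 0
        for rep in range(50):
            r = np.random.default_rng(1000 + rep)
            s = L @ r.standard_normal(len(labels))
            noise = 0.05 * r.normal(size=(len(labels), k, 2))
            shapes = base[None] + s[:, None, None] * direction[None] + noise
            X = pd.DataFrame(shapes.reshape(len(labels), -1), index=labels)
            scores = phylo_pca(X, yule_tree)[0]
            rho = np.corrcoef(scores.to_numpy()[:, 0], s)[0, 1]
            good += abs(rho) > 0.9
        assert good >= 45
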