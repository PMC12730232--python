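"""Mann-Whitney statistics, PCA, discriminant-peak selection and the
turnover model."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu as scipy_mwu

from simslipid.roi import RoiSpectrum
from simslipid.turnover import (
    GroupDesign,
    TurnoverModel,
    compare_conditions,
    mann_whitney_u,
    mann_whitney_u_many,
    pca,
    select_discriminant_peaks,
)


def brute_force_mwu(x, y):
    """Independent oracle: U from pairwise comparisons, p from enumerating
    every split of the pooled sample."""
    x, y = list(x), list(y)
    u_obs = sum(
        1.0 if xi > yj else (0.5 if xi == yj else 0.0) for xi in x for yj in y
    )
    pooled = x + y
    n1 = len(x)
    mu = len(x) * len(y) / 2.0
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(
            1.0 if xi > yj else (0.5 if xi == yj else 0.0)
            for xi in xs for yj in ys
        )
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_complete_separation_small(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 of the 20 rank splits are as extreme

    def test_identical_samples(self):
        u, p = mann_whitney_u([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_large_shift_asymptotic(self, rng):
        x = rng.normal(100, 1, size=8)
        y = rng.normal(0, 1, size=20)
        u, p = mann_whitney_u(x, y, method="asymptotic")
        assert u == 8 * 20  # every treated value exceeds every control value
        assert p < 0.001

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            mann_whitney_u([1], [2, 3])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 3), (6, 6), (4, 8)])
    def test_exact_matches_brute_force_with_ties(self, rng, n1, n2):
        for _ in range(8):
            x = rng.integers(0, 4, size=n1).astype(float)
            y = rng.integers(0, 4, size=n2).astype(float)
            u, p = mann_whitney_u(x, y, method="exact")
            u_ref, p_ref = brute_force_mwu(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)

    def test_asymptotic_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=25)
            x[rng.integers(12)] = y[rng.integers(25)]  # force a tie sometimes
            _, p = mann_whitney_u(x, y, method="asymptotic")
            ref = scipy_mwu(x, y, alternative="two-sided", method="asymptotic")
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_matches_scipy_untied(self, rng):
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            _, p = mann_whitney_u(x, y, method="exact")
            ref = scipy_mwu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue)

    def test_vectorized_matches_scalar(self, rng):
        X = rng.poisson(5, size=(8, 15)).astype(float)
        Y = rng.poisson(6, size=(20, 15)).astype(float)
        U, P = mann_whitney_u_many(X, Y)
        for j in range(15):
            u, p = mann_whitney_u(X[:, j], Y[:, j], method="asymptotic")
            assert U[j] == pytest.approx(u)
            assert P[j] == pytest.approx(p)

    @given(
        st.lists(st.integers(0, 9), min_size=2, max_size=7),
        st.lists(st.integers(0, 9), min_size=2, max_size=7),
    )
    @settings(max_examples=50, deadline=None)
    def test_u_complement_under_group_swap(self, xs, ys):
        u_xy, _ = mann_whitney_u(xs, ys)
        u_yx, _ = mann_whitney_u(ys, xs)
        assert u_xy + u_yx == pytest.approx(len(xs) * len(ys))

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=3, max_size=8),
        st.lists(st.floats(0.01, 100.0), min_size=3, max_size=8),
    )
    @settings(max_examples=40, deadline=None)
    def test_invariance_under_monotone_transform(self, xs, ys):
        u1, p1 = mann_whitney_u(xs, ys)
        u2, p2 = mann_whitney_u(np.log(xs), np.log(ys))
        assert u1 == pytest.approx(u2)
        assert p1 == pytest.approx(p2)


class TestPca:
    def test_two_clusters_on_pc1(self, rng):
        base = np.zeros(30)
        X = np.vstack([base + [5.0 if i < 15 else -5.0] for i in range(8)])
        X[:4] += 5.0
        X[4:] -= 5.0
        res = pca(X)
        assert res.explained_variance_ratio[0] > 0.99

    def test_identical_spectra_zero_components(self):
        X = np.tile(np.arange(10.0), (5, 1))
        res = pca(X)
        assert res.n_components == 0

    def test_reconstruction_and_orthonormal_loadings(self, rng):
        X = rng.normal(size=(6, 40))
        res = pca(X)
        assert np.allclose(res.loadings.T @ res.loadings,
                           np.eye(res.n_components), atol=1e-9)
        assert np.allclose(res.scores @ res.loadings.T, X - res.mean, atol=1e-9)

    def test_matches_sklearn(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        X = rng.normal(size=(10, 25))
        ours = pca(X)
        ref = sklearn_pca(n_components=9).fit(X)
        assert np.allclose(ours.explained_variance[:9],
                           ref.explained_variance_, atol=1e-8)
        for k in range(3):  # sign-indeterminate
            assert abs(np.dot(ours.loadings[:, k], ref.components_[k])) == (
                pytest.approx(1.0, abs=1e-8)
            )

    def test_needs_three_spectra(self, rng):
        with pytest.raises(ValueError):
            pca(rng.normal(size=(2, 5)))

    @pytest.mark.parametrize("scaling", ["uv", "pareto"])
    def test_alternative_scalings_run(self, rng, scaling):
        X = rng.normal(size=(6, 12))
        res = pca(X, scaling=scaling)
        assert res.n_components >= 1


class TestSelection:
    def test_planted_single_bin_difference(self, rng):
        X = rng.normal(0, 0.01, size=(16, 50))
        X[:8, 17] += 10.0  # the only real group difference
        groups = np.r_[np.ones(8, bool), np.zeros(8, bool)]
        res = pca(X)
        idx, comp, t = select_discriminant_peaks(res, groups, top_fraction=0.02)
        assert 17 in idx

    def test_identical_groups_select_nothing(self):
        X = np.tile(np.arange(20.0), (8, 1))
        X += np.arange(8)[:, None] * 0.0
        groups = np.r_[np.ones(4, bool), np.zeros(4, bool)]
        with pytest.warns(UserWarning):
            idx, comp, t = select_discriminant_peaks(pca(X), groups)
        assert idx.size == 0

    def test_planted_shift_bins_in_top_loading_decile(self, sim_config, rng):
        """Bins carrying the isotope shift dominate the loadings of the
        group-separating component."""
        from simslipid.roi import remove_interference, tic_normalize
        from simslipid.simulate import (
            _expected_cell_spectrum,
            simulate_roi_spectra,
        )

        cfg = sim_config
        arm, pol = "13C-stearic", -1
        treated = [
            tic_normalize(remove_interference(s))
            for s in simulate_roi_spectra(cfg, arm, pol, 8, rng)
        ]
        control = [
            tic_normalize(remove_interference(s))
            for s in simulate_roi_spectra(cfg, "control", pol, 20, rng)
        ]
        X = np.vstack([s.normalized for s in treated + control])
        groups = np.r_[np.ones(8, bool), np.zeros(20, bool)]
        res = pca(X)
        idx, comp, t = select_discriminant_peaks(res, groups, top_fraction=0.1)
        _, table = _expected_cell_spectrum(cfg, arm, pol)
        shifted = set(table.loc[table["shifted_bin"] >= 0, "shifted_bin"])
        assert shifted <= set(idx)


def _spectra_from_matrix(mat, axis, polarity, condition):
    out = []
    for i, row in enumerate(mat):
        s = RoiSpectrum(i + 1, row.astype(float), axis, polarity,
                        condition=condition)
        s.normalized = row / row.sum()
        out.append(s)
    return out


class TestTurnoverModel:
    def _design(self, rng, axis, up_bin=None, down_bin=None, n1=6, n2=8):
        base = np.full(axis.n_bins, 0.01)
        base[[30, 60, 90, 120]] = [50, 40, 30, 20]
        treated_mean = base.copy()
        if up_bin is not None:
            treated_mean[up_bin] += 25
        if down_bin is not None:
            treated_mean[down_bin] *= 0.3
        treated = _spectra_from_matrix(
            rng.poisson(treated_mean * 100, size=(n1, axis.n_bins)) + 0.0,
            axis, 1, "treated")
        control = _spectra_from_matrix(
            rng.poisson(base * 100, size=(n2, axis.n_bins)) + 0.0,
            axis, 1, "control")
        return GroupDesign("treated", treated, control, 1)

    def test_direction_calls(self, rng, small_axis):
        design = self._design(rng, small_axis, up_bin=45, down_bin=30)
        res = TurnoverModel(design).fit(top_fraction=0.05)
        table = res.table.set_index("bin")
        assert table.loc[45, "direction"] == "increase"
        assert table.loc[45, "significant"]
        assert table.loc[30, "direction"] == "decrease"

    def test_u_within_bounds_and_p_valid(self, rng, small_axis):
        design = self._design(rng, small_axis, up_bin=45)
        res = TurnoverModel(design).fit()
        n1n2 = len(design.treated) * len(design.control)
        assert ((res.table["U"] >= 0) & (res.table["U"] <= n1n2)).all()
        assert ((res.table["p"] > 0) & (res.table["p"] <= 1)).all()

    def test_bh_adjustment_monotone(self, rng, small_axis):
        design = self._design(rng, small_axis, up_bin=45, down_bin=30)
        res = TurnoverModel(design).fit(adjust="bh")
        assert (res.table["p_adj"] >= res.table["p"] - 1e-12).all()

    def test_summary_mentions_design(self, rng, small_axis):
        design = self._design(rng, small_axis, up_bin=45)
        text = TurnoverModel(design).fit().summary()
        assert "treated vs control" in text
        assert "n_treated=6" in text

    def test_axis_mismatch_rejected(self, rng, small_axis, axis):
        d1 = self._design(rng, small_axis, up_bin=45)
        r1 = TurnoverModel(d1).fit()
        other = RoiSpectrum(1, np.ones(axis.n_bins), axis, 1)
        with pytest.raises(ValueError, match="mass axis"):
            GroupDesign("x", [other, other], d1.control, 1)
        r2 = TurnoverModel(self._design(rng, small_axis, up_bin=60)).fit()
        joint = compare_conditions(r1, r2, names=("a", "b"))
        assert {"direction_a", "direction_b"} <= set(joint.columns)

    def test_compare_identical_arms(self, rng, small_axis):
        design = self._design(rng, small_axis, up_bin=45)
        res = TurnoverModel(design).fit()
        joint = compare_conditions(res, res, names=("x", "y"))
        assert joint["direction_x"].equals(joint["direction_y"])
        assert joint["p_x"].equals(joint["p_y"])


class TestIsotopeTurnoverCalls:
    def test_choline_arm_headgroup_calls(self, sim_config, rng):
        """A 15N-choline arm raises the labeled headgroup bin (185.07) and
        lowers the unlabeled one (184.07)."""
        from simslipid.roi import remove_interference, tic_normalize
        from simslipid.simulate import simulate_roi_spectra, simulation_library

        cfg = sim_config
        arm, pol = "15N-choline", 1
        treated = [
            tic_normalize(remove_interference(s))
            for s in simulate_roi_spectra(cfg, arm, pol, cfg.n_treated, rng)
        ]
        control = [
            tic_normalize(remove_interference(s))
            for s in simulate_roi_spectra(cfg, "control", pol, cfg.n_control, rng)
        ]
        design = GroupDesign(arm, treated, control, pol)
        from simslipid.formula import DELTA_N15

        model = TurnoverModel(design, library=simulation_library(cfg, pol),
                              label_delta=DELTA_N15)
        res = model.fit()
        axis = cfg.mass_axis
        table = res.table.set_index("bin")
        unlabeled = int(axis.bin_of(184.0733))
        labeled = int(axis.bin_of(184.0733 + DELTA_N15))
        assert table.loc[labeled, "direction"] == "increase"
        assert table.loc[labeled, "significant"]
        assert bool(table.loc[labeled, "isotope_shift"])
        assert table.loc[unlabeled, "direction"] == "decrease"
        assert not bool(table.loc[unlabeled, "isotope_shift"])
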