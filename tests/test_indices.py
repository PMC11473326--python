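"""LPTI/LPPI construction, PCA retention, quadrant classes, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lowptol as lp
from lowptol.indices import pca_kaiser, relative_trait_values, select_lines


def _lines(n):
    return [f"L{i:03d}" for i in range(n)]


class TestRelativeTraitValues:
    def test_equal_blups_give_unit_ratios(self):
        m = pd.DataFrame(np.arange(1.0, 7.0).reshape(3, 2), index=_lines(3),
                         columns=["a", "b"])
        assert np.allclose(relative_trait_values(m, m), 1.0)

    def test_half_scale(self):
        ap = pd.DataFrame(np.full((3, 2), 4.0), index=_lines(3), columns=["a", "b"])
        assert np.allclose(relative_trait_values(0.5 * ap, ap), 0.5)

    def test_reference_line_ratio(self):
        """Stalk diameter of a selected line: 4.56 / 6.32 under stress/control."""
        nap = pd.DataFrame({"SD": [4.56]}, index=["VML002"])
        ap = pd.DataFrame({"SD": [6.32]}, index=["VML002"])
        ratio = relative_trait_values(nap, ap)
        assert ratio.loc["VML002", "SD"] == pytest.approx(0.7215, abs=5e-4)

    def test_near_zero_control_rejected_with_location(self):
        nap = pd.DataFrame({"a": [1.0, 2.0]}, index=["L1", "L2"])
        ap = pd.DataFrame({"a": [1.0, 1e-12]}, index=["L1", "L2"])
        with pytest.raises(ValueError, match="L2"):
            relative_trait_values(nap, ap)


class TestStandardize:
    def test_column_values(self):
        m = pd.DataFrame({"a": [2.0, 4.0, 6.0]}, index=_lines(3))
        assert np.allclose(lp.standardize(m)["a"], [-1.0, 0.0, 1.0])

    def test_constant_column_rejected(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0]}, index=_lines(3))
        with pytest.raises(ValueError):
            lp.standardize(m)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(10, 3)), index=_lines(10))
        z = lp.standardize(m)
        pd.testing.assert_frame_equal(lp.standardize(z), z)


class TestPcaKaiser:
    def test_uncorrelated_identity_spectrum(self):
        """Columns built mutually orthogonal: all eigenvalues 1, all retained."""
        base = np.array(
            [[1, 1, 1], [1, -1, 1], [-1, 1, 1], [-1, -1, 1],
             [1, 1, -1], [1, -1, -1], [-1, 1, -1], [-1, -1, -1]], dtype=float
        )
        z = lp.standardize(pd.DataFrame(base, index=_lines(8), columns=list("abc")))
        pca = pca_kaiser(z)
        assert np.allclose(pca.eigenvalues, 1.0)
        assert pca.retained.all()
        assert np.allclose(pca.contribution_rates, 1.0 / 3.0)

    def test_two_trait_closed_form(self):
        """2x2 correlation matrix has eigenvalues 1 +/- r; only PC1 retained."""
        rng = np.random.default_rng(21)
        x = rng.normal(size=500)
        y = 0.8 * x + 0.6 * rng.normal(size=500)
        z = lp.standardize(pd.DataFrame({"a": x, "b": y}, index=_lines(500)))
        r = np.corrcoef(z["a"], z["b"])[0, 1]
        pca = pca_kaiser(z)
        assert np.allclose(sorted(pca.eigenvalues), sorted([1 - r, 1 + r]))
        assert pca.retained.tolist() == [True, False]
        assert pca.contribution_rates[0] == pytest.approx((1 + r) / 2)

    def test_trace_conservation(self, panel_blups):
        z = lp.standardize(panel_blups[0])
        pca = pca_kaiser(z)
        assert pca.eigenvalues.sum() == pytest.approx(z.shape[1], rel=1e-10)
        assert pca.contribution_rates.sum() == pytest.approx(1.0, rel=1e-10)

    def test_loading_orientation_sums_positive(self, panel_blups):
        pca = pca_kaiser(lp.standardize(panel_blups[0]))
        retained_cols = pca.loadings.columns[: pca.retained.sum()]
        for c in retained_cols:
            assert pca.loadings[c].sum() >= 0

    def test_more_traits_than_lines_rejected(self):
        m = pd.DataFrame(np.random.default_rng(1).normal(size=(3, 3)),
                         index=_lines(3))
        with pytest.raises(ValueError):
            pca_kaiser(m)


class TestIndices:
    def _panel(self, n=30, seed=4):
        rng = np.random.default_rng(seed)
        nap = pd.DataFrame(rng.normal(10, 2, size=(n, 4)), index=_lines(n),
                           columns=list("abcd"))
        ap = pd.DataFrame(rng.normal(12, 2, size=(n, 4)), index=_lines(n),
                          columns=list("abcd"))
        return nap, ap.abs() + 1.0

    def test_uniformly_best_line_attains_max_lpti(self):
        """A line whose relative values dominate everywhere scores highest."""
        rng = np.random.default_rng(17)
        n = 25
        factor = rng.normal(size=n)
        factor[0] = factor.max() + 3.0  # line 0 uniformly most tolerant
        rel_noise = 0.05 * rng.normal(size=(n, 4))
        nap = pd.DataFrame(
            (1.0 + 0.2 * factor[:, None] + rel_noise) * 10.0,
            index=_lines(n), columns=list("abcd"),
        )
        ap = pd.DataFrame(np.full((n, 4), 10.0), index=_lines(n), columns=list("abcd"))
        lpti, _ = lp.compute_lpti(nap, ap)
        assert lpti.idxmax() == "L000"

    def test_single_retained_component_scales_scores(self):
        """With one retained PC, the index is CR1 times the PC1 score."""
        rng = np.random.default_rng(33)
        x = rng.normal(size=100)
        nap = pd.DataFrame(
            {"a": x + 0.1 * rng.normal(size=100),
             "b": x + 0.1 * rng.normal(size=100)},
            index=_lines(100),
        )
        lppi, pca = lp.compute_lppi(nap)
        assert pca.retained.sum() == 1
        cr1 = pca.contribution_rates[0]
        assert np.allclose(lppi, cr1 * pca.scores["PC1"])
        assert lppi.rank().equals(pca.scores["PC1"].rank())

    def test_lppi_mean_zero_and_two_line_symmetry(self):
        nap, _ = self._panel()
        lppi, _ = lp.compute_lppi(nap)
        assert lppi.mean() == pytest.approx(0.0, abs=1e-10)

    def test_identical_profiles_degenerate(self):
        nap = pd.DataFrame(np.ones((5, 3)), index=_lines(5), columns=list("abc"))
        with pytest.raises(ValueError):
            lp.compute_lppi(nap)

    def test_latent_factor_recovery(self):
        """LPTI tracks a known tolerance factor (Spearman > 0.9 at low noise)."""
        rng = np.random.default_rng(2024)
        n, T = 151, 8
        factor = rng.normal(size=n)
        loadings = 0.5 + rng.random(T)
        noise = 0.3 * rng.normal(size=(n, T))
        rel = 1.0 + factor[:, None] * loadings[None, :] + noise
        nap = pd.DataFrame(rel * 10.0, index=_lines(n),
                           columns=[f"t{j}" for j in range(T)])
        ap = pd.DataFrame(np.full((n, T), 10.0), index=_lines(n),
                          columns=[f"t{j}" for j in range(T)])
        lpti, _ = lp.compute_lpti(nap, ap)
        from scipy import stats

        rho = stats.spearmanr(lpti, factor)[0]
        assert rho > 0.9


class TestClassifyGroups:
    @pytest.mark.parametrize(
        "lpti, lppi, expected",
        [(1.0, 1.0, "TG"), (1.0, -1.0, "TP"), (-1.0, 1.0, "SG"), (-1.0, -1.0, "SP"),
         (0.0, 0.0, "SP")],
    )
    def test_quadrants(self, lpti, lppi, expected):
        got = lp.classify_groups(pd.Series({"x": lpti}), pd.Series({"x": lppi}))
        assert got["x"] == expected

    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
                    min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_groups_partition_lines(self, pairs):
        idx = [f"L{i}" for i in range(len(pairs))]
        lpti = pd.Series([a for a, _ in pairs], index=idx)
        lppi = pd.Series([b for _, b in pairs], index=idx)
        groups = lp.classify_groups(lpti, lppi)
        assert set(groups.unique()) <= set(lp.indices.GROUPS)
        assert groups.index.tolist() == idx  # every line assigned exactly once


class TestSelectLines:
    def test_top_zero_empty(self):
        s = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        out = select_lines(s, s, top_k=0, bottom_k=0)
        assert not out["selected_top"].any() and not out["selected_bottom"].any()

    def test_strictly_ordered_panel(self):
        s = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        out = select_lines(s, s, top_k=2, bottom_k=1)
        assert set(out.index[out["selected_top"]]) == {"a", "b"}
        assert set(out.index[out["selected_bottom"]]) == {"e"}

    def test_matches_rank_sum_oracle(self):
        rng = np.random.default_rng(55)
        n = 20
        lpti = pd.Series(rng.normal(size=n), index=_lines(n))
        lppi = pd.Series(rng.normal(size=n), index=_lines(n))
        out = select_lines(lpti, lppi, top_k=6, bottom_k=3)
        # independent oracle: brute-force rank-sum over all lines
        r1 = {i: sorted(lpti.index, key=lambda x: -lpti[x]).index(i) + 1
              for i in lpti.index}
        r2 = {i: sorted(lppi.index, key=lambda x: -lppi[x]).index(i) + 1
              for i in lppi.index}
        total = {i: r1[i] + r2[i] for i in lpti.index}
        expect_top = set(sorted(total, key=lambda i: (total[i], i))[:6])
        expect_bottom = set(sorted(total, key=lambda i: (-total[i], i))[:3])
        assert set(out.index[out["selected_top"]]) == expect_top
        assert set(out.index[out["selected_bottom"]]) == expect_bottom

    def test_k_exceeding_n_rejected(self):
        s = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError):
            select_lines(s, s, top_k=3, bottom_k=0)


def test_indices_invariant_to_affine_trait_rescaling():
    """Standardization absorbs affine changes of any input trait."""
    rng = np.random.default_rng(91)
    n = 40
    nap = pd.DataFrame(rng.normal(10, 2, size=(n, 3)), index=_lines(n),
                       columns=list("abc"))
    lppi, _ = lp.compute_lppi(nap)
    scaled = nap.copy()
    scaled["b"] = scaled["b"] * 7.0 + 3.0
    lppi2, _ = lp.compute_lppi(scaled)
    # affine rescaling leaves the standardized matrix, hence the index, intact
    assert np.allclose(lppi, lppi2)


def test_positive_dependence_between_indices_on_construction():
    """Panels built so stress performance drives both indices correlate positively."""
    rng = np.random.default_rng(10)
    n = 100
    quality = rng.normal(size=n)
    nap = pd.DataFrame(
        10 + 2 * quality[:, None] + rng.normal(size=(n, 4)),
        index=_lines(n), columns=list("abcd"),
    )
    ap = pd.DataFrame(
        12 + rng.normal(size=(n, 4)) * 0.5,
        index=_lines(n), columns=list("abcd"),
    )
    tbl, _, _ = lp.index_table(nap, ap, top_k=10, bottom_k=5)
    assert tbl["LPTI"].corr(tbl["LPPI"]) > 0
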