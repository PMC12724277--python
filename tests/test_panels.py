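"""Panel construction: medians, M-values, classifiers, mixed contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ceam
from ceam.panels import (
    CELL_TYPES,
    CellTypePanel,
    PanelError,
    _intermediate,
    beta_to_m,
    classify_high,
    classify_low,
    classify_medium,
    compute_median_profile,
    intersect_cohorts,
    pairwise_mixed_contrasts,
    validate_beta_matrix,
)


def _profile(rows: dict) -> pd.DataFrame:
    """Median profile frame from {cpg: (NEU, MG, OLIG, AST)}."""
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CELL_TYPES))


def _tiny_cohort(values_by_cell, n_per_cell=3):
    """One-CpG beta matrix + metadata with given per-cell-type values."""
    cols, meta_rows = {}, []
    for cell, values in values_by_cell.items():
        for i, v in enumerate(values):
            sid = f"{cell}{i}"
            cols[sid] = [v]
            meta_rows.append((sid, f"D{i}", cell, 80.0, "F", "A"))
    betas = pd.DataFrame(cols, index=["c1"])
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "donor_id", "cell_type", "age", "sex", "cohort"]
    )
    return betas, meta


class TestMedianProfile:
    @pytest.mark.parametrize(
        "values,expected",
        [((0.4, 0.5, 0.6), 0.5), ((0.4, 0.6), 0.5), ((0.9, 0.9), 0.9)],
    )
    def test_median_conventions(self, values, expected):
        betas, meta = _tiny_cohort(
            {"NEU": values, "MG": (0.1, 0.1), "OLIG": (0.1, 0.1), "AST": (0.1, 0.1)}
        )
        profile = compute_median_profile(betas, meta)
        assert profile.loc["c1", "NEU"] == pytest.approx(expected)

    def test_unknown_cell_type_rejected(self):
        betas, meta = _tiny_cohort({c: (0.5, 0.5) for c in CELL_TYPES})
        meta.loc[0, "cell_type"] = "ASTRO"
        with pytest.raises(PanelError, match="cell_type"):
            compute_median_profile(betas, meta)

    def test_requires_two_samples_per_cell_type(self):
        betas, meta = _tiny_cohort(
            {"NEU": (0.5,), "MG": (0.1, 0.1), "OLIG": (0.1, 0.1), "AST": (0.1, 0.1)}
        )
        with pytest.raises(PanelError, match="at least 2"):
            compute_median_profile(betas, meta)

    def test_missing_values_refused(self):
        betas = pd.DataFrame({"s1": [0.5], "s2": [np.nan]}, index=["c1"])
        with pytest.raises(PanelError, match="missing"):
            validate_beta_matrix(betas)

    def test_out_of_range_refused(self):
        betas = pd.DataFrame({"s1": [1.2]}, index=["c1"])
        with pytest.raises(PanelError, match=r"\[0, 1\]"):
            validate_beta_matrix(betas)


class TestBetaToM:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_logit2_values(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_antisymmetric_and_finite(self, beta):
        assert np.isfinite(beta_to_m(beta))
        assert beta_to_m(beta) == pytest.approx(-beta_to_m(1.0 - beta), abs=1e-9)

    @given(st.floats(0.01, 0.98), st.floats(0.001, 0.019))
    def test_monotone(self, beta, step):
        assert beta_to_m(beta + step) > beta_to_m(beta)

    def test_epsilon_bounds(self):
        with pytest.raises(PanelError):
            beta_to_m(0.5, epsilon=0.7)


class TestClassifyHigh:
    def test_forced_assignment(self):
        p = _profile({"c1": (0.50, 0.05, 0.95, 0.02)})
        panel = classify_high(p, p)
        assert "c1" in panel.assignments["NEU"]
        assert all(not panel.assignments[c] for c in ("MG", "OLIG", "AST"))

    def test_exclusivity_violated(self):
        p = _profile({"c1": (0.50, 0.45, 0.05, 0.05)})
        assert classify_high(p, p).all_cpgs() == frozenset()

    def test_gap_criterion(self):
        p = _profile({"c1": (0.15, 0.08, 0.92, 0.95)})
        assert classify_high(p, p).all_cpgs() == frozenset()

    def test_all_extreme_never_assigned(self):
        p = _profile({"hypo": (0.03, 0.05, 0.02, 0.04), "hyper": (0.95, 0.99, 0.93, 0.96)})
        assert classify_high(p, p).all_cpgs() == frozenset()

    def test_cohort_disagreement_excludes(self):
        pa = _profile({"c1": (0.50, 0.05, 0.95, 0.02)})
        pb = _profile({"c1": (0.05, 0.50, 0.95, 0.02)})  # assigned to MG in B
        assert classify_high(pa, pb).all_cpgs() == frozenset()


class TestClassifyMedium:
    def test_three_intermediate_one_extreme(self):
        p = _profile({"c1": (0.5, 0.5, 0.5, 0.05)})
        panel = classify_medium(p, p)
        for cell in ("NEU", "MG", "OLIG"):
            assert "c1" in panel.assignments[cell]
        assert "c1" not in panel.assignments["AST"]

    def test_no_extreme_cell_type_excluded(self):
        p = _profile({"c1": (0.5, 0.5, 0.5, 0.5)})
        assert classify_medium(p, p).all_cpgs() == frozenset()

    def test_medium_gap_flag(self):
        # target 0.15 vs extreme 0.08: gap 0.07 < 0.1 fails only when enforced
        p = _profile({"c1": (0.15, 0.08, 0.95, 0.95)})
        assert "c1" in classify_medium(p, p).assignments["NEU"]
        assert "c1" not in classify_medium(p, p, require_gap=True).assignments["NEU"]


class TestPairwiseContrasts:
    def test_bonferroni_rule_and_null_level(self, purified_meta):
        rng = np.random.default_rng(3)
        n_donors, n_cpgs = 20, 60
        donor_eff = rng.normal(0, 0.5, size=(n_donors, n_cpgs))
        data = {}
        for d in range(n_donors):
            for cell in CELL_TYPES:
                data[f"D{d}_{cell}"] = rng.normal(0, 1, n_cpgs) + donor_eff[d]
        M = pd.DataFrame(data, index=[f"c{i}" for i in range(n_cpgs)])
        res = pairwise_mixed_contrasts(M, purified_meta)
        assert len(res) == 6 * n_cpgs
        assert np.allclose(res["p_bonf"], np.minimum(1.0, 6 * res["p_raw"]))
        assert (res["p_bonf"] >= res["p_raw"]).all()
        # identical distributions in all cell types: p approximately uniform
        assert 0.01 <= (res["p_raw"] < 0.05).mean() <= 0.11

    def test_power_for_large_shift(self, purified_meta):
        rng = np.random.default_rng(4)
        n_donors, n_cpgs = 20, 10
        donor_eff = rng.normal(0, 0.5, size=(n_donors, n_cpgs))
        data = {}
        for d in range(n_donors):
            for cell in CELL_TYPES:
                shift = 4.0 if cell == "NEU" else 0.0
                data[f"D{d}_{cell}"] = rng.normal(shift, 1, n_cpgs) + donor_eff[d]
        M = pd.DataFrame(data, index=[f"c{i}" for i in range(n_cpgs)])
        res = pairwise_mixed_contrasts(M, purified_meta)
        neu = res[(res["cell_a"] == "NEU") | (res["cell_b"] == "NEU")]
        assert (neu["p_bonf"] < 0.05).all()

    def test_single_donor_flagged_failed(self, purified_meta):
        meta1 = purified_meta[purified_meta["donor_id"] == "D0"]
        M = pd.DataFrame(
            {s: [0.1 * i for i in range(2)] for s in meta1["sample_id"]},
            index=["c1", "c2"],
        )
        res = pairwise_mixed_contrasts(M, meta1)
        assert set(res["method"]) == {"failed"}
        assert res["p_bonf"].isna().all()

    def test_trivial_bonferroni_example(self):
        assert min(1.0, 6 * 0.02) == pytest.approx(0.12)


class TestClassifyLow:
    def _contrasts(self, cpg, pvals_by_pair):
        rows = []
        for (a, b), p in pvals_by_pair.items():
            rows.append((cpg, a, b, 1.0, p / 6, min(1.0, p), "mixed_reml"))
        return pd.DataFrame(
            rows,
            columns=["cpg_id", "cell_a", "cell_b", "estimate", "p_raw", "p_bonf", "method"],
        )

    def test_statistical_route(self):
        p = _profile({"c1": (0.5, 0.45, 0.45, 0.45)})
        contrasts = self._contrasts(
            "c1",
            {("NEU", "MG"): 1e-4, ("NEU", "OLIG"): 1e-4, ("NEU", "AST"): 1e-4,
             ("MG", "OLIG"): 0.9, ("MG", "AST"): 0.9, ("OLIG", "AST"): 0.9},
        )
        empty = CellTypePanel("high", {})
        empty_m = CellTypePanel("medium", {})
        panel = classify_low(p, p, contrasts, contrasts, empty, empty_m)
        assert "c1" in panel.assignments["NEU"]
        assert "c1" not in panel.assignments["MG"]

    def test_one_failed_contrast_blocks_route(self):
        p = _profile({"c1": (0.5, 0.45, 0.45, 0.45)})
        contrasts = self._contrasts(
            "c1",
            {("NEU", "MG"): 1e-4, ("NEU", "OLIG"): 0.2, ("NEU", "AST"): 1e-4,
             ("MG", "OLIG"): 0.9, ("MG", "AST"): 0.9, ("OLIG", "AST"): 0.9},
        )
        empty = CellTypePanel("high", {})
        empty_m = CellTypePanel("medium", {})
        panel = classify_low(p, p, contrasts, contrasts, empty, empty_m)
        assert "c1" not in panel.assignments["NEU"]

    def test_carry_over_regardless_of_contrasts(self):
        p = _profile({"c1": (0.05, 0.5, 0.95, 0.02)})
        no_contrasts = self._contrasts("c1", {})
        high = CellTypePanel("high", {"MG": {"c1"}})
        medium = CellTypePanel("medium", {"MG": {"c1"}})
        panel = classify_low(p, p, no_contrasts, no_contrasts, high, medium)
        assert "c1" in panel.assignments["MG"]


class TestIntersectAndInvariants:
    def test_intersection_examples(self):
        a = CellTypePanel("high", {"NEU": {"c1", "c2"}})
        b = CellTypePanel("high", {"NEU": {"c2", "c3"}})
        assert intersect_cohorts(a, b).assignments["NEU"] == {"c2"}
        assert intersect_cohorts(a, a).assignments == a.assignments
        disjoint = CellTypePanel("high", {"NEU": {"c9"}})
        assert intersect_cohorts(a, disjoint).assignments["NEU"] == frozenset()

    def test_specificity_mismatch_rejected(self):
        a = CellTypePanel("high", {})
        b = CellTypePanel("medium", {})
        with pytest.raises(PanelError, match="mismatch"):
            intersect_cohorts(a, b)

    def test_high_disjointness_enforced(self):
        with pytest.raises(PanelError, match="share"):
            CellTypePanel("high", {"NEU": {"c1"}, "MG": {"c1"}})

    def test_nesting_and_disjointness_on_fixture(self, built_panels):
        high, medium, low = (built_panels[k] for k in ("high", "medium", "low"))
        for cell in CELL_TYPES:
            assert high.assignments[cell] <= medium.assignments[cell]
            assert medium.assignments[cell] <= low.assignments[cell]
        high.check_disjoint()

    def test_determinism(self, planted):
        _, ((betas_a, meta_a), (betas_b, meta_b)) = planted
        pa = compute_median_profile(betas_a, meta_a)
        pb = compute_median_profile(betas_b, meta_b)
        assert classify_high(pa, pb) == classify_high(pa.copy(), pb.copy())


class TestThresholdTies:
    def test_borderline_medians_excluded_by_strict_inequality(self):
        truth = ceam.make_borderline_truth(np.random.default_rng(0))
        (ba, ma), (bb, mb) = ceam.synth_purified_cohorts(4, truth, seed=1)
        pa = compute_median_profile(ba, ma)
        pb = compute_median_profile(bb, mb)
        high = classify_high(pa, pb)
        medium = classify_medium(pa, pb)
        # medians exactly at 0.1 / 0.9 are not intermediate
        assert "edge_low" not in high.all_cpgs() | medium.all_cpgs()
        assert "edge_high" not in high.all_cpgs() | medium.all_cpgs()
        # a gap of exactly 0.1 satisfies the >= criterion
        assert "edge_gap" in high.assignments["NEU"]
        assert not _intermediate(pa).loc["edge_low", "NEU"]
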