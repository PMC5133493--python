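import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbnet.comorbidity import (
    DegenerateMarginError,
    bootstrap_prevalence_ci,
    comorbidity_profile,
    gender_stratified_profile,
    pair_statistics,
    select_by_rr,
    stratified_prevalence,
)
from comorbnet.data_model import build_cooccurrence
from comorbnet.simulate import DiseasePlan, PopulationSpec, generate_population
from conftest import make_diag


def brute_force_stats(patient_codes, i, j):
    """Independent oracle: RR and phi from raw indicator vectors."""
    x = np.array([i in s for s in patient_codes], dtype=float)
    y = np.array([j in s for s in patient_codes], dtype=float)
    n = len(x)
    rr = (x * y).mean() / (x.mean() * y.mean())
    phi = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    return rr, phi


class TestPairStatistics:
    @pytest.mark.parametrize(
        "C,Ii,Ij,N,rr,phi",
        [
            (5, 100, 50, 1000, 1.0, 0.0),   # exact independence
            (5, 20, 10, 100, 2.5, 0.25),    # hand evaluation
            (5, 5, 5, 10, 2.0, 1.0),        # perfect overlap
        ],
    )
    def test_printed_formulas(self, C, Ii, Ij, N, rr, phi):
        got = pair_statistics(C, Ii, Ij, N)
        assert got.rr == pytest.approx(rr)
        assert got.phi == pytest.approx(phi)

    @pytest.mark.parametrize("Ii,Ij", [(0, 5), (10, 5), (5, 0), (5, 10)])
    def test_degenerate_margin_raises(self, Ii, Ij):
        with pytest.raises(DegenerateMarginError):
            pair_statistics(0, Ii, Ij, 10)

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValueError):
            pair_statistics(6, 5, 5, 10)

    def test_symmetry_in_pair(self):
        assert pair_statistics(3, 12, 7, 40) == pair_statistics(3, 7, 12, 40)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.sets(st.sampled_from("AB")), min_size=4, max_size=10))
    def test_matches_brute_force_and_independence_equivalence(self, pop):
        ia = sum("A" in s for s in pop)
        ib = sum("B" in s for s in pop)
        n = len(pop)
        if ia in (0, n) or ib in (0, n):
            return  # degenerate margins are covered separately
        c = sum({"A", "B"} <= s for s in pop)
        got = pair_statistics(c, ia, ib, n)
        rr, phi = brute_force_stats(pop, "A", "B")
        assert got.rr == pytest.approx(rr)
        assert got.phi == pytest.approx(phi)
        # RR = 1 and phi = 0 flag independence together
        assert (got.rr == pytest.approx(1.0)) == (got.phi == pytest.approx(0.0, abs=1e-12))
        assert math.copysign(1, got.rr - 1) == math.copysign(1, got.phi) or got.phi == 0


class TestComorbidityProfile:
    def make_cooc(self):
        rows = [("p1", "496", 70, "M"), ("p1", "491", 70, "M"),
                ("p2", "496", 75, "F"), ("p2", "250", 75, "F"),
                ("p3", "491", 80, "M"), ("p4", "250", 66, "F")]
        return build_cooccurrence(make_diag(rows))

    def test_one_row_per_other_code(self):
        prof = comorbidity_profile(self.make_cooc(), "496")
        assert list(prof.rows.index) == ["250", "491"]

    def test_rows_match_pair_statistics(self):
        cooc = self.make_cooc()
        prof = comorbidity_profile(cooc, "496")
        for code in prof.rows.index:
            expect = pair_statistics(
                cooc.get_C(code, "496"), cooc.I[code], cooc.I["496"], cooc.N
            )
            assert prof.rows.loc[code, "RR"] == pytest.approx(expect.rr)
            assert prof.rows.loc[code, "Phi"] == pytest.approx(expect.phi)

    def test_never_codiagnosed_gives_rr_zero_phi_negative(self):
        rows = [("p1", "496", 70, "M"), ("p2", "300", 70, "M"), ("p3", "X", 70, "M")]
        prof = comorbidity_profile(build_cooccurrence(make_diag(rows)), "496")
        assert prof.rows.loc["300", "RR"] == 0.0
        assert prof.rows.loc["300", "Phi"] < 0

    def test_missing_index_code_raises(self):
        with pytest.raises(KeyError):
            comorbidity_profile(self.make_cooc(), "999")

    def test_degenerate_code_carried_with_missing_phi(self):
        rows = [("p1", "496", 70, "M"), ("p1", "V70", 70, "M"),
                ("p2", "V70", 70, "M")]
        prof = comorbidity_profile(build_cooccurrence(make_diag(rows)), "496")
        assert prof.rows.loc["V70", "degenerate"]
        assert np.isnan(prof.rows.loc["V70", "Phi"])
        assert prof.rows.loc["V70", "RR"] == pytest.approx(1.0)


class TestSelectByRR:
    def make_profile(self, rrs):
        rows = pd.DataFrame({"RR": pd.Series(rrs)})
        from comorbnet.comorbidity import ComorbidityProfile
        return ComorbidityProfile(index_code="496", rows=rows)

    def test_strict_inequality(self):
        prof = self.make_profile({"A": 1.3, "B": 1.2, "C": 0.9})
        assert select_by_rr(prof, 1.2) == ["A"]

    def test_empty_profile(self):
        assert select_by_rr(self.make_profile({}), 1.2) == []

    def test_all_above(self):
        prof = self.make_profile({"B": 2.0, "A": 3.0})
        assert select_by_rr(prof, 1.2) == ["A", "B"]


class TestStratifiedPrevalence:
    def test_hand_count_window(self):
        # ages 74, 75, 76 are inside the 75 +/- 2 window; 80 is not
        rows = [("p1", "496", 74, "M"), ("p1", "T", 74, "M"),
                ("p2", "496", 75, "M"), ("p2", "T", 75, "M"),
                ("p3", "496", 76, "M"),
                ("p4", "496", 80, "M"), ("p4", "T", 80, "M")]
        prev = stratified_prevalence(make_diag(rows), {"T"}, "496",
                                     window_centers=[75], half_width=2,
                                     bootstrap_reps=10, seed=0)
        assert prev.loc[0, "prev_index"] == pytest.approx(2 / 3)
        assert prev.loc[0, "n_index"] == 3

    def test_target_equal_index_gives_one(self):
        rows = [("p1", "496", 75, "M"), ("p2", "496", 75, "F")]
        prev = stratified_prevalence(make_diag(rows), {"496"}, "496",
                                     window_centers=[75], half_width=2,
                                     bootstrap_reps=10)
        assert prev.loc[0, "prev_index"] == 1.0

    def test_empty_window_is_missing_not_zero(self):
        rows = [("p1", "496", 75, "M")]
        prev = stratified_prevalence(make_diag(rows), {"T"}, "496",
                                     window_centers=[90], half_width=2,
                                     bootstrap_reps=10)
        assert np.isnan(prev.loc[0, "prev_index"])
        assert prev.loc[0, "n_index"] == 0

    def test_window_endpoints_both_included(self):
        rows = [("p1", "496", 73, "M"), ("p1", "T", 73, "M"),
                ("p2", "496", 77, "M"), ("p2", "T", 77, "M"),
                ("p3", "496", 78, "M"), ("p3", "T", 78, "M")]
        prev = stratified_prevalence(make_diag(rows), {"T"}, "496",
                                     window_centers=[75], half_width=2,
                                     bootstrap_reps=10)
        assert prev.loc[0, "n_index"] == 2  # 73 and 77 in, 78 out


class TestBootstrapCI:
    def test_all_ones(self):
        assert bootstrap_prevalence_ci([1, 1, 1], B=50, seed=0) == (1.0, 1.0)

    def test_half_ones_interval(self):
        flags = [1] * 50 + [0] * 50
        lo, hi = bootstrap_prevalence_ci(flags, B=1000, level=0.95, seed=42)
        # analytic percentile interval for Binomial(100, .5)/100 is ~[.40, .60]
        assert lo == pytest.approx(0.40, abs=0.03)
        assert hi == pytest.approx(0.60, abs=0.03)

    def test_single_replicate_degenerate(self):
        lo, hi = bootstrap_prevalence_ci([0, 1], B=1, seed=3)
        assert lo == hi

    def test_deterministic_given_seed(self):
        flags = [0, 1, 1, 0, 1]
        assert bootstrap_prevalence_ci(flags, 100, seed=7) == bootstrap_prevalence_ci(
            flags, 100, seed=7
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_prevalence_ci([], B=10)


class TestGenderStratified:
    def test_no_sex_effect_gives_small_differences(self):
        spec = PopulationSpec(
            n_patients=40_000, index_prevalence=0.1,
            diseases={"491": DiseasePlan(prevalence=0.05, rr=2.0)}, seed=5,
        )
        diag, _ = generate_population(spec)
        table = gender_stratified_profile(diag, "496")
        # ~3 standard errors of the stratified RR/Phi difference at this size
        assert abs(table.loc["491", ("diff_M_minus_F", "RR")]) < 0.5
        assert abs(table.loc["491", ("diff_M_minus_F", "Phi")]) < 0.05

    def test_planted_female_only_comorbidity(self):
        spec = PopulationSpec(
            n_patients=40_000, index_prevalence=0.1,
            diseases={"491": DiseasePlan(prevalence=0.05, rr=1.0, rr_female=3.0)},
            seed=6,
        )
        diag, _ = generate_population(spec)
        table = gender_stratified_profile(diag, "496")
        assert table.loc["491", ("F", "RR")] > table.loc["491", ("M", "RR")] + 1.0

    def test_pct_is_one_for_universal_code(self):
        rows = [("p1", "496", 70, "M"), ("p1", "ALL", 70, "M"),
                ("p2", "496", 70, "F"), ("p2", "ALL", 70, "F"),
                ("p3", "ALL", 70, "M"), ("p4", "ALL", 70, "F")]
        table = gender_stratified_profile(make_diag(rows), "496")
        assert table.loc["ALL", ("M", "pct")] == 1.0
        assert table.loc["ALL", ("F", "pct")] == 1.0
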