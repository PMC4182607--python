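"""Wilcoxon/BH oracles, QC filtering, summaries, family runs."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

import epiquant as eq
from epiquant import (
    Comparison,
    ExplantRecord,
    FamilyDeclaration,
    PairedSample,
    bh_adjust,
    filter_explants,
    ratio_test,
    run_comparison_family,
    summarize,
    wilcoxon_signed_rank,
)
from epiquant._core import ValidationError


def brute_force_wilcoxon_p(diffs):
    """Oracle: two-sided exact p by enumerating all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    lower = (ws <= w_obs + 1e-9).mean()
    upper = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(lower, upper))


class TestWilcoxon:
    def test_all_positive_n5(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.p_value == pytest.approx(0.0625)
        assert res.method == "exact"

    def test_antisymmetric_pairs_give_p_one(self):
        res = wilcoxon_signed_rank([3, -3, 1.5, -1.5])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_for_all_small_n(self, rng):
        for n in range(1, 11):
            for _ in range(10):
                d = np.round(rng.normal(size=n), 1)  # induces ties and zeros
                if not (d != 0).any():
                    continue
                mine = wilcoxon_signed_rank(d, mode="exact").p_value
                assert mine == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_all_zero_differences_warn_and_return_one(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="epiquant.stats"):
            res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0 and res.n_used == 0
        assert any("zero" in r.message for r in caplog.records)

    def test_normal_approximation_close_to_exact_at_moderate_n(self, rng):
        d = rng.normal(0.4, 1.0, size=24)
        p_ex = wilcoxon_signed_rank(d, mode="exact").p_value
        p_no = wilcoxon_signed_rank(d, mode="normal").p_value
        assert p_no == pytest.approx(p_ex, abs=0.02)

    def test_paired_sample_interface(self):
        ps = PairedSample("t", inner=(1, 2, 3, 4, 5), outer=(2, 4, 6, 8, 10))
        res = wilcoxon_signed_rank(ps)
        assert res.p_value == pytest.approx(0.0625)  # all differences negative


class TestRatioTest:
    def test_all_ones_give_p_one(self):
        assert ratio_test([1.0] * 6).p_value == 1.0

    def test_all_above_one_n6(self):
        assert ratio_test([1.1, 1.3, 1.7, 2.0, 2.4, 3.0]).p_value == pytest.approx(0.03125)

    def test_log_and_raw_scales_agree_for_one_sided_ratios(self, rng):
        """When all ratios lie on one side of 1, |log r| and |r − 1| induce
        the same magnitude ranks, so the two formulations coincide.  (With
        ratios straddling 1 the rank magnitudes may differ, so the tests
        are not identical in general; the log scale is the shipped one.)"""
        r = 1.0 + rng.random(12) * 3  # all > 1
        assert ratio_test(r).p_value == pytest.approx(
            wilcoxon_signed_rank(r - 1.0).p_value
        )
        r_lo = 1.0 / r
        assert ratio_test(r_lo).p_value == pytest.approx(
            wilcoxon_signed_rank(r_lo - 1.0).p_value
        )

    def test_scale_invariance(self, rng):
        inner = np.exp(rng.normal(1, 0.5, size=10))
        outer = np.exp(rng.normal(1, 0.5, size=10))
        p1 = ratio_test(inner / outer).p_value
        p2 = ratio_test((7.3 * inner) / (7.3 * outer)).p_value
        assert p1 == pytest.approx(p2)

    def test_nonpositive_ratio_errors(self):
        with pytest.raises(ValidationError):
            ratio_test([1.0, 0.0, 2.0])


def brute_force_bh(p, m):
    """Oracle: direct step-up definition, O(n²)."""
    p = np.asarray(p, float)
    ranks = rankdata(p, method="ordinal")
    out = np.empty_like(p)
    for i in range(p.size):
        candidates = [
            min(1.0, p[j] * m / ranks[j]) for j in range(p.size) if ranks[j] >= ranks[i]
        ]
        out[i] = min(candidates)
    return out


class TestBH:
    def test_worked_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05]) == pytest.approx([0.05] * 5)
        assert bh_adjust([0.5]) == pytest.approx([0.5])
        assert bh_adjust([0.001, 0.5], 53) == pytest.approx([0.053, 1.0])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 20))
            p = rng.random(n)
            m = n + int(rng.integers(0, 40))
            np.testing.assert_allclose(bh_adjust(p, m), brute_force_bh(p, m), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_monotone_and_dominates_raw(self, rng):
        p = np.sort(rng.random(30))
        adj = bh_adjust(p, 53)
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()

    def test_family_smaller_than_list_errors(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 0.2, 0.3], 2)


class TestExplantFilter:
    def rec(self, hb, compartment="epidermis", sid="s1"):
        return ExplantRecord(
            subject_id=sid,
            site="inner",
            compartment=compartment,
            hemoglobin_concentration=hb,
            lod=1.0,
            lod_ci=0.2,
        )

    def test_boundary_is_inclusive(self):
        kept, excluded = filter_explants([self.rec(1.2)])
        assert not kept and len(excluded) == 1
        assert "1.2" in excluded[0].reason

    def test_below_lod_kept_and_dermis_passes(self):
        kept, excluded = filter_explants([self.rec(0.5), self.rec(99.0, "dermis")])
        assert len(kept) == 2 and not excluded

    def test_missing_qc_fields_error(self):
        bad = ExplantRecord(subject_id="s", site="inner")
        with pytest.raises(ValidationError, match="QC"):
            filter_explants([bad])

    def test_cohort_flags_recovered_exactly(self):
        co = eq.generate_cohort(
            eq.CohortSpec(n_subjects=20, hemoglobin_contamination_rate=0.15, seed=4)
        )
        epi = co.explants[co.explants["compartment"] == "epidermis"]
        records = [
            ExplantRecord(r.subject_id, r.site, "epidermis", {}, r.hemoglobin_ng_ml, r.lod, r.lod_ci)
            for r in epi.itertuples()
        ]
        _, excluded = filter_explants(records)
        got = {(e.record.subject_id, e.record.site) for e in excluded}
        want = {(r.subject_id, r.site) for r in epi.itertuples() if r.contaminated}
        assert got == want


class TestSummarize:
    def test_examples(self):
        med, (q1, q3) = summarize([1, 2, 3, 4, 5])
        assert (med, q1, q3) == (3, 2, 4)
        med, (q1, q3) = summarize([7.5])
        assert med == q1 == q3 == 7.5
        with pytest.raises(ValidationError):
            summarize([])

    def test_agreement_with_percentile_oracle(self, rng):
        for _ in range(300):
            v = rng.normal(size=int(rng.integers(1, 40)))
            med, (q1, q3) = summarize(v)
            assert med == pytest.approx(np.median(v))
            assert q1 == pytest.approx(np.quantile(v, 0.25))
            assert q3 == pytest.approx(np.quantile(v, 0.75))


class TestFamily:
    def test_family_of_one_leaves_p_unchanged(self):
        co = eq.generate_cohort(eq.CohortSpec(n_subjects=8, seed=1))
        fam = FamilyDeclaration((Comparison("sc_thickness_um"),))
        res = run_comparison_family(co, fam)[0]
        assert res.adjusted_p == pytest.approx(res.raw_p)
        assert res.family_size == 1

    def test_unresolvable_metric_errors_before_computation(self):
        co = eq.generate_cohort(eq.CohortSpec(n_subjects=5, seed=2))
        fam = FamilyDeclaration((Comparison("nonexistent_metric"),))
        with pytest.raises(ValidationError, match="nonexistent_metric"):
            run_comparison_family(co, fam)

    def test_verdicts_consistent_with_thresholds(self):
        eff = eq.study_effects()
        co = eq.generate_cohort(
            eq.CohortSpec(effects=eff["metric"], analyte_effects=eff["analyte"], seed=6)
        )
        from epiquant.stats import default_family

        results = run_comparison_family(co, default_family(co, 53))
        for r in results:
            assert r.adjusted_p >= r.raw_p - 1e-12
            assert 0 <= r.adjusted_p <= 1
            expect = (
                "significant"
                if r.adjusted_p < 0.05
                else ("trend" if r.adjusted_p < 0.10 else "ns")
            )
            assert r.verdict == expect

    def test_declared_family_size_smaller_than_members_errors(self):
        with pytest.raises(ValidationError):
            FamilyDeclaration((Comparison("a"), Comparison("b")), family_size=1)


def test_null_pvalues_are_uniform_or_superuniform():
    """One-sided KS: the ECDF of null Wilcoxon p-values never exceeds the
    uniform CDF by more than sampling noise (α = 0.01)."""
    rng = np.random.default_rng(77)
    pvals = []
    for _ in range(1000):
        d = rng.normal(size=17)
        pvals.append(wilcoxon_signed_rank(d).p_value)
    pvals = np.sort(pvals)
    ecdf = np.arange(1, len(pvals) + 1) / len(pvals)
    d_plus = float(np.max(ecdf - pvals))
    crit = 1.52 / np.sqrt(len(pvals))  # one-sided KS critical value, α = 0.01
    assert d_plus < crit
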