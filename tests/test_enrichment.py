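import numpy as np
import pytest
from scipy import stats as sps

from repsel.annotate import AnnotatedRearrangement
from repsel.enrichment import (CdrCountTable, EnrichmentRecord, count_cdr3,
                               detect_outliers, fit_selection_regression,
                               polyreactivity_flags)
from repsel.simulate import (apply_selection, assign_fitness, emit_reads,
                             simulate_repertoire)


def passing_record(cdr3, rid, chain="heavy"):
    return AnnotatedRearrangement(
        read_id=rid, sequence="", expected_chain=chain, locus="IGH",
        v_call="V", j_call="J", v_identity=100.0, junction="X",
        junction_start=0, junction_end=9, cdr3_aa=cdr3, productive=True,
        pass_filter=True)


def table(counts, library_id="L", chain="heavy"):
    return CdrCountTable(library_id, chain, counts)


def zipf_counts(rng, n, depth, s=1.1):
    w = np.arange(1, n + 1, dtype=float) ** -s
    counts = rng.multinomial(depth, w / w.sum())
    return {f"CDR{i:04d}": int(c) for i, c in enumerate(counts) if c}


class TestCountCdr3:
    def test_direct_multiset_count(self):
        recs = [passing_record("ARRGFDY", f"r{i}") for i in range(3)]
        t = count_cdr3(recs, "L1", "heavy")
        assert t.counts == {"ARRGFDY": 3} and t.total == 3

    def test_empty_input_gives_empty_table(self):
        t = count_cdr3([], "L1", "heavy")
        assert t.counts == {} and t.total == 0

    def test_unfiltered_record_rejected(self):
        rec = passing_record("AAA", "r0")
        rec.pass_filter = False
        with pytest.raises(ValueError, match="filter"):
            count_cdr3([rec], "L1", "heavy")

    def test_counts_match_simulation_truth(self, germline, annotator):
        rep = simulate_repertoire(germline, 100, rng_seed=31, chain="heavy")
        batch = emit_reads(rep, 2000, error_rate=0.0, rng_seed=32)
        from repsel.annotate import filter_annotations
        from repsel.merge import merge_batch
        recs = [annotator.annotate(m.seq, p.read_id, "heavy")
                for p, m in zip(batch.pairs, merge_batch(batch.pairs))]
        kept, _ = filter_annotations(recs)
        observed = count_cdr3(kept, "L", "heavy")
        expected = rep.truth_cdr3_counts(batch.clone_read_counts)
        assert observed.counts == expected


class TestRegression:
    def test_identity_pair_is_perfect_fit(self):
        rng = np.random.default_rng(0)
        counts = zipf_counts(rng, 100, 5000)
        fit = fit_selection_regression(table(counts, "A"), table(counts, "B"))
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fit.residuals, 0.0, atol=1e-9)
        assert all(r.label == "none" for r in detect_outliers(fit, alpha=0.5))

    def test_amplified_clone_has_largest_positive_residual(self):
        rng = np.random.default_rng(1)
        counts = zipf_counts(rng, 50, 3000)
        target = "CDR0025"
        enriched = dict(counts)
        enriched[target] = counts[target] * 100
        fit = fit_selection_regression(table(counts, "A"),
                                       table(enriched, "B"))
        top = fit.cdr3s[int(np.argmax(fit.residuals))]
        assert top == target

    def test_absent_keys_enter_with_zero(self):
        fit = fit_selection_regression(
            table({"A": 5, "B": 9, "C": 2}), table({"A": 4, "B": 11, "D": 7}))
        i_c = fit.cdr3s.index("C")
        i_d = fit.cdr3s.index("D")
        assert fit.enriched_counts[i_c] == 0
        assert fit.baseline_counts[i_d] == 0
        assert fit.n == 4

    def test_doubling_enriched_preserves_residual_ranking_log1p(self):
        rng = np.random.default_rng(2)
        counts = zipf_counts(rng, 80, 4000)
        enriched = {k: v + int(rng.integers(0, 5)) for k, v in counts.items()}
        f1 = fit_selection_regression(table(counts), table(enriched),
                                      transform="log1p")
        f2 = fit_selection_regression(table(counts),
                                      table({k: 2 * v for k, v in enriched.items()}),
                                      transform="log1p")
        rho = sps.spearmanr(f1.residuals, f2.residuals).statistic
        assert rho > 0.95

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_selection_regression(table({"A": 3, "B": 3, "C": 3}),
                                     table({"A": 1, "B": 2, "C": 9}))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_selection_regression(table({"A": 1}), table({"A": 2}))

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError, match="transform"):
            fit_selection_regression(table({"A": 1, "B": 2, "C": 3}),
                                     table({"A": 1, "B": 2, "C": 3}),
                                     transform="cube")


def loo_studentized_oracle(x, y):
    """Brute-force externally studentized residuals: for each point, refit
    without it and scale its prediction error by the out-of-sample standard
    error.  Pure numpy; independent of statsmodels."""
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        X = np.column_stack([np.ones(n - 1), x[mask]])
        beta, rss, *_ = np.linalg.lstsq(X, y[mask], rcond=None)
        resid = y[mask] - X @ beta
        s2 = float(resid @ resid) / (n - 3)
        xi = np.array([1.0, x[i]])
        var = s2 * (1.0 + xi @ np.linalg.inv(X.T @ X) @ xi)
        out[i] = (y[i] - xi @ beta) / np.sqrt(var)
    return out


class TestOutlierStatistic:
    def test_studentized_residuals_match_leave_one_out_oracle(self):
        rng = np.random.default_rng(7)
        counts = zipf_counts(rng, 100, 8000)
        enriched = {k: max(1, v + int(rng.integers(-3, 8)))
                    for k, v in counts.items()}
        fit = fit_selection_regression(table(counts), table(enriched))
        recs = detect_outliers(fit, alpha=0.05)
        oracle = loo_studentized_oracle(fit.x, fit.y)
        got = np.array([r.studentized_residual for r in recs])
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_label_sign_agrees_with_residual_sign(self):
        rng = np.random.default_rng(8)
        counts = zipf_counts(rng, 60, 4000)
        enriched = dict(counts)
        enriched["CDR0030"] = counts["CDR0030"] * 200
        enriched["CDR0031"] = 0 if "CDR0031" not in counts else 1
        fit = fit_selection_regression(table(counts), table(enriched))
        for rec in detect_outliers(fit):
            if rec.label == "positive":
                assert rec.studentized_residual > 0
            elif rec.label == "negative":
                assert rec.studentized_residual < 0
            assert (rec.label != "none") == (rec.bonferroni_p < 0.05)

    def test_strong_outliers_swap_sign_when_pair_is_relabeled(self):
        rng = np.random.default_rng(9)
        counts = zipf_counts(rng, 120, 6000)
        enriched = dict(counts)
        enriched["CDR0050"] = max(1, counts.get("CDR0050", 1)) * 150
        fwd = detect_outliers(fit_selection_regression(table(counts, "A"),
                                                       table(enriched, "B")))
        rev = detect_outliers(fit_selection_regression(table(enriched, "B"),
                                                       table(counts, "A")))
        fwd_labels = {r.cdr3: r.label for r in fwd}
        rev_labels = {r.cdr3: r.label for r in rev}
        assert fwd_labels["CDR0050"] == "positive"
        assert rev_labels["CDR0050"] == "negative"

    def test_minimum_point_count_enforced(self):
        fit = fit_selection_regression(table({"A": 1, "B": 2, "C": 9}),
                                       table({"A": 1, "B": 2, "C": 9}))
        with pytest.raises(ValueError, match="points"):
            detect_outliers(fit)


def enr(cdr3, base, enriched, label):
    return EnrichmentRecord(cdr3=cdr3, baseline_count=base,
                            enriched_count=enriched, x=0.0, y=0.0,
                            studentized_residual=0.0,
                            bonferroni_p=0.001 if label != "none" else 1.0,
                            label=label)


class TestPolyreactivity:
    def base_results(self):
        # shared baseline: P=50, Q=30, R=20 (total 100)
        results = {}
        for lib, p_label, p_count in [("MBP", "positive", 400),
                                      ("MOG", "positive", 300),
                                      ("LMP1", "positive", 500),
                                      ("LMP1_MBP", "positive", 450)]:
            results[lib] = [enr("P", 50, p_count, p_label),
                            enr("Q", 30, 20, "none"),
                            enr("R", 20, 10, "none")]
        return results

    def test_cdr3_increased_in_all_four_is_polyreactive(self):
        df = polyreactivity_flags(self.base_results())
        row = df.set_index("cdr3").loc["P"]
        assert row["n_positive"] == 4 and bool(row["polyreactive"])

    def test_cdr3_positive_only_in_mog_records_subset(self):
        results = self.base_results()
        for lib in ("MBP", "LMP1", "LMP1_MBP"):
            # P at 20/50 = 0.4 of reads, below its 0.5 baseline share
            results[lib] = [enr("P", 50, 20, "none"), enr("Q", 30, 20, "none"),
                            enr("R", 20, 10, "none")]
        df = polyreactivity_flags(
            results, cross_reactive_subset=("MBP", "LMP1", "LMP1_MBP"))
        row = df.set_index("cdr3").loc["P"]
        assert row["positive_in"] == "MOG"
        assert not bool(row["polyreactive"])
        assert not bool(row["cross_reactive_candidate"])

    def test_cross_reactive_pattern_detected(self):
        results = self.base_results()
        results["MOG"] = [enr("P", 50, 30, "none"), enr("Q", 30, 40, "none"),
                          enr("R", 20, 30, "none")]
        df = polyreactivity_flags(
            results, cross_reactive_subset=("MBP", "LMP1", "LMP1_MBP"))
        row = df.set_index("cdr3").loc["P"]
        assert bool(row["cross_reactive_candidate"])
        assert not bool(row["polyreactive"])  # not increased in MOG

    def test_inconsistent_baselines_rejected(self):
        results = self.base_results()
        results["MOG"][0] = enr("P", 99, 300, "positive")
        with pytest.raises(ValueError, match="inconsistent"):
            polyreactivity_flags(results)

    def test_needs_at_least_two_sublibraries(self):
        with pytest.raises(ValueError, match=">= 2"):
            polyreactivity_flags({"MBP": [enr("P", 5, 9, "none")]})

    def test_planted_sharing_structure_recovered(self, germline):
        rep = simulate_repertoire(germline, 300, rng_seed=41, chain="heavy")
        ids = [c.clone_id for c in rep.clones if c.productive]
        shared, only_a = ids[40], ids[60]
        assign_fitness(rep, "AG_A", clone_ids=[shared, only_a], value=25.0)
        assign_fitness(rep, "AG_B", clone_ids=[shared], value=25.0)
        rng = np.random.default_rng(42)
        base_counts = rep.truth_cdr3_counts(rng.multinomial(8000, rep.frequencies))
        results = {}
        for ag in ("AG_A", "AG_B"):
            sel = apply_selection(rep, ag, 2)
            counts = sel.truth_cdr3_counts(rng.multinomial(8000, sel.frequencies))
            fit = fit_selection_regression(table(base_counts, "MS"),
                                           table(counts, ag))
            results[ag] = detect_outliers(fit)
        df = polyreactivity_flags(results).set_index("cdr3")
        shared_cdr3 = rep.by_id(shared).cdr3_aa
        only_a_cdr3 = rep.by_id(only_a).cdr3_aa
        assert df.loc[shared_cdr3, "n_positive"] == 2
        assert df.loc[shared_cdr3, "polyreactive"]
        assert df.loc[only_a_cdr3, "positive_in"] == "AG_A"
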