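import numpy as np
import pytest
from scipy import stats

from repsel.simulate import (apply_selection, assign_fitness, emit_reads,
                             revcomp, simulate_repertoire)

from conftest import oracle_translate


class TestSimulateRepertoire:
    def test_degenerate_parameters_concatenate_segments(self, germline):
        # zero trimming and zero insertion on a light chain (V–J, junction
        # already a codon multiple) must give the exact V+J concatenation
        rep = simulate_repertoire(germline, 1, rng_seed=0, chain="light",
                                  trim_mean=0.0, max_n_insert=0,
                                  productive_fraction=1.0, shm_rate=0.0)
        clone = rep.clones[0]
        v = germline.get(clone.v_name)
        j = germline.get(clone.j_name)
        assert clone.full_nt == v.nt_seq + j.nt_seq

    def test_abundance_law_is_monotone(self, germline):
        rep = simulate_repertoire(germline, 500, rng_seed=4, chain="heavy")
        assert rep.frequencies[0] > rep.frequencies[49]
        assert np.all(np.diff(rep.frequencies) <= 0)

    def test_frequencies_sum_to_one(self, heavy_repertoire):
        assert abs(heavy_repertoire.frequencies.sum() - 1.0) < 1e-9

    def test_productive_junctions_are_codon_multiples(self, heavy_repertoire):
        for clone in heavy_repertoire.clones:
            if clone.productive:
                assert len(clone.junction_nt) % 3 == 0

    def test_truth_cdr3_matches_junction_retranslation(self, heavy_repertoire,
                                                       light_repertoire):
        # independent oracle: re-translate the recorded junction with a codon
        # table built in the test suite
        for rep in (heavy_repertoire, light_repertoire):
            for clone in rep.clones:
                if not clone.productive:
                    continue
                aa = oracle_translate(clone.junction_nt)
                assert aa[0] == "C" and aa[-1] in "FW"
                assert "*" not in aa
                assert clone.cdr3_aa == aa[1:-1]

    def test_junction_sits_at_v_anchor(self, germline, heavy_repertoire):
        for clone in heavy_repertoire.clones:
            anchor = germline.get(clone.v_name).anchor_pos
            assert clone.full_nt[anchor:].startswith(clone.junction_nt)

    def test_unproductive_fraction_controlled(self, germline):
        rep = simulate_repertoire(germline, 400, rng_seed=9, chain="heavy",
                                  productive_fraction=0.5)
        frac = np.mean([c.productive for c in rep.clones])
        assert 0.35 < frac < 0.65

    def test_bad_arguments_rejected(self, germline):
        with pytest.raises(ValueError):
            simulate_repertoire(germline, 0)
        with pytest.raises(ValueError):
            simulate_repertoire(germline, 5, chain="kappa")


class TestApplySelection:
    def test_unit_fitness_is_identity(self, heavy_repertoire):
        assign_fitness(heavy_repertoire, "AG", value=1.0)
        sel = apply_selection(heavy_repertoire, "AG", 2)
        np.testing.assert_allclose(sel.frequencies,
                                   heavy_repertoire.frequencies)

    def test_zero_rounds_is_identity(self, heavy_repertoire):
        assign_fitness(heavy_repertoire, "AG",
                       clone_ids=[heavy_repertoire.clones[5].clone_id],
                       value=50.0)
        sel = apply_selection(heavy_repertoire, "AG", 0)
        np.testing.assert_allclose(sel.frequencies,
                                   heavy_repertoire.frequencies)

    def test_two_clone_closed_form(self, germline):
        rep = simulate_repertoire(germline, 2, rng_seed=1, chain="heavy",
                                  zipf_exponent=0.0)  # equal frequencies
        rep.clones[0].fitness["AG"] = 4.0
        rep.clones[1].fitness["AG"] = 1.0
        sel = apply_selection(rep, "AG", 1)
        np.testing.assert_allclose(sel.frequencies, [0.8, 0.2])

    def test_planted_clone_rank_strictly_improves(self, germline):
        rep = simulate_repertoire(germline, 500, rng_seed=6, chain="heavy")
        target = rep.clones[300].clone_id
        assign_fitness(rep, "AG", clone_ids=[target], value=20.0)
        sel = apply_selection(rep, "AG", 2)
        # independent recomputation of the closed form
        w = np.array([c.fitness_for("AG") for c in rep.clones]) ** 2
        expected = rep.frequencies * w
        expected /= expected.sum()
        np.testing.assert_allclose(sel.frequencies, expected, atol=1e-12)
        rank_before = (rep.frequencies > rep.frequencies[300]).sum()
        rank_after = (sel.frequencies > sel.frequencies[300]).sum()
        assert rank_after < rank_before
        assert abs(sel.frequencies.sum() - 1.0) < 1e-9

    def test_extinct_library_raises(self, germline):
        rep = simulate_repertoire(germline, 3, rng_seed=2, chain="heavy")
        for c in rep.clones:
            c.fitness["AG"] = 0.0
        with pytest.raises(ValueError, match="extinguished"):
            apply_selection(rep, "AG", 1)


class TestEmitReads:
    def test_error_free_mates_tile_the_amplicon(self, heavy_repertoire):
        batch = emit_reads(heavy_repertoire, 300, error_rate=0.0, rng_seed=3)
        truth = {c.clone_id: c.full_nt for c in heavy_repertoire.clones}
        for pair in batch.pairs:
            full = truth[pair.clone_id]
            assert pair.seq1 == full[:250]
            assert revcomp(pair.seq2) == full[-250:]

    def test_multinomial_sampling_matches_frequencies(self, heavy_repertoire):
        n = 50_000
        batch = emit_reads(heavy_repertoire, n, error_rate=0.0, rng_seed=8)
        expected = n * heavy_repertoire.frequencies
        keep = expected >= 5
        observed = batch.clone_read_counts[keep].astype(float)
        exp = expected[keep]
        # fold the small-expectation tail into one bin
        observed = np.append(observed, n - observed.sum())
        exp = np.append(exp, n - exp.sum())
        _, p = stats.chisquare(observed, exp)
        assert p > 0.001

    def test_same_seed_identical_reads(self, heavy_repertoire):
        a = emit_reads(heavy_repertoire, 200, error_rate=0.01, rng_seed=5)
        b = emit_reads(heavy_repertoire, 200, error_rate=0.01, rng_seed=5)
        assert [(p.read_id, p.seq1, p.qual1, p.seq2, p.qual2)
                for p in a.pairs] == \
               [(p.read_id, p.seq1, p.qual1, p.seq2, p.qual2)
                for p in b.pairs]

    def test_error_rate_and_read_len_validated(self, heavy_repertoire):
        with pytest.raises(ValueError, match="error_rate"):
            emit_reads(heavy_repertoire, 10, error_rate=0.3)
        with pytest.raises(ValueError, match="overlap"):
            emit_reads(heavy_repertoire, 10, read_len=150)

    def test_error_rate_perturbs_reads(self, heavy_repertoire):
        noisy = emit_reads(heavy_repertoire, 500, error_rate=0.05, rng_seed=7)
        truth = {c.clone_id: c.full_nt for c in heavy_repertoire.clones}
        mismatched = sum(p.seq1 != truth[p.clone_id][:250] for p in noisy.pairs)
        assert mismatched > 450  # P(error-free mate) ~ 3e-6 at 5% per base
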