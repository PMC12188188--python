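"""Log-odds scanning, enrichment, co-occurrence and grouped ISM profiles."""

import itertools

import numpy as np
import pytest

from camformer.interpret import ISMResult
from camformer.motifs import (MotifHit, PWM, cooccurrence_expression,
                              enrichment, feature_correlations,
                              grouped_ism_profile, read_meme, scan,
                              scan_library, write_meme)
from camformer.simulate import reverse_complement


def random_pwm(rng, name="M", w=6):
    p = rng.random((4, w)) + 0.05
    return PWM(name, p / p.sum(axis=0, keepdims=True))


class TestScanner:
    def test_scores_match_brute_force_on_all_hexamers(self, rng):
        """Every 4^6 hexamer scored by the scanner equals the explicit
        log-odds sum computed independently from the matrix."""
        pwm = random_pwm(rng)
        lo = pwm.log_odds()
        for bases in itertools.product("ACGT", repeat=6):
            seq = "".join(bases)
            hits = {(h.start, h.strand): h.score
                    for h in scan(seq, pwm, threshold=-1e9)}
            expected = sum(lo["ACGT".index(b), j] for j, b in enumerate(seq))
            assert hits[(1, "+")] == pytest.approx(expected, abs=1e-9)

    def test_consensus_is_maximal_plus_strand_hit(self, rng):
        pwm = random_pwm(rng, w=8)
        seq = "A" * 29 + pwm.consensus + "A" * (110 - 29 - 8)
        hits = [h for h in scan(seq, pwm, threshold=pwm.max_score() - 1e-9)
                if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].start == 30
        assert hits[0].score == pytest.approx(pwm.max_score())

    def test_gc_motif_absent_from_at_sequence(self):
        probs = np.zeros((4, 4))
        probs[1] = probs[2] = 0.5     # C and G only
        pwm = PWM("GC", probs)
        assert scan("A" * 50, pwm, threshold=0.0) == []

    def test_palindrome_hits_both_strands_equally(self):
        # consensus GAATTC (EcoRI site) is its own reverse complement
        pwm = PWM("PAL", np.array([
            [.1, .7, .7, .1, .1, .1],
            [.1, .1, .1, .1, .1, .7],
            [.7, .1, .1, .1, .1, .1],
            [.1, .1, .1, .7, .7, .1]]))
        seq = "CCCC" + "GAATTC" + "CCCC"
        hits = scan(seq, pwm, threshold=5.0)
        assert {h.strand for h in hits} == {"+", "-"}
        plus = next(h for h in hits if h.strand == "+")
        minus = next(h for h in hits if h.strand == "-")
        assert plus.start == minus.start == 5
        assert plus.score == pytest.approx(minus.score)

    def test_strand_consistency_under_reverse_complement(self, rng):
        """Scanning the reverse complement swaps strands and mirrors starts
        with identical scores."""
        pwm = random_pwm(rng, w=5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        fwd = scan(seq, pwm, threshold=-1e9)
        rev = scan(reverse_complement(seq), pwm, threshold=-1e9)
        L, w = len(seq), pwm.width
        mapped = sorted((L - (h.start + w - 1) + 1,
                         "+" if h.strand == "-" else "-", round(h.score, 9))
                        for h in rev)
        assert mapped == sorted((h.start, h.strand, round(h.score, 9))
                                for h in fwd)

    def test_n_contributes_zero_information(self, rng):
        pwm = random_pwm(rng, w=4)
        hits = scan("NNNN", pwm, threshold=-1e9)
        for h in hits:
            assert h.score == pytest.approx(0.0)

    def test_motif_wider_than_sequence_rejected(self, rng):
        with pytest.raises(ValueError, match="width"):
            scan("ACG", random_pwm(rng, w=6))

    def test_meme_round_trip(self, tmp_path, rng):
        pwms = [random_pwm(rng, "alpha", 5), random_pwm(rng, "beta", 7)]
        path = tmp_path / "motifs.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert [p.name for p in back] == ["alpha", "beta"]
        for a, b in zip(pwms, back):
            np.testing.assert_allclose(a.probs, b.probs, atol=1e-5)


class TestEnrichment:
    @staticmethod
    def _library(rng, n, planted_frac_high, consensus="TGACTCAT"):
        seqs, expr = [], []
        for i in range(n):
            seq = list("".join("ACGT"[j] for j in rng.integers(0, 4, 110)))
            high = i < n // 2
            expr.append(2.0 + rng.normal(0, .2) if high
                        else rng.normal(0, .2))
            if high and rng.random() < planted_frac_high:
                s = int(rng.integers(18, 91))
                seq[s - 1:s + 7] = consensus
            seqs.append("".join(seq))
        return seqs, expr

    def test_planted_motif_enriched_in_top_quantile(self, rng):
        seqs, expr = self._library(rng, 1000, 0.8)
        from camformer.simulate import motif_from_consensus
        pwm = PWM("PLANT",
                  motif_from_consensus("PLANT", "TGACTCAT", 0.0,
                                       consensus_prob=0.97).pwm)
        df = enrichment(seqs, expr, [pwm], quantiles=10, threshold=8.0)
        row = df.iloc[0]
        assert row["odds_ratio"] > 1
        assert row["p_adj"] < 0.05

    def test_null_motifs_rarely_significant(self, rng):
        seqs = ["".join("ACGT"[j] for j in rng.integers(0, 4, 110))
                for _ in range(300)]
        expr = rng.normal(size=300)
        pwms = [random_pwm(rng, f"null{i}", 8) for i in range(60)]
        df = enrichment(seqs, expr, pwms, quantiles=5, threshold=6.0)
        assert (df["p_adj"] < 0.05).mean() <= 0.1

    def test_constant_expression_rejected(self, rng):
        seqs = ["A" * 110] * 20
        with pytest.raises(ValueError, match="quantile"):
            enrichment(seqs, [1.0] * 20, [random_pwm(rng)], quantiles=4)


def hit(seq_id, motif, start=20, strand="+", score=5.0, width=8):
    return MotifHit(sequence_id=seq_id, motif=motif, start=start,
                    strand=strand, score=score, width=width)


class TestCooccurrence:
    def test_constant_predictions(self):
        hits = [hit(0, "A"), hit(0, "B", 40), hit(1, "A"), hit(1, "B", 50)]
        M, D = cooccurrence_expression([3.0, 3.0], hits, min_n=1)
        assert np.all(M.values == 3.0)
        assert np.all(D.values == 0.0)

    def test_additive_construction_recovers_constants(self):
        """With predictions built as baseline + per-motif constants, the
        difference matrix equals the column motif's constant exactly."""
        consts = {"A": 1.0, "B": -2.0, "C": 0.5}
        combos = [{"A"}, {"B"}, {"C"}, {"A", "B"}, {"A", "C"}, {"B", "C"}]
        hits, preds = [], {}
        for i, present in enumerate(combos):
            preds[i] = 10.0 + sum(consts[m] for m in present)
            for m in present:
                hits.append(hit(i, m))
        M, D = cooccurrence_expression(preds, hits, min_n=1)
        # the diagonal mixes combos, so compare pair cells directly
        for a in consts:
            for b in consts:
                if a == b:
                    continue
                assert M.loc[a, b] == pytest.approx(
                    10.0 + consts[a] + consts[b])

    def test_low_support_cells_flagged_empty(self):
        hits = [hit(0, "A"), hit(1, "B")]
        M, _ = cooccurrence_expression([1.0, 2.0], hits, min_n=1)
        assert np.isnan(M.loc["A", "B"])      # no co-occurrence support

    def test_partner_dependent_repressor(self):
        """A motif with no effect of its own but a strong negative
        interaction shows up in the difference matrix only with its
        partner."""
        from camformer.simulate import (InteractionSpec, LibrarySpec,
                                        generate_library,
                                        motif_from_consensus)
        spec = LibrarySpec(
            n=4000, seed=13, baseline=1.0, gc_coeff=0.0,
            motifs=[motif_from_consensus("P", "TGACTCAT", 1.0, 0.15),
                    motif_from_consensus("Q", "ACCGGTTA", 0.0, 0.3),
                    motif_from_consensus("R", "GGATCCGA", 1.0, 0.3)],
            interactions=[InteractionSpec("P", "Q", -3.0)],
            cells_per_promoter=1, cell_noise_sd=0.0, bin_range=(0, 18))
        sims = generate_library(spec)
        hits = []
        for i, s in enumerate(sims):
            for name, start, strand in s.planted:
                hits.append(hit(i, name, start, strand))
        preds = {i: s.latent for i, s in enumerate(sims)}
        _, D = cooccurrence_expression(preds, hits, min_n=10)
        assert D.loc["P", "Q"] < -1.5
        assert abs(D.loc["R", "Q"]) < 0.8


class TestFeatureCorrelations:
    def test_score_graded_effect(self, rng):
        hits, preds = [], {}
        for i in range(30):
            s = float(rng.random() * 10)
            hits.append(hit(i, "M", score=s))
            preds[i] = 2.0 * s + rng.normal(0, 0.1)
        df = feature_correlations(preds, hits)
        assert df.loc["M", "score"] > 0.9

    def test_constant_scores_are_missing(self):
        hits = [hit(i, "M", score=4.0) for i in range(10)]
        preds = {i: float(i) for i in range(10)}
        df = feature_correlations(preds, hits)
        assert np.isnan(df.loc["M", "score"])

    def test_count_effect_positive(self, rng):
        hits, preds = [], {}
        for i in range(30):
            k = int(rng.integers(1, 4))
            for j in range(k):
                hits.append(hit(i, "M", start=20 + 10 * j))
            preds[i] = float(k) + rng.normal(0, 0.1)
        df = feature_correlations(preds, hits)
        assert df.loc["M", "count"] > 0.8


class TestGroupedISM:
    @staticmethod
    def _res(importance):
        arr = np.zeros(80)
        arr[:] = importance
        return ISMResult(delta=np.zeros((80, 4)), importance=arr,
                         reference="A" * 110, region=(18, 97))

    def test_no_b_hits_gives_empty_overlap_group(self):
        results = {0: self._res(1.0)}
        prof = grouped_ism_profile(results, [hit(0, "A", start=30)], [])
        assert prof.n_overlap == 0
        assert prof.n_alone == 1
        assert np.all(np.isnan(prof.overlap_mean))

    def test_constant_model_zero_profiles(self):
        results = {0: self._res(0.0), 1: self._res(0.0)}
        prof = grouped_ism_profile(
            results, [hit(0, "A", start=30), hit(1, "A", start=40)],
            [hit(1, "B", start=42)])
        assert np.all(prof.alone_mean == 0)
        assert np.all(prof.overlap_mean == 0)

    def test_overlap_definition_shares_one_position(self):
        results = {0: self._res(1.0), 1: self._res(1.0)}
        a_hits = [hit(0, "A", start=30, width=8),
                  hit(1, "A", start=30, width=8)]
        # B at 37 overlaps [30..37]; B at 38 does not
        b_hits = [hit(0, "B", start=37, width=8),
                  hit(1, "B", start=38, width=8)]
        prof = grouped_ism_profile(results, a_hits, b_hits)
        assert prof.n_overlap == 1
        assert prof.n_alone == 1

    def test_minus_strand_windows_are_reversed(self):
        imp = np.arange(80.0)
        results = {0: ISMResult(delta=np.zeros((80, 4)), importance=imp,
                                reference="A" * 110, region=(18, 97))}
        prof = grouped_ism_profile(
            results, [hit(0, "A", start=20, strand="-", width=4)], [])
        np.testing.assert_array_equal(prof.alone_mean, [5, 4, 3, 2])

    def test_no_a_hits_rejected(self):
        with pytest.raises(ValueError, match="no hits"):
            grouped_ism_profile({}, [], [])
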