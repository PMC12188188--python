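"""Saturation mutagenesis, entropy ranking, Grad-CAM and embeddings."""

import numpy as np
import pytest

from camformer.data import EncodedBatch, PromoterRecord, encode_batch
from camformer.interpret import (activation_embedding, average_saliency,
                                 gc_content, gradcam, ism, ism_entropy,
                                 SaliencyMap, write_ism_table)
from camformer.zoo import ModelConfig, build_model


class LinearStub:
    """Purpose-built linear predictor: f(seq) = sum of per-(position, base)
    weights.  Under this model every ISM delta has a closed form."""

    def __init__(self, weights):
        self.weights = weights          # (110, 4)

    def forward(self, batch: EncodedBatch, batch_size: int = 0):
        x = batch.values[:, :, 0, :4]
        return (x * self.weights).sum(axis=(1, 2))


class ConstantStub:
    def forward(self, batch, batch_size=0):
        return np.zeros(len(batch))


def brute_force_linear_deltas(seq, weights, region=(18, 97)):
    """Enumerate all substitutions and score them from the string alone."""
    def score(s):
        return sum(weights[p, "ACGT".index(b)] for p, b in enumerate(s)
                   if b != "N")
    lo, hi = region
    delta = np.zeros((hi - lo + 1, 4))
    f0 = score(seq)
    count = 0
    for pos in range(lo, hi + 1):
        if seq[pos - 1] == "N":
            continue
        for b_i, base in enumerate("ACGT"):
            if base == seq[pos - 1]:
                continue
            var = seq[:pos - 1] + base + seq[pos:]
            delta[pos - lo, b_i] = score(var) - f0
            count += 1
    return delta, count


class TestISM:
    def test_linear_model_matches_brute_force_oracle(self, rng):
        weights = rng.standard_normal((110, 4))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 110))
        res = ism(LinearStub(weights), seq)
        expected, count = brute_force_linear_deltas(seq, weights)
        assert count == 240
        np.testing.assert_allclose(res.delta, expected, atol=1e-9)
        # importance = -(mean of the three non-reference deltas)
        for pos in range(18, 98):
            ref = "ACGT".index(seq[pos - 1])
            others = [expected[pos - 18, j] for j in range(4) if j != ref]
            assert res.importance[pos - 18] == pytest.approx(
                -np.mean(others), abs=1e-9)

    def test_exactly_240_variants_for_n_free_sequence(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 110))
        res = ism(ConstantStub(), seq)
        assert res.n_variants == 240
        assert res.delta.shape == (80, 4)

    def test_delta_zero_at_reference_base(self, rng):
        weights = rng.standard_normal((110, 4))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 110))
        res = ism(LinearStub(weights), seq)
        for pos in range(18, 98):
            assert res.delta[pos - 18, "ACGT".index(seq[pos - 1])] == 0.0

    def test_constant_model_gives_zero_attribution(self):
        res = ism(ConstantStub(), "ACGT" * 27 + "GA")
        assert np.all(res.delta == 0)
        assert np.all(res.importance == 0)

    def test_n_positions_skipped_and_counted(self):
        seq = "A" * 17 + "N" * 3 + "A" * 77 + "C" * 13
        res = ism(ConstantStub(), seq)
        assert res.skipped == [18, 19, 20]
        assert res.n_variants == 240 - 9

    def test_batching_invariance(self, micro_config, rng):
        model = build_model(micro_config, seed=2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 110))
        a = ism(model, seq, batch_size=1)
        b = ism(model, seq, batch_size=64)
        np.testing.assert_allclose(a.delta, b.delta, atol=1e-6)

    def test_unstandardized_sequence_rejected(self):
        with pytest.raises(ValueError, match="standardised"):
            ism(ConstantStub(), "ACGT")

    def test_table_output(self, tmp_path, rng):
        weights = rng.standard_normal((110, 4))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 110))
        res = ism(LinearStub(weights), seq)
        path = tmp_path / "ism.tsv"
        write_ism_table(res, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 81                  # header + 80 positions
        assert lines[0].startswith("position\tref")


class TestISMEntropy:
    def _res(self, importance):
        from camformer.interpret import ISMResult
        arr = np.asarray(importance, dtype=float)
        return ISMResult(delta=np.zeros((arr.size, 4)), importance=arr,
                         reference="A" * 110, region=(18, 18 + arr.size - 1))

    def test_uniform_importance_attains_log_n(self):
        assert ism_entropy(self._res(np.ones(80))) \
            == pytest.approx(np.log(80))

    def test_point_mass_is_zero(self):
        imp = np.zeros(80)
        imp[17] = 2.5
        assert ism_entropy(self._res(imp)) == 0.0

    def test_two_equal_peaks_give_log2(self):
        imp = np.zeros(80)
        imp[3] = 1.0
        imp[70] = -1.0    # absolute values are used
        assert ism_entropy(self._res(imp)) == pytest.approx(np.log(2))

    def test_all_zero_defined_as_max_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert ism_entropy(self._res(np.zeros(80))) \
                == pytest.approx(np.log(80))

    def test_configurable_log_base(self):
        imp = np.zeros(16)
        imp[:4] = 1.0
        assert ism_entropy(self._res(imp), base=2) == pytest.approx(2.0)


def single_filter_motif_model(motif="TGACTCAT"):
    """One conv filter matched to an 8-mer, fires only on a perfect match."""
    cfg = ModelConfig(conv_channels=[1], kernel_sizes=[9], residual_after=[],
                      penultimate_maxpool=False, fc_dims=[], dropout=[],
                      batchnorm=False, input_channels=4)
    model = build_model(cfg, seed=0)
    W = np.zeros((1, 4, 9), dtype=np.float32)
    for j, base in enumerate(motif):
        W[0, "ACGT".index(base), j] = 1.0
    model.net.convs[0].params["W"] = W
    model.net.convs[0].params["b"] = np.full(1, -7.5, dtype=np.float32)
    model.net.out.params["W"] = np.ones((110, 1), dtype=np.float32)
    model.net.out.params["b"] = np.zeros(1, dtype=np.float32)
    return model


class TestGradCAM:
    def test_zero_model_gives_zero_maps(self, micro_config):
        model = build_model(micro_config, seed=0)
        for lyr in model.net.layers():
            for k in lyr.params:
                lyr.params[k][:] = 0
        batch = encode_batch([PromoterRecord("ACGT" * 27 + "GA", 0.0)],
                             "onehot")
        maps = gradcam(model, batch, 1)
        assert np.all(maps[0].scores == 0)

    def test_maps_nonnegative_and_length_110_at_every_layer(self, rng,
                                                            micro_config):
        model = build_model(micro_config, seed=3)
        records = [PromoterRecord("".join(
            "ACGT"[i] for i in rng.integers(0, 4, 110)), 0.0)
            for _ in range(4)]
        batch = encode_batch(records, "onehot")
        for layer in (1, 2):
            maps = gradcam(model, batch, layer)
            assert len(maps) == 4
            for m in maps:
                assert m.scores.shape == (110,)
                assert np.all(m.scores >= 0)

    def test_determinism_in_eval_mode(self, micro_config, rng):
        model = build_model(micro_config, seed=4)
        records = [PromoterRecord("".join(
            "ACGT"[i] for i in rng.integers(0, 4, 110)), 0.0)
            for _ in range(3)]
        batch = encode_batch(records, "onehot")
        a = gradcam(model, batch, 2)
        b = gradcam(model, batch, 2)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.scores, mb.scores)

    def test_single_filter_model_localizes_planted_motif(self, rng):
        motif = "TGACTCAT"
        model = single_filter_motif_model(motif)
        hits = 0
        n = 25
        records, starts = [], []
        for _ in range(n):
            seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 110)))
            s = int(rng.integers(18, 91))        # 1-based start in insert
            seq[s - 1:s + 7] = motif
            records.append(PromoterRecord("".join(seq), 0.0))
            starts.append(s)
        maps = gradcam(model, encode_batch(records, "onehot"), 1)
        for m, s in zip(maps, starts):
            if abs(int(np.argmax(m.scores)) + 1 - s) <= 4:
                hits += 1
        assert hits >= 0.9 * n


class TestSaliencyAggregation:
    def test_single_map_identity(self):
        m = SaliencyMap(scores=np.arange(110.0), layer=1, sequence_id=0)
        np.testing.assert_array_equal(average_saliency([m]), m.scores)

    def test_two_maps_average(self):
        a = SaliencyMap(np.zeros(110), 1, 0)
        b = SaliencyMap(np.ones(110), 1, 1)
        np.testing.assert_array_equal(average_saliency([a, b]),
                                      np.full(110, 0.5))

    def test_mixed_layers_rejected(self):
        a = SaliencyMap(np.zeros(110), 1, 0)
        b = SaliencyMap(np.zeros(110), 2, 0)
        with pytest.raises(ValueError, match="mixed"):
            average_saliency([a, b])


class TestActivationEmbedding:
    def test_dimension_is_product_of_layer_shape(self, micro_config, rng):
        model = build_model(micro_config, seed=5)
        records = [PromoterRecord("".join(
            "ACGT"[i] for i in rng.integers(0, 4, 110)), 0.0)
            for _ in range(3)]
        batch = encode_batch(records, "onehot")
        emb = activation_embedding(model, batch, 2)
        assert emb.shape == (3, 110 * 1 * 8)

    def test_identical_sequences_identical_rows(self, micro_config):
        model = build_model(micro_config, seed=5)
        records = [PromoterRecord("ACGT" * 27 + "GA", 0.0)] * 2
        emb = activation_embedding(model, encode_batch(records, "onehot"), 1)
        np.testing.assert_array_equal(emb[0], emb[1])


class TestGCContent:
    def test_extremes_and_count(self):
        assert gc_content("GCGC") == 1.0
        assert gc_content("ATAT") == 0.0
        assert gc_content("GATTACA") == pytest.approx(2 / 7)

    def test_region_restriction(self):
        assert gc_content("AAGG", region=(3, 4)) == 1.0

    def test_n_excluded_from_denominator(self):
        assert gc_content("GCNN") == 1.0

    def test_all_n_region_rejected(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")
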