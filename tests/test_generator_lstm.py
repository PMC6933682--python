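import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aptagen.generator_lstm import (
    EpochRecord,
    GeneratorModel,
    TrainConfig,
    TrainingTrace,
    generate_pool,
    iu_ratio,
    sample_sequence,
    select_checkpoint,
    sequence_loss,
    softmax,
    train,
)
from aptagen.sequence_io import Alphabet, Sequence, build_streams, encode_one_hot

LN4 = float(np.log(4.0))


class TestSoftmax:
    def test_uniform_on_zeros(self):
        np.testing.assert_allclose(softmax(np.zeros(4)), np.full(4, 0.25), atol=1e-12)

    def test_log_inputs_give_normalized_weights(self):
        np.testing.assert_allclose(
            softmax(np.log([1.0, 2.0, 3.0, 4.0])), [0.1, 0.2, 0.3, 0.4], atol=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=4),
        st.floats(-100, 100),
    )
    def test_shift_invariance_and_normalization(self, z, c):
        z = np.array(z)
        p = softmax(z)
        assert p.min() > 0 and abs(p.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(softmax(z + c), p, atol=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([0.0, np.inf, 0.0, 0.0]))


class _FixedLogitsModel:
    """Stub emitting a preset logit sequence, for hand-checkable losses."""

    def __init__(self, logit_rows):
        self.logit_rows = [np.asarray(r, dtype=float).reshape(1, 4) for r in logit_rows]
        self.t = 0

    def zero_state(self, batch):
        self.t = 0
        return None

    def step(self, x, state):
        z = self.logit_rows[self.t]
        self.t += 1
        return z, state


class TestSequenceLoss:
    def _xs(self, residues):
        return encode_one_hot(Sequence("s", residues))

    def test_untrained_model_is_exactly_ln4(self, tiny_model):
        # zero output projection -> uniform prediction -> -ln(1/4)
        xs = self._xs("ACGT")
        assert sequence_loss(tiny_model, xs, [2, 3, 4, 1]) == pytest.approx(LN4, abs=1e-12)

    def test_perfect_predictor_loss_zero(self):
        model = _FixedLogitsModel([[1e3, 0, 0, 0], [0, 1e3, 0, 0]])
        assert sequence_loss(model, self._xs("AC"), [1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_two_step_hand_computation(self):
        z1, z2 = [0.1, 0.2, 0.3, 0.4], [1.0, 0.0, -1.0, 0.5]
        model = _FixedLogitsModel([z1, z2])
        # independent arithmetic: mean of -ln softmax_y over the two steps
        def nll(z, y):
            z = np.array(z)
            return -(z[y - 1] - np.log(np.exp(z).sum()))
        expected = (nll(z1, 2) + nll(z2, 1)) / 2.0
        got = sequence_loss(model, self._xs("AC"), [2, 1])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            sequence_loss(tiny_model, self._xs("AC"), [1])


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Central finite differences vs BPTT on a hidden-size-8 model."""
        model = GeneratorModel(layers=2, hidden_size=8, seed=3)
        rng = np.random.default_rng(0)
        model.params["Wy"] = rng.normal(0, 0.1, model.params["Wy"].shape)
        model.params["by"] = rng.normal(0, 0.1, 4)
        X = rng.integers(0, 4, (2, 3))
        Y = rng.integers(0, 4, (2, 3))
        _, grads = model.loss_and_grads(X, Y)
        h = 1e-5
        for k, p in model.params.items():
            num = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = p[ix]
                p[ix] = orig + h
                lp = model.loss_and_grads(X, Y)[0]
                p[ix] = orig - h
                lm = model.loss_and_grads(X, Y)[0]
                p[ix] = orig
                num[ix] = (lp - lm) / (2 * h)
            rel = np.linalg.norm(num - grads[k]) / max(np.linalg.norm(num), 1e-12)
            assert rel < 1e-4, f"gradient mismatch for {k}: rel={rel}"


def _chunks_from(seqs, batch_size=4, seq_len=20):
    return build_streams(seqs, batch_size=batch_size, seq_len=seq_len, val_frac=0.05)


class TestTraining:
    def test_one_record_per_epoch_and_determinism(self, motif_training_set):
        chunks = _chunks_from(motif_training_set[:200])
        losses = []
        for _ in range(2):
            model = GeneratorModel(layers=2, hidden_size=24, seed=9)
            trace = train(model, chunks, epochs=3, seed=11)
            assert [r.epoch for r in trace.records] == [1, 2, 3]
            losses.append([(r.train_loss, r.val_loss) for r in trace.records])
        assert losses[0] == losses[1]

    def test_checkpoints_reproduce_their_validation_loss(self, motif_training_set):
        chunks = _chunks_from(motif_training_set[:200])
        model = GeneratorModel(layers=2, hidden_size=24, seed=9)
        trace = train(model, chunks, epochs=2, seed=11)
        for rec in trace.records:
            probe = GeneratorModel(layers=2, hidden_size=24, seed=0)
            probe.set_params(rec.params)
            revals = [probe.chunk_loss(X, Y) for X, Y in chunks.val_chunks]
            assert float(np.mean(revals)) == pytest.approx(rec.val_loss, abs=1e-12)

    def test_motif_training_beats_uniform_baseline(self, motif_training_set):
        # a planted motif lowers next-character entropy below ln 4
        chunks = _chunks_from(motif_training_set)
        model = GeneratorModel(layers=2, hidden_size=32, seed=2)
        trace = train(model, chunks, epochs=8, seed=4)
        assert min(r.val_loss for r in trace.records) < LN4 - 0.02

    def test_divergence_reports_epoch(self, motif_training_set):
        chunks = _chunks_from(motif_training_set[:100])
        model = GeneratorModel(layers=1, hidden_size=8, seed=0)
        cfg = TrainConfig(learning_rate=1e8, clip_norm=1e12)
        with pytest.raises(RuntimeError, match="epoch"):
            train(model, chunks, epochs=50, config=cfg, seed=1)

    def test_iu_probe_recorded_when_enabled(self, motif_training_set):
        chunks = _chunks_from(motif_training_set[:100])
        model = GeneratorModel(layers=1, hidden_size=8, seed=0)
        cfg = TrainConfig(iu_probe_size=50)
        trace = train(model, chunks, epochs=1, config=cfg, train_seqs=motif_training_set[:100], seed=1)
        assert 0.0 <= trace.records[0].iu_ratio <= 1.0


class TestSelectCheckpoint:
    def _trace(self, val_losses):
        model = GeneratorModel(layers=1, hidden_size=4, seed=0)
        records = [
            EpochRecord(
                epoch=i + 1,
                train_loss=v,
                val_loss=v,
                iu_ratio=float("nan"),
                params={k: p + i for k, p in model.copy_params().items()},
            )
            for i, v in enumerate(val_losses)
        ]
        return TrainingTrace(records, TrainConfig(), model), model

    def test_minimum_validation_loss_wins(self):
        trace, model = self._trace([1.2, 0.95, 1.0])
        best = select_checkpoint(trace)
        np.testing.assert_array_equal(best.params["by"], model.params["by"] + 1)

    def test_singleton_and_tie_break_to_earliest(self):
        trace, model = self._trace([1.1])
        np.testing.assert_array_equal(select_checkpoint(trace).params["by"], model.params["by"])
        trace, model = self._trace([1.0, 1.0])
        np.testing.assert_array_equal(select_checkpoint(trace).params["by"], model.params["by"])

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            select_checkpoint(TrainingTrace([], TrainConfig(), GeneratorModel(1, 4)))


class TestSampling:
    def test_length_and_seeded_determinism(self, tiny_model):
        s1 = sample_sequence(tiny_model, 20, seed=7)
        s2 = sample_sequence(tiny_model, 20, seed=7)
        s3 = sample_sequence(tiny_model, 20, seed=8)
        assert len(s1) == 20 and s1.residues == s2.residues
        assert s1.residues != s3.residues  # astronomically unlikely to collide

    def test_pool_determinism_and_single_draw_consistency(self, tiny_model):
        p1 = generate_pool(tiny_model, 5, seed=3)
        p2 = generate_pool(tiny_model, 5, seed=3)
        assert [s.residues for s in p1] == [s.residues for s in p2]
        child = np.random.SeedSequence(3).spawn(1)[0]
        assert p1[0].residues == sample_sequence(tiny_model, 20, seed=child).residues

    def test_untrained_model_samples_uniformly(self, tiny_model):
        pool = generate_pool(tiny_model, 5000, seed=5)
        chars = "".join(s.residues for s in pool)
        freqs = np.array([chars.count(b) for b in "ACGT"]) / len(chars)
        np.testing.assert_allclose(freqs, 0.25, atol=0.01)

    def test_sampling_is_a_proper_multinomial_draw(self):
        from scipy import stats

        # zero LSTM output -> logits equal the output bias at every step,
        # so samples must follow softmax(by) exactly
        model = GeneratorModel(layers=1, hidden_size=4, seed=0)
        target = np.array([0.1, 0.2, 0.3, 0.4])
        model.params["by"] = np.log(target)
        pool = generate_pool(model, 3000, seed=11, length=10)
        chars = "".join(s.residues for s in pool)
        counts = np.array([chars.count(b) for b in "ACGT"])
        p = stats.chisquare(counts, f_exp=target * counts.sum()).pvalue
        assert p > 0.01

    def test_rna_alphabet_renders_u(self):
        model = GeneratorModel(layers=1, hidden_size=4, alphabet=Alphabet.RNA, seed=0)
        s = sample_sequence(model, 50, seed=1)
        assert set(s.residues) <= set("ACGU") and "T" not in s.residues

    def test_temperature_must_be_positive(self, tiny_model):
        with pytest.raises(ValueError):
            sample_sequence(tiny_model, 5, seed=0, temperature=0.0)


class TestCheckpointIO:
    def test_save_load_restores_bitwise_behavior(self, tmp_path, motif_training_set):
        chunks = _chunks_from(motif_training_set[:100])
        model = GeneratorModel(layers=2, hidden_size=12, seed=6)
        train(model, chunks, epochs=1, seed=2)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = GeneratorModel.load(path)
        for k in model.params:
            np.testing.assert_array_equal(model.params[k], loaded.params[k])
        assert (
            sample_sequence(model, 20, seed=1).residues
            == sample_sequence(loaded, 20, seed=1).residues
        )


class TestIURatio:
    def test_identity_disjoint_and_partial_overlap(self):
        assert iu_ratio({"AA", "CC"}, {"AA", "CC"}) == 1.0
        assert iu_ratio({"AA"}, {"CC"}) == 0.0
        assert iu_ratio({"s1", "s2"}, {"s2", "s3"}) == pytest.approx(1 / 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.sets(st.text(alphabet="ACGT", min_size=1, max_size=4), min_size=1, max_size=8),
        st.sets(st.text(alphabet="ACGT", min_size=1, max_size=4), min_size=1, max_size=8),
    )
    def test_symmetry_and_equality_iff_one(self, a, b):
        r = iu_ratio(a, b)
        assert r == iu_ratio(b, a)
        assert (r == 1.0) == (a == b)

    def test_duplicates_collapse_and_empty_rejected(self):
        assert iu_ratio(["AA", "AA"], ["AA"]) == 1.0
        with pytest.raises(ValueError):
            iu_ratio([], [])
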