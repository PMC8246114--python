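"""Schedule, multi-task sampling, beam search and training behavior."""

import itertools

import numpy as np
import pytest

from ert.model import (
    EncodedCorpus,
    Hypothesis,
    ModelConfig,
    MultiTaskMixture,
    TrainedModel,
    TrainingSchedule,
    beam_search_decode,
    build_network,
    decode_batch,
    noam_lr,
    sample_multitask_batches,
    train,
)
from ert.nn import Seq2SeqTransformer
from ert.tokenization import SmilesTokenizer, TextTokenizer, TokenizerPair


def make_tokenizers(n_tokens=10):
    smi = SmilesTokenizer({c: i for i, c in enumerate("CNOSPFIcno=#-+"[:n_tokens])})
    return TokenizerPair(smiles=smi, text=TextTokenizer())


def copy_corpus(n=300, lo=4, hi=9, seed=0, vocab_lo=5, vocab_hi=15):
    rng = np.random.default_rng(seed)
    seqs = [list(map(int, rng.integers(vocab_lo, vocab_hi, rng.integers(lo, hi))))
            for _ in range(n)]
    return EncodedCorpus("copy", seqs, [list(s) for s in seqs])


class TestNoamSchedule:
    def test_closed_form_at_peak(self):
        sched = TrainingSchedule(base_lr=4.0, warmup_steps=8000, max_steps=8000)
        expected = 4 * 384 ** -0.5 * 8000 ** -0.5
        assert noam_lr(8000, sched, 384) == pytest.approx(expected, rel=1e-12)

    def test_peak_at_warmup(self):
        sched = TrainingSchedule(base_lr=4.0, warmup_steps=100, max_steps=1000)
        peak = noam_lr(100, sched, 128)
        assert all(noam_lr(s, sched, 128) <= peak for s in range(1, 501))

    def test_linear_ramp_during_warmup(self):
        sched = TrainingSchedule(base_lr=4.0, warmup_steps=100, max_steps=1000)
        assert noam_lr(1, sched, 128) / noam_lr(2, sched, 128) == pytest.approx(0.5)

    def test_step_below_one_rejected(self):
        sched = TrainingSchedule(base_lr=4.0, warmup_steps=100, max_steps=1000)
        with pytest.raises(ValueError):
            noam_lr(0, sched, 128)

    def test_matches_closed_form_at_sampled_steps(self):
        sched = TrainingSchedule(base_lr=2.0, warmup_steps=4000, max_steps=200_000)
        rng = np.random.default_rng(1)
        for step in rng.integers(1, 200_000, 100):
            step = int(step)
            expected = 2.0 * 256 ** -0.5 * min(step ** -0.5, step * 4000 ** -1.5)
            assert noam_lr(step, sched, 256) == pytest.approx(expected, rel=1e-12)


class TestMultiTaskSampling:
    def test_one_to_nine_cycle_counts(self):
        mix = MultiTaskMixture([copy_corpus(40, seed=1), copy_corpus(40, seed=2)], [1, 9])
        mix.corpora[0].name, mix.corpora[1].name = "special", "general"
        names = [n for n, _ in sample_multitask_batches(mix, 100, seed=0, batch_tokens=64)]
        assert names.count("special") == 10
        for cycle_start in range(0, 100, 10):
            cycle = names[cycle_start : cycle_start + 10]
            assert cycle.count("special") == 1

    def test_equal_weights_alternate_strictly(self):
        a, b = copy_corpus(20, seed=1), copy_corpus(20, seed=2)
        a.name, b.name = "a", "b"
        names = [n for n, _ in sample_multitask_batches(
            MultiTaskMixture([a, b], [1, 1]), 10, seed=0, batch_tokens=64)]
        assert names == ["a", "b"] * 5

    def test_every_example_visited_before_repeats(self):
        corpus = copy_corpus(50, seed=3)
        corpus.name = "solo"
        mix = MultiTaskMixture([corpus], [1])
        seen: list[int] = []
        for _, idx in sample_multitask_batches(mix, 200, seed=0, batch_tokens=128):
            seen.extend(int(i) for i in idx)
            if len(seen) >= 100:
                break
        first_epoch = seen[:50]
        assert sorted(first_epoch) == list(range(50))

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            MultiTaskMixture([copy_corpus(5)], [0])


class _FixedLogitModel:
    """Toy decoder whose next-token distribution depends only on the prefix."""

    def __init__(self, vocab_logps, pad_id=0):
        self.vocab_logps = vocab_logps  # function prefix-tuple -> logp array
        self.pad_id = pad_id

    def encode_fwd(self, src, train=False, rng=None):
        return np.zeros((src.shape[0], src.shape[1], 1), dtype=np.float32), None

    def next_token_logprobs(self, ys, enc_out, src):
        out = np.stack([self.vocab_logps(tuple(int(t) for t in row[1:] if t != -1))
                        for row in ys])
        return out


def _toy_trained_model(vocab_logps):
    tok = make_tokenizers(3)

    class FakeConfig:
        max_len = 3

    net = _FixedLogitModel(vocab_logps)
    model = TrainedModel.__new__(TrainedModel)
    model.network = net
    model.tokenizers = tok
    model.config = FakeConfig()
    return model


class TestBeamSearch:
    def _logps(self):
        # vocabulary ids: 0 PAD, 1 BOS, 2 EOS, 5.. tokens; use {5, 6, EOS=2}
        rng = np.random.default_rng(42)
        table = {}

        def fn(prefix):
            if prefix not in table:
                logits = rng.normal(size=8).astype(np.float64)
                logits[[0, 1, 3, 4]] = -50.0  # only tokens 5, 6, 7 and EOS(2) live
                e = np.exp(logits - logits.max())
                table[prefix] = np.log(e / e.sum())
            return table[prefix]

        return fn

    def _brute_force(self, fn, max_len=3, eos=2, live=(2, 5, 6, 7)):
        best = []
        for L in range(0, max_len):
            for seq in itertools.product([5, 6, 7], repeat=L):
                # terminated sequences: logp of tokens + EOS
                lp = 0.0
                for i, t in enumerate(seq):
                    lp += fn(tuple(seq[:i]))[t]
                lp += fn(tuple(seq))[eos]
                best.append((lp, list(seq)))
        # hypotheses truncated at max_len (no EOS)
        for seq in itertools.product([5, 6, 7], repeat=max_len):
            lp = sum(fn(tuple(seq[:i]))[t] for i, t in enumerate(seq))
            best.append((lp, list(seq)))
        best.sort(key=lambda x: -x[0])
        return best

    def test_exhaustive_width_matches_brute_force(self):
        fn = self._logps()
        model = _toy_trained_model(fn)
        hyps = beam_search_decode(model, [5, 5], beam_width=64, n_best=4, max_len=3)
        expected = self._brute_force(fn)
        for h, (lp, seq) in zip(hyps, expected[:4]):
            assert h.ids == seq
            assert h.log_prob == pytest.approx(lp, rel=1e-6)

    def test_confidence_is_probability_product(self):
        h = Hypothesis(tokens=["C", "C"], ids=[5, 5],
                       log_prob=float(np.log(0.99) + np.log(0.99) + np.log(1.0)),
                       rank=1)
        assert h.confidence == pytest.approx(0.9801, abs=1e-6)

    def test_greedy_is_beam_width_one(self):
        fn = self._logps()
        model = _toy_trained_model(fn)
        greedy = beam_search_decode(model, [5], beam_width=1, n_best=1, max_len=3)[0]
        wide = beam_search_decode(model, [5], beam_width=64, n_best=8, max_len=3)
        # greedy follows locally best tokens; it must appear in the wide pool
        assert any(h.ids == greedy.ids for h in wide)

    def test_n_best_larger_than_width_rejected(self):
        model = _toy_trained_model(self._logps())
        with pytest.raises(ValueError):
            beam_search_decode(model, [5], beam_width=2, n_best=3)

    def test_hypotheses_sorted_by_log_prob(self):
        model = _toy_trained_model(self._logps())
        hyps = beam_search_decode(model, [5, 6], beam_width=16, n_best=5, max_len=3)
        lps = [h.log_prob for h in hyps]
        assert lps == sorted(lps, reverse=True)
        assert [h.rank for h in hyps] == [1, 2, 3, 4, 5]


class TestTraining:
    def test_copy_task_reaches_high_token_accuracy(self):
        """A 2-layer, 64-dim model masters an identity task within 500 steps."""
        tok = make_tokenizers()
        corpus = copy_corpus(300, seed=0)
        cfg = ModelConfig(layers=2, model_dim=64, heads=4, ff_dim=128, dropout=0.1)
        sched = TrainingSchedule(base_lr=1.0, warmup_steps=100, max_steps=500,
                                 batch_tokens=512, accum_count=1, seed=3,
                                 valid_interval=250, patience=10, valid_max_examples=64)
        model = train(cfg, sched, corpus, regime="single", valid=corpus, tokenizers=tok)
        src, tgt_in, tgt_out = _arrays(corpus, tok, range(64))
        _, _, acc = model.network.loss_and_grads(src, tgt_in, tgt_out, train=False)
        assert acc >= 0.99

    def test_loss_curve_trends_downward(self):
        tok = make_tokenizers()
        corpus = copy_corpus(200, seed=1)
        cfg = ModelConfig(layers=1, model_dim=32, heads=2, ff_dim=64, dropout=0.0)
        sched = TrainingSchedule(base_lr=1.0, warmup_steps=50, max_steps=200,
                                 batch_tokens=256, accum_count=1, seed=0,
                                 valid_interval=500)
        model = train(cfg, sched, corpus, regime="single", tokenizers=tok)
        first = np.mean(model.loss_curve[:20])
        last = np.mean(model.loss_curve[-20:])
        assert last < first

    def test_fixed_seed_reproduces_loss_curve(self):
        tok = make_tokenizers()
        corpus = copy_corpus(100, seed=2)
        cfg = ModelConfig(layers=1, model_dim=32, heads=2, ff_dim=64, dropout=0.1)
        sched = TrainingSchedule(base_lr=1.0, warmup_steps=20, max_steps=40,
                                 batch_tokens=256, accum_count=1, seed=9,
                                 valid_interval=500)
        a = train(cfg, sched, corpus, regime="single", tokenizers=tok)
        b = train(cfg, sched, corpus, regime="single", tokenizers=tok)
        assert a.loss_curve == b.loss_curve

    def test_stl_phase2_starts_below_cold_start(self):
        """Pretraining on a related corpus lowers the initial specialized loss."""
        tok = make_tokenizers()
        general = copy_corpus(300, seed=4)
        general.name = "general"
        specialized = copy_corpus(120, seed=5)
        specialized.name = "spec"
        cfg = ModelConfig(layers=1, model_dim=32, heads=2, ff_dim=64, dropout=0.0)
        sched = TrainingSchedule(base_lr=1.0, warmup_steps=50, max_steps=150,
                                 batch_tokens=256, accum_count=1, seed=0,
                                 valid_interval=500)
        pre = train(cfg, sched, general, regime="single", tokenizers=tok)
        cold = build_network(cfg, tok, seed=sched.seed)
        src, tgt_in, tgt_out = _arrays(specialized, tok, range(64))
        cold_loss, _, _ = cold.loss_and_grads(src, tgt_in, tgt_out, train=False)
        warm_loss, _, _ = pre.network.loss_and_grads(src, tgt_in, tgt_out, train=False)
        assert warm_loss < cold_loss

    def test_stl_regime_runs_both_phases(self):
        """Sequential transfer learning pretrains then fine-tunes."""
        tok = make_tokenizers()
        general = copy_corpus(100, seed=7)
        general.name = "general"
        specialized = copy_corpus(60, seed=8)
        specialized.name = "spec"
        cfg = ModelConfig(layers=1, model_dim=32, heads=2, ff_dim=64, dropout=0.0)
        sched = TrainingSchedule(base_lr=0.5, warmup_steps=20, max_steps=60,
                                 batch_tokens=256, accum_count=1, seed=1,
                                 valid_interval=500)
        model = train(cfg, sched, specialized, regime="stl", tokenizers=tok,
                      general=general)
        # loss curve covers both phases
        assert len(model.loss_curve) == 60
        with pytest.raises(ValueError, match="general"):
            train(cfg, sched, specialized, regime="stl", tokenizers=tok)

    def test_vocabulary_mismatch_rejected(self):
        tok = make_tokenizers(5)
        corpus = copy_corpus(20, vocab_lo=30, vocab_hi=40)
        cfg = ModelConfig(layers=1, model_dim=16, heads=2, ff_dim=32)
        sched = TrainingSchedule(base_lr=1.0, warmup_steps=5, max_steps=5,
                                 batch_tokens=64)
        with pytest.raises(ValueError, match="outside model vocabulary"):
            train(cfg, sched, corpus, regime="single", tokenizers=tok)


class TestCheckpointRoundtrip:
    def test_save_load_preserves_weights_and_tokenizers(self, tmp_path):
        tok = make_tokenizers()
        corpus = copy_corpus(50, seed=6)
        cfg = ModelConfig(layers=1, model_dim=32, heads=2, ff_dim=64)
        sched = TrainingSchedule(base_lr=1.0, warmup_steps=10, max_steps=10,
                                 batch_tokens=128, valid_interval=500)
        model = train(cfg, sched, corpus, regime="single", tokenizers=tok)
        model.save(tmp_path / "ckpt")
        back = TrainedModel.load(tmp_path / "ckpt")
        for k, v in model.network.params.items():
            np.testing.assert_array_equal(back.network.params[k], v)
        assert back.tokenizers.vocab_size == tok.vocab_size
        src = corpus.sources[:4]
        a = decode_batch(model, src, beam_width=2, n_best=1, max_len=12)
        b = decode_batch(back, src, beam_width=2, n_best=1, max_len=12)
        assert [h[0].ids for h in a] == [h[0].ids for h in b]


def _arrays(corpus, tok, idx):
    from ert.model import make_training_arrays

    return make_training_arrays(corpus, np.array(list(idx)), tok.pad_id,
                                tok.bos_id, tok.eos_id)


class TestModelConfigValidation:
    def test_dim_heads_divisibility(self):
        with pytest.raises(ValueError):
            ModelConfig(layers=2, model_dim=100, heads=8, ff_dim=64)

    def test_schedule_warmup_bounds(self):
        with pytest.raises(ValueError):
            TrainingSchedule(warmup_steps=0, max_steps=10)
        with pytest.raises(ValueError):
            TrainingSchedule(warmup_steps=100, max_steps=50)
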