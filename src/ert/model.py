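"""Training regimes and decoding for the reaction-product transformer.

Three regimes are supported, mirroring how general-chemistry and
enzymatic corpora are combined in practice:

* ``single``  — train on one corpus only;
* ``stl``     — sequential transfer learning: pretrain on the general
  corpus, then continue from those weights on the specialized corpus;
* ``mtl``     — multi-task transfer learning: one model trained on a
  weighted mixture, drawing a fixed number of batches per corpus in
  every sampling cycle (reference weighting: specialized 1 : general 9).

Learning rate follows the noam schedule
``base_lr * dim^-0.5 * min(step^-0.5, step * warmup^-1.5)`` — linear
warmup to a peak at ``warmup_steps``, then inverse-square-root decay.
Checkpoint selection uses exact-match validation accuracy with early
stopping.

Decoding is breadth-limited beam search; each hypothesis carries the sum
of its token log-probabilities and a confidence score defined as the
product of token probabilities, ``exp(log_prob)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .nn import Adam, Seq2SeqTransformer
from .tokenization import TokenizerPair

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Transformer architecture parameters.

    The reference configuration (4 layers, 384 dims, 8 heads, 2048 ff) is
    the published scale; :func:`desk_config` returns the small
    configuration used for CPU-scale experiments.
    """

    layers: int = 4
    model_dim: int = 384
    heads: int = 8
    ff_dim: int = 2048
    dropout: float = 0.1
    label_smoothing: float = 0.0
    shared_vocab_size: int | None = None
    max_len: int = 256

    def __post_init__(self) -> None:
        if self.model_dim % self.heads:
            raise ValueError("model_dim must be divisible by heads")
        if min(self.layers, self.model_dim, self.heads, self.ff_dim) < 1:
            raise ValueError("all dimensions must be >= 1")


def desk_config(**overrides) -> ModelConfig:
    """Small architecture for CPU-scale experiments."""
    cfg = dict(layers=2, model_dim=128, heads=4, ff_dim=512)
    cfg.update(overrides)
    return ModelConfig(**cfg)


@dataclass
class TrainingSchedule:
    """Optimization schedule (reference values follow the published run)."""

    base_lr: float = 4.0
    warmup_steps: int = 8000
    max_steps: int = 200_000
    batch_tokens: int = 6144
    accum_count: int = 4
    adam_betas: tuple[float, float] = (0.9, 0.998)
    seed: int = 42
    valid_interval: int = 200
    patience: int = 5
    valid_max_examples: int = 128

    def __post_init__(self) -> None:
        if self.warmup_steps < 1:
            raise ValueError("warmup_steps must be >= 1")
        if self.max_steps < self.warmup_steps:
            raise ValueError("max_steps must be >= warmup_steps")


def desk_schedule(**overrides) -> TrainingSchedule:
    """CPU-scale schedule: short warmup, ~1e-3 peak learning rate."""
    cfg = dict(base_lr=0.5, warmup_steps=300, max_steps=1000,
               batch_tokens=1536, accum_count=1)
    cfg.update(overrides)
    return TrainingSchedule(**cfg)


def noam_lr(step: int, schedule: TrainingSchedule, model_dim: int) -> float:
    """noam learning rate at ``step`` (1-based); peaks at ``warmup_steps``."""
    if step < 1:
        raise ValueError("step must be >= 1")
    w = schedule.warmup_steps
    return schedule.base_lr * model_dim ** -0.5 * min(step ** -0.5, step * w ** -1.5)


# ---------------------------------------------------------------------------
# data plumbing


@dataclass
class EncodedCorpus:
    """Tokenized parallel corpus: aligned source/target id sequences."""

    name: str
    sources: list[list[int]]
    targets: list[list[int]]

    def __post_init__(self) -> None:
        if len(self.sources) != len(self.targets):
            raise ValueError("source/target length mismatch")
        if not self.sources:
            raise ValueError(f"corpus {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sources)


def encode_corpus(corpus, tokenizers: TokenizerPair, mode: str = "full_sentence",
                  name: str | None = None, strict: bool = True) -> EncodedCorpus:
    """Encode a ReactionCorpus into id sequences for training/decoding."""
    sources, targets = [], []
    for rec in corpus:
        sources.append(tokenizers.encode_source(rec, mode=mode, strict=strict).ids)
        targets.append(tokenizers.encode_target(rec.products, strict=strict).ids)
    return EncodedCorpus(name=name or corpus.name, sources=sources, targets=targets)


@dataclass
class MultiTaskMixture:
    """Named corpora with integer batch-sampling weights.

    With weights ``(w1, ..., wk)`` every cycle of ``w1+...+wk`` batches
    draws exactly ``wi`` batches from corpus ``i``.
    """

    corpora: list[EncodedCorpus]
    weights: list[int]

    def __post_init__(self) -> None:
        if len(self.corpora) != len(self.weights):
            raise ValueError("weights must align with corpora")
        if any(w < 1 for w in self.weights):
            raise ValueError("all weights must be >= 1 (integers)")


def _make_batches(corpus: EncodedCorpus, batch_tokens: int, rng) -> list[np.ndarray]:
    """Padding-aware token-count batching for one epoch.

    Examples are shuffled, sorted by length with the shuffle as tiebreak
    (keeps batches length-homogeneous while varying composition between
    epochs), greedily chunked so padded source+target token counts stay
    near ``batch_tokens``, and the batch order is shuffled.
    """
    n = len(corpus)
    order = rng.permutation(n)
    lengths = np.array([len(corpus.sources[i]) + len(corpus.targets[i]) for i in order])
    order = order[np.argsort(lengths, kind="stable")]
    batches: list[np.ndarray] = []
    cur: list[int] = []
    max_s = max_t = 0
    for i in order:
        s, t = len(corpus.sources[i]), len(corpus.targets[i]) + 1  # +1 for BOS/EOS shift
        ms, mt = max(max_s, s), max(max_t, t)
        if cur and (ms + mt) * (len(cur) + 1) > batch_tokens:
            batches.append(np.array(cur))
            cur, ms, mt = [], s, t
        cur.append(int(i))
        max_s, max_t = ms, mt
    if cur:
        batches.append(np.array(cur))
    perm = rng.permutation(len(batches))
    return [batches[i] for i in perm]


def _epoch_batches(corpus: EncodedCorpus, batch_tokens: int, seed: int) -> Iterator[np.ndarray]:
    """Endless batch stream; reshuffles (new epoch) on wraparound."""
    epoch = 0
    while True:
        rng = np.random.default_rng((seed, epoch))
        yield from _make_batches(corpus, batch_tokens, rng)
        epoch += 1


def sample_multitask_batches(mixture: MultiTaskMixture, n_batches: int, seed: int,
                             batch_tokens: int = 1536) -> Iterator[tuple[str, np.ndarray]]:
    """Deterministic cyclic interleaving of per-corpus batch streams.

    Yields ``(corpus_name, example_indices)`` pairs. Per cycle of
    ``sum(weights)`` batches, corpus ``i`` contributes exactly
    ``weights[i]`` batches; within each corpus all examples are visited
    (seeded shuffle) before any repeats.
    """
    streams = [
        _epoch_batches(c, batch_tokens, seed + 1000 * k)
        for k, c in enumerate(mixture.corpora)
    ]
    schedule: list[int] = []
    for i, w in enumerate(mixture.weights):
        schedule.extend([i] * w)
    yielded = 0
    while yielded < n_batches:
        for i in schedule:
            if yielded >= n_batches:
                return
            yield mixture.corpora[i].name, next(streams[i])
            yielded += 1


def _pad_batch(seqs: Sequence[Sequence[int]], pad_id: int, extra: int = 0) -> np.ndarray:
    width = max(len(s) for s in seqs) + extra
    out = np.full((len(seqs), width), pad_id, dtype=np.int64)
    for r, s in enumerate(seqs):
        out[r, : len(s)] = s
    return out


def make_training_arrays(corpus: EncodedCorpus, idx: np.ndarray, pad_id: int,
                         bos_id: int, eos_id: int):
    """(src, tgt_in, tgt_out) arrays for one batch with BOS/EOS framing."""
    src = _pad_batch([corpus.sources[i] for i in idx], pad_id)
    tgts = [corpus.targets[i] for i in idx]
    tgt_in = _pad_batch([[bos_id] + list(t) for t in tgts], pad_id)
    tgt_out = _pad_batch([list(t) + [eos_id] for t in tgts], pad_id)
    return src, tgt_in, tgt_out


# ---------------------------------------------------------------------------
# trained model container


@dataclass
class TrainedModel:
    """A trained transformer bundled with its tokenizers and history."""

    network: Seq2SeqTransformer
    tokenizers: TokenizerPair
    config: ModelConfig
    loss_curve: list[float] = field(default_factory=list)
    val_curve: list[tuple[int, float]] = field(default_factory=list)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.savez(str(prefix) + ".weights.npz", **self.network.params)
        meta = {
            "config": asdict(self.config),
            "tokenizers": self.tokenizers.to_json(),
            "loss_curve": self.loss_curve,
            "val_curve": self.val_curve,
        }
        Path(str(prefix) + ".meta.json").write_text(json.dumps(meta), encoding="utf-8")

    @classmethod
    def load(cls, prefix: str | Path) -> "TrainedModel":
        meta = json.loads(Path(str(prefix) + ".meta.json").read_text(encoding="utf-8"))
        config = ModelConfig(**meta["config"])
        tokenizers = TokenizerPair.from_json(meta["tokenizers"])
        model = cls(
            network=build_network(config, tokenizers, seed=0),
            tokenizers=tokenizers,
            config=config,
            loss_curve=list(meta.get("loss_curve", [])),
            val_curve=[tuple(v) for v in meta.get("val_curve", [])],
        )
        with np.load(str(prefix) + ".weights.npz") as npz:
            model.network.params = {k: npz[k] for k in npz.files}
        return model


def build_network(config: ModelConfig, tokenizers: TokenizerPair, seed: int) -> Seq2SeqTransformer:
    vocab = config.shared_vocab_size or tokenizers.vocab_size
    if vocab < tokenizers.vocab_size:
        raise ValueError("model vocabulary smaller than tokenizer vocabulary")
    return Seq2SeqTransformer(
        vocab_size=vocab,
        dim=config.model_dim,
        ff_dim=config.ff_dim,
        heads=config.heads,
        n_enc=config.layers,
        n_dec=config.layers,
        dropout=config.dropout,
        pad_id=tokenizers.pad_id,
        max_len=config.max_len,
        rng=np.random.default_rng(seed),
    )


# ---------------------------------------------------------------------------
# training


def _greedy_decode_ids(network: Seq2SeqTransformer, sources: list[list[int]],
                       bos_id: int, eos_id: int, pad_id: int, max_len: int) -> list[list[int]]:
    """Batched greedy decoding (used for validation accuracy)."""
    src = _pad_batch(sources, pad_id)
    enc_out, _ = network.encode_fwd(src, train=False)
    B = src.shape[0]
    ys = np.full((B, 1), bos_id, dtype=np.int64)
    done = np.zeros(B, dtype=bool)
    for _ in range(max_len):
        logp = network.next_token_logprobs(ys, enc_out, src)
        nxt = logp.argmax(axis=-1)
        nxt[done] = pad_id
        ys = np.concatenate([ys, nxt[:, None]], axis=1)
        done |= nxt == eos_id
        if done.all():
            break
    outs = []
    for row in ys[:, 1:]:
        ids = []
        for t in row:
            if t in (eos_id, pad_id):
                break
            ids.append(int(t))
        outs.append(ids)
    return outs


def _validation_accuracy(network, corpus: EncodedCorpus, tok: TokenizerPair,
                         max_examples: int, max_len: int) -> float:
    n = min(len(corpus), max_examples)
    # decoding past the longest reference can only produce mismatches
    max_len = min(max_len, max(len(t) for t in corpus.targets[:n]) + 4)
    correct = 0
    for lo in range(0, n, 64):
        hi = min(lo + 64, n)
        outs = _greedy_decode_ids(network, corpus.sources[lo:hi], tok.bos_id,
                                  tok.eos_id, tok.pad_id, max_len)
        for pred, ref in zip(outs, corpus.targets[lo:hi]):
            correct += int(pred == list(ref))
    return correct / n


def train(config: ModelConfig, schedule: TrainingSchedule,
          data: MultiTaskMixture | EncodedCorpus, regime: str = "single",
          valid: EncodedCorpus | None = None, tokenizers: TokenizerPair | None = None,
          general: EncodedCorpus | None = None,
          init_from: TrainedModel | None = None) -> TrainedModel:
    """Train a transformer under one of the three regimes.

    ``single`` trains on ``data`` (an :class:`EncodedCorpus`); ``mtl``
    trains on a :class:`MultiTaskMixture`; ``stl`` pretrains on
    ``general`` and then continues (fresh schedule, same weights) on
    ``data``. Checkpoints are selected by exact-match validation
    accuracy with early stopping; the best weights are restored before
    returning.
    """
    if tokenizers is None:
        raise ValueError("tokenizers are required")
    if regime == "stl":
        if general is None:
            raise ValueError("stl regime needs the general corpus")
        pre = train(config, schedule, general, regime="single", valid=valid,
                    tokenizers=tokenizers)
        return train(config, schedule, data, regime="single", valid=valid,
                     tokenizers=tokenizers, init_from=pre)
    if regime == "mtl":
        if not isinstance(data, MultiTaskMixture):
            raise ValueError("mtl regime needs a MultiTaskMixture")
        mixture = data
    elif regime == "single":
        if isinstance(data, MultiTaskMixture):
            raise ValueError("single regime needs one corpus")
        mixture = MultiTaskMixture([data], [1])
    else:
        raise ValueError(f"unknown regime: {regime!r}")

    vocab = config.shared_vocab_size or tokenizers.vocab_size
    for corpus in mixture.corpora:
        top = max((max(s) for s in corpus.sources), default=0)
        top = max(top, max((max(t) for t in corpus.targets), default=0))
        if top >= vocab:
            raise ValueError(
                f"corpus {corpus.name!r} contains id {top} outside model vocabulary {vocab}"
            )

    if init_from is not None:
        network = build_network(config, tokenizers, seed=schedule.seed)
        network.params = {k: v.copy() for k, v in init_from.network.params.items()}
    else:
        network = build_network(config, tokenizers, seed=schedule.seed)
    opt = Adam(network.params, betas=schedule.adam_betas)
    drop_rng = np.random.default_rng((schedule.seed, 7))

    batch_stream = sample_multitask_batches(
        mixture, n_batches=schedule.max_steps * schedule.accum_count,
        seed=schedule.seed, batch_tokens=schedule.batch_tokens)

    loss_curve: list[float] = []
    val_curve: list[tuple[int, float]] = []
    best_acc, best_params, bad_validations = -1.0, None, 0
    corpus_by_name = {c.name: c for c in mixture.corpora}
    tok = tokenizers

    step = 0
    accum = {k: np.zeros_like(v) for k, v in network.params.items()}
    n_accum = 0
    for name, idx in batch_stream:
        corpus = corpus_by_name[name]
        src, tgt_in, tgt_out = make_training_arrays(
            corpus, idx, tok.pad_id, tok.bos_id, tok.eos_id)
        loss, grads, _acc = network.loss_and_grads(
            src, tgt_in, tgt_out, train=True, rng=drop_rng,
            label_smoothing=config.label_smoothing)
        for k in accum:
            accum[k] += grads[k]
        n_accum += 1
        if n_accum < schedule.accum_count:
            continue
        step += 1
        lr = noam_lr(step, schedule, config.model_dim)
        if schedule.accum_count > 1:
            for k in accum:
                accum[k] /= schedule.accum_count
        opt.step(network.params, accum, lr)
        for k in accum:
            accum[k][...] = 0.0
        n_accum = 0
        loss_curve.append(loss)

        if valid is not None and step % schedule.valid_interval == 0:
            acc = _validation_accuracy(network, valid, tok,
                                       schedule.valid_max_examples, config.max_len)
            val_curve.append((step, acc))
            logger.info("step %d loss %.4f val-acc %.3f", step, loss, acc)
            if acc > best_acc:
                best_acc = acc
                best_params = {k: v.copy() for k, v in network.params.items()}
                bad_validations = 0
            else:
                bad_validations += 1
                if bad_validations >= schedule.patience:
                    logger.info("early stopping at step %d (best val-acc %.3f)",
                                step, best_acc)
                    break
        if step >= schedule.max_steps:
            break

    if best_params is not None:
        network.params = best_params
    return TrainedModel(network=network, tokenizers=tok, config=config,
                        loss_curve=loss_curve, val_curve=val_curve)


# ---------------------------------------------------------------------------
# beam search


@dataclass
class Hypothesis:
    """One beam-search output."""

    tokens: list[str]
    ids: list[int]
    log_prob: float
    rank: int

    @property
    def confidence(self) -> float:
        """Product of token probabilities, ``exp(log_prob)``."""
        return float(np.exp(self.log_prob))

    @property
    def smiles(self) -> str:
        return "".join(t for t in self.tokens)


def beam_search_decode(model: TrainedModel, source: Sequence[int] | "np.ndarray",
                       beam_width: int = 5, n_best: int = 2,
                       max_len: int = 128) -> list[Hypothesis]:
    """Beam-search decode one source sequence.

    Returns the ``n_best`` highest-scoring hypotheses sorted by
    descending total log-probability (ties: shorter first, then
    lexicographic token order). Every hypothesis ends at EOS or at
    ``max_len``.
    """
    if n_best > beam_width:
        raise ValueError("n_best cannot exceed beam_width")
    if n_best < 1:
        raise ValueError("n_best must be >= 1")
    return decode_batch(model, [list(source)], beam_width, n_best, max_len)[0]


def decode_batch(model: TrainedModel, sources: list[list[int]], beam_width: int = 5,
                 n_best: int = 2, max_len: int = 128) -> list[list[Hypothesis]]:
    """Beam-search decode a batch of sources (vectorized over beams)."""
    if n_best > beam_width:
        raise ValueError("n_best cannot exceed beam_width")
    net = model.network
    tok = model.tokenizers
    pad, bos, eos = tok.pad_id, tok.bos_id, tok.eos_id
    B, W = len(sources), beam_width

    src = _pad_batch(sources, pad)
    enc_out, _ = net.encode_fwd(src, train=False)
    # tile each source W times: rows b*W..b*W+W-1 are the beams of source b
    src_t = np.repeat(src, W, axis=0)
    enc_t = np.repeat(enc_out, W, axis=0)

    ys = np.full((B * W, 1), bos, dtype=np.int64)
    beam_logp = np.full((B, W), -np.inf, dtype=np.float64)
    beam_logp[:, 0] = 0.0  # only one live beam initially (identical prefixes)
    finished: list[list[tuple[float, list[int]]]] = [[] for _ in range(B)]
    alive = np.ones((B, W), dtype=bool)
    alive[:, 1:] = False

    for _t in range(max_len):
        logp = net.next_token_logprobs(ys, enc_t, src_t)  # (B*W, V)
        V = logp.shape[-1]
        logp = logp.reshape(B, W, V)
        total = beam_logp[:, :, None] + logp
        total[~alive] = -np.inf
        flat = total.reshape(B, W * V)
        k = min(W, flat.shape[1])
        top = np.argpartition(-flat, kth=k - 1, axis=1)[:, :k]
        new_ys = np.full((B * W, ys.shape[1] + 1), pad, dtype=np.int64)
        new_logp = np.full((B, W), -np.inf)
        new_alive = np.zeros((B, W), dtype=bool)
        for b in range(B):
            cands = sorted(top[b], key=lambda f: -flat[b, f])
            slot = 0
            for f in cands:
                w, v = divmod(int(f), V)
                score = flat[b, f]
                if not np.isfinite(score):
                    continue
                seq = list(ys[b * W + w, 1:]) + [v]
                if v == eos:
                    finished[b].append((float(score), seq[:-1]))
                    continue
                if slot < W:
                    new_ys[b * W + slot, : len(seq) + 1] = [bos] + seq
                    new_logp[b, slot] = score
                    new_alive[b, slot] = True
                    slot += 1
        ys = new_ys
        beam_logp = new_logp
        alive = new_alive
        if not alive.any():
            break
        if all(len(f) >= n_best for f in finished):
            # stop when no live beam can beat the n-th best finished score
            can_improve = False
            for b in range(B):
                nth = sorted(finished[b], key=lambda s: -s[0])[n_best - 1][0]
                if alive[b].any() and beam_logp[b][alive[b]].max() > nth:
                    can_improve = True
                    break
            if not can_improve:
                break

    results: list[list[Hypothesis]] = []
    for b in range(B):
        pool = list(finished[b])
        # beams still alive at max_len count as length-truncated hypotheses
        for w in range(W):
            if alive[b, w]:
                seq = [int(t) for t in ys[b * W + w, 1:] if t != pad]
                pool.append((float(beam_logp[b, w]), seq))
        token_pool = [
            (score, seq, [model.tokenizers.id_to_token(i) for i in seq])
            for score, seq in pool
        ]
        token_pool.sort(key=lambda s: (-s[0], len(s[1]), s[2]))
        hyps = [
            Hypothesis(tokens=toks, ids=seq, log_prob=score, rank=r + 1)
            for r, (score, seq, toks) in enumerate(token_pool[:n_best])
        ]
        results.append(hyps)
    return results
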