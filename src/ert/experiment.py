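"""End-to-end desk-scale experiments on the synthetic benchmark.

``run_experiment`` wires the whole pipeline: generate corpora, build the
shared tokenizer pair, train one transformer per requested cell of the
(source-mode x regime) matrix, decode the enzymatic test set with beam
search, and evaluate — including the scrambled-sentence ablation, where
the best full-sentence model is re-evaluated on a test set whose enzyme
descriptions were deranged between reactions.

Everything is reproducible from a config plus one global seed; stage
seeds are derived from it.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .curation import split_by_product
from .evaluation import (
    EvaluationReport,
    build_prediction_records,
    calibration_bins,
    top_k_metrics,
)
from .model import (
    EncodedCorpus,
    ModelConfig,
    MultiTaskMixture,
    TrainedModel,
    TrainingSchedule,
    decode_batch,
    desk_config,
    desk_schedule,
    encode_corpus,
    train,
)
from .synthetic_data import GeneratorConfig, benchmark_suite, no_text_ceiling
from .tokenization import TokenizerPair, build_tokenizer_pair

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One experiment: which matrix cells to run under which conditions.

    Desk-scale defaults throughout; the weighted multi-task mixture
    oversamples the enzymatic corpus (2:1 batch weights against a 5x
    larger general corpus), serving the same purpose as the reference
    1:9 weighting does against a general corpus two orders of magnitude
    larger: keeping the small specialized corpus from being drowned out.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelConfig = field(default_factory=desk_config)
    schedule: TrainingSchedule = field(default_factory=desk_schedule)
    modes: tuple[str, ...] = ("no_text", "full_sentence")
    regime: str = "mtl"
    mtl_weights: tuple[int, int] = (1, 1)  # (enzymatic, general)
    beam_width: int = 3
    n_best: int = 2
    scrambled_ablation: bool = True
    text_target_vocab: int = 300
    text_top_k: int = 250
    eval_max_records: int | None = None  # decode only the first N test records
    seed: int = 0
    n_calibration_bins: int = 5


@dataclass
class ExperimentResult:
    """Reports per matrix cell plus the scrambled-sentence ablation."""

    reports: dict[str, EvaluationReport]
    calibration: dict[str, object]
    models: dict[str, TrainedModel]
    suite: dict
    stereo_subset_accuracy: dict[str, float]
    no_text_ceiling: float

    def summary(self) -> dict:
        out = {
            "cells": {k: v.to_dict() for k, v in self.reports.items()},
            "stereo_subset_top1": self.stereo_subset_accuracy,
            "no_text_ceiling": self.no_text_ceiling,
        }
        for name, df in self.calibration.items():
            out.setdefault("calibration", {})[name] = {
                "bins": df.to_dict(orient="records"),
                "true_fraction_above_high_confidence":
                    df.attrs.get("true_fraction_above_high_confidence"),
                "false_fraction_below_low_confidence":
                    df.attrs.get("false_fraction_below_low_confidence"),
            }
        return out


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.default_rng((seed, stage)).integers(0, 2**31 - 1))


def benchmark_run_config(seed: int, **overrides) -> RunConfig:
    """The standard desk-scale benchmark cell matrix.

    Default study conditions: 5000 enzymatic + 25000 general reactions,
    stereo-informative fraction 0.5, 2-layer/128-dim model, MTL with 1:1
    batch weights, early-stopped noam schedule. ``overrides`` replace
    top-level RunConfig fields.
    """
    cfg = RunConfig(
        generator=GeneratorConfig(seed=_stage_seed(seed, 0)),
        model=desk_config(ff_dim=256),
        schedule=desk_schedule(base_lr=0.2, warmup_steps=250, max_steps=2200,
                               batch_tokens=1024, valid_interval=300, patience=5,
                               valid_max_examples=64),
        modes=("no_text", "full_sentence"),
        regime="mtl",
        mtl_weights=(2, 1),
        beam_width=2,
        n_best=2,
        eval_max_records=300,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def evaluate_model(model: TrainedModel, test_corpus, mode: str, beam_width: int,
                   n_best: int, batch: int = 64, max_len: int | None = None):
    """Beam-decode a test corpus and build prediction records.

    Decoding length is bounded a little above the longest reference
    product — predictions longer than every reference cannot match.
    """
    encoded = encode_corpus(test_corpus, model.tokenizers, mode=mode, strict=False)
    if max_len is None:
        max_len = min(model.config.max_len,
                      max(len(t) for t in encoded.targets) + 8)
    all_hyps = []
    for lo in range(0, len(encoded), batch):
        chunk = encoded.sources[lo : lo + batch]
        all_hyps.extend(
            decode_batch(model, chunk, beam_width=beam_width, n_best=n_best,
                         max_len=max_len)
        )
    return build_prediction_records(test_corpus, all_hyps)


def _stereo_subset_ids(suite) -> set[str]:
    manifest = suite["manifest"]
    return set(manifest.loc[manifest["stereo_informative"], "source_id"])


def run_experiment(config: RunConfig, workdir: str | Path | None = None) -> ExperimentResult:
    """Run the requested matrix cells and the scrambled ablation.

    Returns reports keyed ``"<mode>/<regime>"`` (plus
    ``"full_sentence/<regime>/scrambled"`` when the ablation runs).
    """
    t0 = time.time()
    gen_cfg = config.generator
    suite = benchmark_suite(gen_cfg, split_seed=_stage_seed(config.seed, 1))
    enz, gen = suite["enzymatic"], suite["general"]
    logger.info(
        "benchmark: %d enzymatic (train %d / valid %d / test %d), %d general",
        sum(len(enz[s]) for s in ("train", "valid", "test")),
        len(enz["train"]), len(enz["valid"]), len(enz["test"]),
        sum(len(gen[s]) for s in ("train", "valid", "test")),
    )

    tokenizers = build_tokenizer_pair(
        [enz["train"], enz["valid"], gen["train"], gen["valid"]],
        text_target_vocab=config.text_target_vocab,
        text_top_k=config.text_top_k,
    )
    logger.info(
        "tokenizers: %d SMILES tokens, %d/%d text tokens (coverage %.3f), %d combined",
        len(tokenizers.smiles), len(tokenizers.text), tokenizers.text.full_vocab_size,
        tokenizers.text.coverage, tokenizers.vocab_size,
    )

    gen_train = encode_corpus(gen["train"], tokenizers, mode="no_text", name="general")
    stereo_ids = _stereo_subset_ids(suite)

    from .reaction_io import ReactionCorpus

    def eval_subset(corpus):
        if config.eval_max_records is None or len(corpus) <= config.eval_max_records:
            return corpus
        return ReactionCorpus(corpus.records[: config.eval_max_records],
                              name=corpus.name)

    reports: dict[str, EvaluationReport] = {}
    calibration: dict[str, object] = {}
    models: dict[str, TrainedModel] = {}
    stereo_acc: dict[str, float] = {}

    for mode in config.modes:
        cell = f"{mode}/{config.regime}"
        logger.info("training cell %s", cell)
        enz_train = encode_corpus(enz["train"], tokenizers, mode=mode, name="enzymatic")
        enz_valid = encode_corpus(enz["valid"], tokenizers, mode=mode, name="enzymatic_valid")
        schedule = TrainingSchedule(**{**config.schedule.__dict__,
                                       "seed": _stage_seed(config.seed, 2)})
        if config.regime == "mtl":
            data = MultiTaskMixture([enz_train, gen_train], list(config.mtl_weights))
            model = train(config.model, schedule, data, regime="mtl",
                          valid=enz_valid, tokenizers=tokenizers)
        elif config.regime == "stl":
            model = train(config.model, schedule, enz_train, regime="stl",
                          valid=enz_valid, tokenizers=tokenizers, general=gen_train)
        else:
            model = train(config.model, schedule, enz_train, regime="single",
                          valid=enz_valid, tokenizers=tokenizers)
        models[cell] = model

        records = evaluate_model(model, eval_subset(enz["test"]), mode,
                                 config.beam_width, config.n_best)
        reports[cell] = top_k_metrics(records, k=config.n_best)
        calibration[cell] = calibration_bins(records, config.n_calibration_bins)
        sub = [r for r in records if r.source_id in stereo_ids]
        stereo_acc[cell] = (
            sum(r.correct_at(1) for r in sub) / len(sub) if sub else float("nan")
        )
        logger.info("cell %s: top1 %.3f top2 %.3f stereo-subset %.3f (%.0fs)",
                    cell, reports[cell].top1_accuracy, reports[cell].top2_accuracy,
                    stereo_acc[cell], time.time() - t0)

        if workdir is not None:
            model.save(Path(workdir) / cell.replace("/", "_"))

    if config.scrambled_ablation and any(m == "full_sentence" for m in config.modes):
        cell = f"full_sentence/{config.regime}"
        scr_cell = cell + "/scrambled"
        records = evaluate_model(models[cell], eval_subset(enz["test_scrambled"]),
                                 "full_sentence", config.beam_width, config.n_best)
        reports[scr_cell] = top_k_metrics(records, k=config.n_best)
        logger.info("cell %s: top1 %.3f", scr_cell, reports[scr_cell].top1_accuracy)

    result = ExperimentResult(
        reports=reports,
        calibration=calibration,
        models=models,
        suite=suite,
        stereo_subset_accuracy=stereo_acc,
        no_text_ceiling=no_text_ceiling(suite["manifest"]),
    )
    if workdir is not None:
        Path(workdir).mkdir(parents=True, exist_ok=True)
        (Path(workdir) / "report.json").write_text(
            json.dumps(result.summary(), indent=2, default=float), encoding="utf-8")
    return result
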