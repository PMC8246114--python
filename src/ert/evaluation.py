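"""Scoring of predicted reaction products against references.

The headline metric is stereo-exact top-k accuracy: a prediction counts
as correct when its canonical SMILES equals the canonical reference,
stereo annotations included. A stereo-agnostic variant (both sides
stripped of stereochemistry, then re-canonicalized) is reported
alongside. Invalid-SMILES rates, per-stratum breakdowns by enzyme-name
profile, and equal-frequency confidence-calibration bins complete the
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import AseProfile, extract_ase_words
from .model import Hypothesis
from .reaction_io import SmilesParseError, canonicalize_smiles

#: confidence above which a prediction is treated as trustworthy, and
#: below which it is treated as unreliable, in the headline summaries
HIGH_CONFIDENCE = 0.98
LOW_CONFIDENCE = 0.80


def is_valid_smiles(s: str) -> bool:
    if not s:
        return False
    return Chem.MolFromSmiles(s) is not None


def strip_stereo(s: str) -> str:
    """Canonical form with all stereo annotations removed."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {s!r}")
    Chem.RemoveStereochemistry(mol)
    return canonicalize_smiles(Chem.MolToSmiles(mol))


def match_product(hypothesis: str, reference: str, stereo: bool = True) -> bool:
    """Compare a predicted product against the canonical reference.

    ``stereo=True`` requires canonical string equality including stereo
    annotations; ``stereo=False`` compares after removing stereochemistry
    from both sides. An unparsable hypothesis never matches.
    """
    try:
        hyp = canonicalize_smiles(hypothesis)
    except SmilesParseError:
        return False
    if stereo:
        return hyp == reference
    return strip_stereo(hyp) == strip_stereo(reference)


@dataclass
class PredictionRecord:
    """One test record with its ranked hypotheses and stratum labels."""

    source_id: str
    reference_product: str
    hypotheses: list[Hypothesis]
    ase_profile: AseProfile | None = None
    enantioselective: bool = False

    @property
    def top1_confidence(self) -> float:
        return self.hypotheses[0].confidence

    def correct_at(self, k: int, stereo: bool = True) -> bool:
        return any(
            match_product(h.smiles, self.reference_product, stereo=stereo)
            for h in self.hypotheses[:k]
        )


def build_prediction_records(test_corpus, hypotheses_per_record: Sequence[list[Hypothesis]]
                             ) -> list[PredictionRecord]:
    """Pair a test corpus with decoded hypotheses, attaching strata."""
    records = []
    for rec, hyps in zip(test_corpus, hypotheses_per_record):
        from .curation import flag_enantioselective

        records.append(
            PredictionRecord(
                source_id=rec.source_id,
                reference_product=rec.products,
                hypotheses=list(hyps),
                ase_profile=extract_ase_words(rec.enzyme_text),
                enantioselective=flag_enantioselective(rec),
            )
        )
    return records


@dataclass
class EvaluationReport:
    """Aggregate metrics for one evaluated model."""

    n: int
    top1_accuracy: float
    top2_accuracy: float
    top1_accuracy_no_stereo: float
    top2_accuracy_no_stereo: float
    top1_invalid_rate: float
    top2_invalid_rate: float
    top1_invalid_record_rate: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "top1_accuracy": self.top1_accuracy,
            "top2_accuracy": self.top2_accuracy,
            "top1_accuracy_no_stereo": self.top1_accuracy_no_stereo,
            "top2_accuracy_no_stereo": self.top2_accuracy_no_stereo,
            "top1_invalid_rate": self.top1_invalid_rate,
            "top2_invalid_rate": self.top2_invalid_rate,
            "top1_invalid_record_rate": self.top1_invalid_record_rate,
        }
        out.update(self.extras)
        return out


def top_k_metrics(records: Sequence[PredictionRecord], k: int = 2) -> EvaluationReport:
    """Top-1/top-k accuracy and invalid-SMILES rates.

    Accuracy counts records with a stereo-exact match among the first
    ``k`` hypotheses. The invalid rate's denominator is every emitted
    hypothesis up to rank ``k`` (``k * N`` strings); a per-record variant
    (record has an invalid SMILES in its top-1) is reported too.
    """
    if not records:
        raise ValueError("no records to evaluate")
    for r in records:
        if len(r.hypotheses) < k:
            raise ValueError(f"record {r.source_id} has fewer than {k} hypotheses")
    n = len(records)
    top1 = sum(r.correct_at(1) for r in records) / n
    topk = sum(r.correct_at(k) for r in records) / n
    top1_ns = sum(r.correct_at(1, stereo=False) for r in records) / n
    topk_ns = sum(r.correct_at(k, stereo=False) for r in records) / n
    invalid1 = sum(not is_valid_smiles(r.hypotheses[0].smiles) for r in records)
    invalidk = sum(
        not is_valid_smiles(h.smiles) for r in records for h in r.hypotheses[:k]
    )
    return EvaluationReport(
        n=n,
        top1_accuracy=top1,
        top2_accuracy=topk,
        top1_accuracy_no_stereo=top1_ns,
        top2_accuracy_no_stereo=topk_ns,
        top1_invalid_rate=invalid1 / n,
        top2_invalid_rate=invalidk / (k * n),
        top1_invalid_record_rate=invalid1 / n,
    )


FREQUENCY_BUCKETS = ((0, 0), (1, 5), (6, 20), (21, 100), (101, None))


def _bucket_label(count: int) -> str:
    for lo, hi in FREQUENCY_BUCKETS:
        if hi is None:
            if count >= lo:
                return f">{lo - 1}"
        elif lo <= count <= hi:
            return f"{lo}" if lo == hi else f"{lo}-{hi}"
    raise AssertionError(count)


def stratify(records: Sequence[PredictionRecord], by: str,
             train_combination_counts: dict[tuple[str, ...], int] | None = None,
             k: int = 2) -> dict[str, EvaluationReport]:
    """Per-stratum evaluation reports.

    ``by`` is one of:

    * ``ase_count`` — number of "-ase" words in the sentence;
    * ``combination_frequency`` — how often the record's enzyme-name
      combination occurs in the training set (buckets 0 / 1-5 / 6-20 /
      21-100 / >100); needs ``train_combination_counts``;
    * ``lipase_only`` — the subset whose enzyme names include "lipase";
    * ``enantioselective_only`` — the enantioselective subset.

    The first two modes partition all records; the ``*_only`` modes
    return the subset plus its complement ("other"), so stratum sizes
    always sum to the total.
    """
    groups: dict[str, list[PredictionRecord]] = {}
    if by == "ase_count":
        for r in records:
            groups.setdefault(str(r.ase_profile.ase_count), []).append(r)
    elif by == "combination_frequency":
        if train_combination_counts is None:
            raise ValueError("combination_frequency mode needs the training-set table")
        for r in records:
            count = train_combination_counts.get(r.ase_profile.combination_key, 0)
            groups.setdefault(_bucket_label(count), []).append(r)
    elif by == "lipase_only":
        for r in records:
            key = "lipase" if any("lipase" in w for w in r.ase_profile.ase_words) else "other"
            groups.setdefault(key, []).append(r)
    elif by == "enantioselective_only":
        for r in records:
            groups.setdefault("enantioselective" if r.enantioselective else "other", []).append(r)
    else:
        raise ValueError(f"unknown stratification: {by!r}")
    return {name: top_k_metrics(rs, k=k) for name, rs in sorted(groups.items())}


def combination_counts(corpus) -> dict[tuple[str, ...], int]:
    """Training-set occurrence count of each enzyme-name combination."""
    counts: dict[tuple[str, ...], int] = {}
    for rec in corpus:
        key = extract_ase_words(rec.enzyme_text).combination_key
        counts[key] = counts.get(key, 0) + 1
    return counts


def calibration_bins(records: Sequence[PredictionRecord], n_bins: int = 5) -> pd.DataFrame:
    """Equal-frequency calibration of top-1 confidence scores.

    Records are sorted by top-1 confidence and divided into ``n_bins``
    bins of (as near as possible) equal count; each bin reports its
    confidence range and the fraction of stereo-exact-correct top-1
    predictions. Attached as ``df.attrs``: the fraction of correct
    predictions above the high-confidence threshold (0.98) and the
    fraction of incorrect ones below the low threshold (0.80).
    """
    n = len(records)
    if n_bins > n:
        raise ValueError("more bins than records")
    order = np.argsort([r.top1_confidence for r in records], kind="stable")
    rows = []
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        rs = [records[i] for i in chunk]
        confs = [r.top1_confidence for r in rs]
        rows.append(
            {
                "bin": b,
                "conf_lo": float(min(confs)),
                "conf_hi": float(max(confs)),
                "n": len(rs),
                "true_fraction": sum(r.correct_at(1) for r in rs) / len(rs),
            }
        )
    df = pd.DataFrame(rows)
    high = [r for r in records if r.top1_confidence > HIGH_CONFIDENCE]
    low = [r for r in records if r.top1_confidence < LOW_CONFIDENCE]
    df.attrs["true_fraction_above_high_confidence"] = (
        sum(r.correct_at(1) for r in high) / len(high) if high else float("nan")
    )
    df.attrs["false_fraction_below_low_confidence"] = (
        sum(not r.correct_at(1) for r in low) / len(low) if low else float("nan")
    )
    return df


def predictions_to_tsv(records: Sequence[PredictionRecord], path) -> None:
    """Write hypotheses as `source_id  rank  smiles  log_prob  confidence`."""
    rows = []
    for r in records:
        for h in r.hypotheses:
            rows.append((r.source_id, h.rank, h.smiles, h.log_prob, h.confidence))
    pd.DataFrame(rows, columns=["source_id", "rank", "smiles", "log_prob", "confidence"]).to_csv(
        path, sep="\t", index=False
    )
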