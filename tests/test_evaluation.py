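"""Product matching, top-k metrics, stratification and calibration."""

import numpy as np
import pytest

from ert.curation import extract_ase_words
from ert.evaluation import (
    PredictionRecord,
    calibration_bins,
    combination_counts,
    match_product,
    stratify,
    top_k_metrics,
)
from ert.model import Hypothesis
from ert.reaction_io import canonicalize_smiles


def hyp(smiles, log_prob=-0.1, rank=1):
    return Hypothesis(tokens=list(smiles), ids=[], log_prob=log_prob, rank=rank)


def record(ref, predictions, source_id="r", sentence="", enantioselective=False):
    return PredictionRecord(
        source_id=source_id,
        reference_product=canonicalize_smiles(ref),
        hypotheses=[hyp(p, log_prob=-0.1 * (i + 1), rank=i + 1)
                    for i, p in enumerate(predictions)],
        ase_profile=extract_ase_words(sentence),
        enantioselective=enantioselective,
    )


class TestMatchProduct:
    def test_matches_up_to_canonicalization(self):
        assert match_product("OCC", canonicalize_smiles("CCO"))

    def test_stereo_flag_controls_enantiomer_match(self):
        ref = canonicalize_smiles("C[C@@H](O)CC")
        assert not match_product("C[C@H](O)CC", ref, stereo=True)
        assert match_product("C[C@H](O)CC", ref, stereo=False)

    def test_unparsable_hypothesis_never_matches(self):
        assert not match_product("C1CC", canonicalize_smiles("CCO"))

    def test_multi_product_set_comparison(self):
        ref = canonicalize_smiles("CC(=O)O.CCO")
        assert match_product("CCO.CC(=O)O", ref)


class TestTopKMetrics:
    def test_counting_example(self):
        records = [
            record("CCO", ["CCO", "CCC"]),          # match at rank 1
            record("CCN", ["CCC", "CCN"]),          # match at rank 2
            record("CCF", ["CCO", "CCC"]),          # no match
        ]
        report = top_k_metrics(records, k=2)
        assert report.top1_accuracy == pytest.approx(1 / 3)
        assert report.top2_accuracy == pytest.approx(2 / 3)
        assert report.top2_invalid_rate == 0.0

    def test_invalid_rate_counts_all_emitted_hypotheses(self):
        records = [
            record("CCO", ["CCO", "C1CC"]),
            record("CCN", ["C1CC", "CCN"]),
        ]
        report = top_k_metrics(records, k=2)
        assert report.top2_invalid_rate == pytest.approx(2 / 4)
        assert report.top1_invalid_record_rate == pytest.approx(1 / 2)

    def test_top2_never_below_top1(self, rng):
        pool = ["CCO", "CCN", "CCF", "C1CC", "CC(C)O"]
        records = [
            record(pool[rng.integers(3)], [pool[rng.integers(5)], pool[rng.integers(5)]],
                   source_id=str(i))
            for i in range(200)
        ]
        report = top_k_metrics(records, k=2)
        assert report.top2_accuracy >= report.top1_accuracy

    def test_independent_recount_agrees(self, rng):
        """Cross-check against a naive recount on randomized records."""
        pool = ["CCO", "CCN", "CCF", "CCCl", "CC(C)O", "C1CC"]
        records = []
        for i in range(500):
            ref = pool[rng.integers(5)]
            preds = [pool[rng.integers(6)], pool[rng.integers(6)]]
            records.append(record(ref, preds, source_id=str(i)))
        report = top_k_metrics(records, k=2)

        # naive recount, independent of the evaluation code paths
        from rdkit import Chem

        def canon(s):
            m = Chem.MolFromSmiles(s)
            return None if m is None else Chem.MolToSmiles(m)

        top1 = top2 = invalid = 0
        for r in records:
            preds = ["".join(h.tokens) for h in r.hypotheses]
            cs = [canon(p) for p in preds]
            invalid += sum(c is None for c in cs)
            if cs[0] == r.reference_product:
                top1 += 1
            if r.reference_product in [c for c in cs if c]:
                top2 += 1
        assert report.top1_accuracy == pytest.approx(top1 / 500)
        assert report.top2_accuracy == pytest.approx(top2 / 500)
        assert report.top2_invalid_rate == pytest.approx(invalid / 1000)

    def test_missing_hypotheses_rejected(self):
        records = [record("CCO", ["CCO"])]
        with pytest.raises(ValueError, match="fewer than 2"):
            top_k_metrics(records, k=2)


class TestStratify:
    def _records(self):
        return [
            record("CCO", ["CCO", "CCN"], "a", "alcohol dehydrogenase"),
            record("CCN", ["CCN", "CCO"], "b", "lipase from candida"),
            record("CCF", ["CCO", "CCN"], "c",
                   "ketoreductase glucose dehydrogenase"),
            record("CCO", ["CCO", "CCN"], "d", "", enantioselective=True),
        ]

    def test_ase_count_partition(self):
        strata = stratify(self._records(), by="ase_count")
        assert {k: v.n for k, v in strata.items()} == {"0": 1, "1": 2, "2": 1}

    def test_lipase_only_subset(self):
        strata = stratify(self._records(), by="lipase_only")
        assert strata["lipase"].n == 1
        assert strata["lipase"].top1_accuracy == 1.0
        assert strata["other"].n == 3

    def test_enantioselective_subset(self):
        strata = stratify(self._records(), by="enantioselective_only")
        assert strata["enantioselective"].n == 1

    def test_sizes_always_sum_to_total(self):
        records = self._records()
        for by in ("ase_count", "lipase_only", "enantioselective_only"):
            strata = stratify(records, by=by)
            assert sum(v.n for v in strata.values()) == len(records)

    def test_combination_frequency_buckets(self):
        counts = {("dehydrogenase",): 3, ("lipase",): 120}
        strata = stratify(self._records(), by="combination_frequency",
                          train_combination_counts=counts)
        assert strata["1-5"].n == 1       # dehydrogenase seen 3x in training
        assert strata[">100"].n == 1      # lipase seen 120x
        assert strata["0"].n == 2         # empty + unseen combination
        with pytest.raises(ValueError):
            stratify(self._records(), by="combination_frequency")

    def test_combination_counts_helper(self, tiny_corpus):
        counts = combination_counts(tiny_corpus)
        assert counts[("ketoreductase",)] == 2
        assert counts[()] == 1


class TestCalibration:
    def _records_with_conf(self, confs, correct):
        records = []
        for i, (c, ok) in enumerate(zip(confs, correct)):
            ref = "CCO"
            pred = "CCO" if ok else "CCN"
            r = record(ref, [pred, "CCN"], source_id=str(i))
            r.hypotheses[0].log_prob = float(np.log(c))
            records.append(r)
        return records

    def test_equal_frequency_bins_exact(self):
        confs = np.linspace(0.01, 0.99, 100)
        records = self._records_with_conf(confs, [True] * 100)
        df = calibration_bins(records, n_bins=5)
        assert list(df["n"]) == [20] * 5
        assert all(df["true_fraction"] == 1.0)

    def test_bins_partition_and_order(self):
        rng = np.random.default_rng(5)
        confs = rng.uniform(0.01, 0.99, 83)
        records = self._records_with_conf(confs, rng.random(83) > 0.5)
        df = calibration_bins(records, n_bins=4)
        assert df["n"].sum() == 83
        assert (df["conf_lo"].values[1:] >= df["conf_hi"].values[:-1]).all()

    def test_threshold_summaries(self):
        confs = [0.99, 0.995, 0.5, 0.6]
        correct = [True, True, False, False]
        records = self._records_with_conf(confs, correct)
        df = calibration_bins(records, n_bins=2)
        assert df.attrs["true_fraction_above_high_confidence"] == 1.0
        assert df.attrs["false_fraction_below_low_confidence"] == 1.0

    def test_more_bins_than_records_rejected(self):
        records = self._records_with_conf([0.5], [True])
        with pytest.raises(ValueError):
            calibration_bins(records, n_bins=2)
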