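"""Enzyme-name analytics, enantioselectivity, splits, augmentation, scrambling."""

import numpy as np
import pytest
from rdkit import Chem

from ert.curation import (
    ase_frequency_table,
    augment_noncanonical,
    extract_ase_words,
    flag_enantioselective,
    scramble_sentences,
    split_by_product,
)
from ert.reaction_io import EnzymaticReaction, ReactionCorpus, canonicalize_smiles


class TestAseWords:
    @pytest.mark.parametrize(
        "sentence,words,count",
        [
            ("Candida antarctica lipase B", ["lipase"], 1),
            ("glucose dehydrogenase alcohol dehydrogenase",
             ["dehydrogenase", "dehydrogenase"], 2),
            ("", [], 0),
            ("in any case the base buffer", [], 0),          # short words excluded
            ("a lyase and a ligase.", ["lyase", "ligase"], 2),  # punctuation stripped
            ("(R)-selective transaminase,", ["transaminase"], 1),
        ],
    )
    def test_extraction(self, sentence, words, count):
        profile = extract_ase_words(sentence)
        assert list(profile.ase_words) == words
        assert profile.ase_count == count

    def test_combination_key_order_invariant(self):
        a = extract_ase_words("lipase then esterase")
        b = extract_ase_words("esterase with lipase")
        assert a.combination_key == b.combination_key == ("esterase", "lipase")


class TestEnantioselective:
    @pytest.mark.parametrize(
        "reactants,products,expected",
        [
            ("CC(=O)c1ccccc1", "C[C@H](O)c1ccccc1", True),
            ("C[C@H](O)CC", "CC(=O)CC", False),
            ("CCO", "CC=O", False),
        ],
    )
    def test_rule(self, reactants, products, expected):
        rec = EnzymaticReaction(reactants, products, "", "x")
        assert flag_enantioselective(rec) is expected

    def test_agreement_with_stereocenter_oracle(self, small_corpus):
        """The '@'-based rule must agree with RDKit's assigned-stereocenter count."""
        corpus, _ = small_corpus
        for rec in corpus:
            def assigned(smiles):
                mol = Chem.MolFromSmiles(smiles)
                return len(Chem.FindMolChiralCenters(mol, includeUnassigned=False))
            expected = assigned(rec.reactants) == 0 and assigned(rec.products) >= 1
            assert flag_enantioselective(rec) is expected


class TestSplitByProduct:
    def _corpus(self, product_sizes):
        records = []
        for p, size in enumerate(product_sizes):
            product = canonicalize_smiles("C" * (p + 2) + "O")
            for i in range(size):
                records.append(
                    EnzymaticReaction("C" * (p + 2), product, "", f"{p}-{i}"))
        return ReactionCorpus(records)

    def test_groups_stay_whole(self):
        corpus = self._corpus([4, 3, 2, 1])
        split = split_by_product(corpus, (0.8, 0.1, 0.1), seed=0)
        for product in {r.products for r in corpus}:
            splits = {split.assignment[i] for i, r in enumerate(corpus)
                      if r.products == product}
            assert len(splits) == 1

    def test_zero_leakage_over_many_seeds(self, small_corpus):
        corpus, _ = small_corpus
        for seed in range(20):
            split = split_by_product(corpus, seed=seed)
            products = {
                s: {corpus.records[i].products for i in split.indices(s)}
                for s in ("train", "valid", "test")
            }
            assert not products["train"] & products["valid"]
            assert not products["train"] & products["test"]
            assert not products["valid"] & products["test"]

    def test_deterministic(self, small_corpus):
        corpus, _ = small_corpus
        a = split_by_product(corpus, seed=7)
        b = split_by_product(corpus, seed=7)
        assert a.assignment == b.assignment

    def test_achieved_fractions_close_on_generator_corpus(self, small_corpus):
        corpus, _ = small_corpus
        split = split_by_product(corpus, (0.8, 0.1, 0.1), seed=1)
        achieved = split.achieved_fractions()
        assert achieved["train"] == pytest.approx(0.8, abs=0.05)
        assert achieved["valid"] == pytest.approx(0.1, abs=0.05)

    def test_too_few_groups_rejected(self):
        corpus = self._corpus([3, 2])
        with pytest.raises(ValueError, match="3 product groups"):
            split_by_product(corpus)

    def test_bad_fractions_rejected(self, small_corpus):
        corpus, _ = small_corpus
        with pytest.raises(ValueError):
            split_by_product(corpus, (0.5, 0.2, 0.2))


class TestAugmentation:
    def test_doubles_and_preserves_canonical_multiset(self, small_corpus):
        corpus, _ = small_corpus
        sub = ReactionCorpus(corpus.records[:80], name="sub")
        out = augment_noncanonical(sub, seed=5)
        assert len(out) == 2 * len(sub)
        before = [(r.reactants, r.products, r.enzyme_text) for r in sub]
        after = sorted(
            (canonicalize_smiles(r.reactants), r.products, r.enzyme_text)
            for r in out)
        assert after == sorted(before + before)

    def test_single_record(self):
        corpus = ReactionCorpus(
            [EnzymaticReaction("CC(=O)c1ccccc1", "C[C@H](O)c1ccccc1", "kred", "a")])
        out = augment_noncanonical(corpus, seed=0)
        assert len(out) == 2
        assert canonicalize_smiles(out.records[1].reactants) == out.records[0].reactants


class TestScramble:
    def test_two_records_swap(self):
        corpus = ReactionCorpus([
            EnzymaticReaction("CCO", "CC=O", "sentence one", "a"),
            EnzymaticReaction("CCCO", "CCC=O", "sentence two", "b"),
        ])
        out = scramble_sentences(corpus, seed=0)
        assert out.records[0].enzyme_text == "sentence two"
        assert out.records[1].enzyme_text == "sentence one"

    def test_sentence_multiset_conserved_and_smiles_untouched(self, small_corpus):
        corpus, _ = small_corpus
        out = scramble_sentences(corpus, seed=3)
        assert sorted(r.enzyme_text for r in out) == sorted(r.enzyme_text for r in corpus)
        assert [(r.reactants, r.products) for r in out] == [
            (r.reactants, r.products) for r in corpus]

    def test_no_fixed_points_with_distinct_sentences(self):
        records = [EnzymaticReaction("CCO", "CC=O", f"enzyme variant {i}", str(i))
                   for i in range(1000)]
        corpus = ReactionCorpus(records)
        out = scramble_sentences(corpus, seed=11)
        fixed = sum(a.enzyme_text == b.enzyme_text for a, b in zip(corpus, out))
        assert fixed / len(corpus) < 0.01


class TestFrequencyTables:
    def test_counts_partition_corpus(self):
        records = [
            EnzymaticReaction("CCO", "CC=O", "alcohol dehydrogenase", "0"),
            EnzymaticReaction("CCO", "CC=O", "lipase", "1"),
            EnzymaticReaction("CCO", "CC=O", "lipase b", "2"),
            EnzymaticReaction("CCO", "CC=O", "lipase from candida", "3"),
            EnzymaticReaction("CCO", "CC=O", "no enzyme here", "4"),
        ]
        combo, counts = ase_frequency_table(ReactionCorpus(records))
        assert counts.set_index("ase_count")["n_reactions"].to_dict() == {1: 4, 0: 1}
        assert combo["n_reactions"].sum() == 5
        assert combo.iloc[0]["combination"] == "lipase"

    def test_top_combination_matches_generator_family_skew(self, small_corpus):
        """Default family weights make lipase the most common single enzyme."""
        corpus, manifest = small_corpus
        combo, _ = ase_frequency_table(corpus)
        top_single = combo[combo["combination"].str.split().str.len() == 1].iloc[0]
        top_family = manifest["family"].value_counts()
        assert "lipase" in top_single["combination"] or top_family.idxmax() in (
            top_single["combination"])
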