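"""Dataset analytics and split construction for enzymatic reaction corpora.

The enzyme-family structure of a corpus is summarized through the words
ending in "-ase" (lipase, dehydrogenase, ketoreductase, ...), which act as
coarse enzyme-family labels. Train/validation/test splits group reactions
by canonical product so that no product a model must write out at test
time was ever seen during training — the leakage-free contract that makes
exact-match product accuracy meaningful.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .reaction_io import EnzymaticReaction, ReactionCorpus, randomize_smiles

_PUNCT = re.compile(r"^[\W_]+|[\W_]+$")

#: minimum word length for "-ase" matching; excludes short English words
#: such as "case" and "base" while keeping the shortest enzyme names
#: ("lyase", "ligase").
MIN_ASE_LENGTH = 5


@dataclass(frozen=True)
class AseProfile:
    """Enzyme-name words extracted from one sentence."""

    ase_words: tuple[str, ...]
    combination_key: tuple[str, ...]

    @property
    def ase_count(self) -> int:
        return len(self.ase_words)


def extract_ase_words(sentence: str) -> AseProfile:
    """Extract enzyme-name words (suffix "-ase") from a sentence.

    Words are whitespace-delimited, stripped of surrounding punctuation
    and matched case-insensitively; occurrences are counted, so a coupled
    system naming two dehydrogenases counts as two. The combination key is
    the sorted, deduplicated tuple of lowercased words — invariant to the
    order in which enzymes are mentioned.
    """
    words = []
    for raw in sentence.split():
        word = _PUNCT.sub("", raw).lower()
        if len(word) >= MIN_ASE_LENGTH and word.endswith("ase"):
            words.append(word)
    return AseProfile(ase_words=tuple(words), combination_key=tuple(sorted(set(words))))


def flag_enantioselective(reaction: EnzymaticReaction) -> bool:
    """Detect enantioselective / kinetic-resolution reactions.

    True when the reactant SMILES carries no "@" stereo annotation (no
    chiral centers, or undefined configuration) while the product SMILES
    carries at least one — i.e. the transformation created or resolved
    stereochemistry.
    """
    return "@" not in reaction.reactants and "@" in reaction.products


@dataclass
class SplitAssignment:
    """Record-index → split-name assignment produced by product grouping."""

    assignment: dict[int, str]
    fractions: tuple[float, float, float]
    seed: int

    def indices(self, split: str) -> list[int]:
        return sorted(i for i, s in self.assignment.items() if s == split)

    def subset(self, corpus: ReactionCorpus, split: str) -> ReactionCorpus:
        return ReactionCorpus(
            [corpus.records[i] for i in self.indices(split)],
            name=f"{corpus.name}.{split}",
        )

    def achieved_fractions(self) -> dict[str, float]:
        n = len(self.assignment)
        return {
            s: sum(1 for v in self.assignment.values() if v == s) / n
            for s in ("train", "valid", "test")
        }


def split_by_product(
    corpus: ReactionCorpus,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 42,
) -> SplitAssignment:
    """Split a corpus into train/valid/test with zero product leakage.

    Reactions sharing a canonical product string form one group; whole
    groups are assigned to splits, so a product occurring in the test set
    can never occur in training. Groups are shuffled with the seed, then
    assigned largest-first to whichever split is furthest below its
    target reaction count — this tracks the requested fractions tightly
    even when group sizes are skewed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(corpus):
        groups.setdefault(rec.products, []).append(i)
    if len(groups) < 3:
        raise ValueError(f"need >= 3 product groups to split, got {len(groups)}")

    rng = np.random.default_rng(seed)
    keys = sorted(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda k: -len(groups[k]))  # stable: keeps shuffled order within size

    names = ("train", "valid", "test")
    targets = {s: f * len(corpus) for s, f in zip(names, fractions)}
    counts = {s: 0 for s in names}
    assignment: dict[int, str] = {}
    for key in keys:
        # largest deficit relative to target; ties resolved train > valid > test
        split = max(names, key=lambda s: targets[s] - counts[s])
        for i in groups[key]:
            assignment[i] = split
        counts[split] += len(groups[key])
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)


def augment_noncanonical(corpus: ReactionCorpus, seed: int = 0) -> ReactionCorpus:
    """Double a training corpus with non-canonical precursor renderings.

    For each record a duplicate is appended whose reactants are a seeded
    random atom-order rendering of the same molecules; products and
    enzyme text are unchanged, so the multiset of canonical reactions is
    preserved exactly.
    """
    augmented: list[EnzymaticReaction] = list(corpus.records)
    for i, rec in enumerate(corpus):
        randomized = randomize_smiles(rec.reactants, seed=seed + i)
        augmented.append(
            replace(rec, reactants=randomized, source_id=f"{rec.source_id}+aug")
        )
    return ReactionCorpus(augmented, name=corpus.name)


def scramble_sentences(corpus: ReactionCorpus, seed: int = 0) -> ReactionCorpus:
    """Swap enzyme sentences between reactions (ablation control).

    Sentences are permuted with a seeded Sattolo shuffle, which produces a
    single-cycle permutation: no record keeps its own position's sentence
    (records can only retain their sentence when duplicates of it exist
    elsewhere in the corpus). Reaction SMILES are untouched and the
    multiset of sentences is conserved.
    """
    n = len(corpus)
    if n < 2:
        raise ValueError("need >= 2 records to scramble sentences")
    rng = np.random.default_rng(seed)
    perm = np.arange(n)
    for i in range(n - 1, 0, -1):  # Sattolo: j strictly below i -> one n-cycle
        j = int(rng.integers(0, i))
        perm[i], perm[j] = perm[j], perm[i]
    records = [
        replace(rec, enzyme_text=corpus.records[perm[i]].enzyme_text)
        for i, rec in enumerate(corpus)
    ]
    return ReactionCorpus(records, name=f"{corpus.name}.scrambled")


def ase_frequency_table(corpus: ReactionCorpus | Iterable[EnzymaticReaction]):
    """Per-corpus "-ase" frequency tables.

    Returns ``(combination_table, count_table)`` DataFrames: reactions per
    enzyme-name combination and reactions per number of "-ase" words,
    both sorted by descending reaction count. Rows partition the corpus.
    """
    combos: dict[tuple[str, ...], int] = {}
    counts: dict[int, int] = {}
    total = 0
    for rec in corpus:
        profile = extract_ase_words(rec.enzyme_text)
        combos[profile.combination_key] = combos.get(profile.combination_key, 0) + 1
        counts[profile.ase_count] = counts.get(profile.ase_count, 0) + 1
        total += 1
    combo_df = pd.DataFrame(
        {
            "combination": [" ".join(k) if k else "(none)" for k in combos],
            "n_reactions": list(combos.values()),
        }
    ).sort_values(["n_reactions", "combination"], ascending=[False, True], ignore_index=True)
    count_df = pd.DataFrame(
        {"ase_count": list(counts), "n_reactions": list(counts.values())}
    ).sort_values(["n_reactions", "ase_count"], ascending=[False, True], ignore_index=True)
    assert int(combo_df["n_reactions"].sum()) == total
    assert int(count_df["n_reactions"].sum()) == total
    return combo_df, count_df
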