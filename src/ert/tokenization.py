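"""Tokenizers for mixed SMILES + natural-language reaction sources.

Two tokenizers share one combined vocabulary:

* :class:`SmilesTokenizer` — the molecular-transformer atomic tokenizer.
  Every character is its own token except the two-letter halogens
  (``Cl``/``Br``), bracketed atom strings (``[C@@H]``, ``[nH]``, ...) and
  two-digit ring closures (``%NN``). Joining the tokens reproduces the
  input string exactly, so tokenization is lossless by construction.

* :class:`TextTokenizer` — a byte-pair-encoding subword tokenizer for the
  enzyme sentences, built by greedy most-frequent-pair merging with an
  end-of-word marker, then truncated to the ``k`` most frequent tokens
  (everything else encodes as ``UNK``). The retained fraction of training
  token occurrences is reported as ``coverage``.

The combined vocabulary keeps special tokens, SMILES tokens and text
tokens in disjoint id ranges, so identical strings on the two sides (none
occur in practice) could never collide on an id.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

PAD, BOS, EOS, UNK = "[PAD]", "[BOS]", "[EOS]", "[UNK]"
from .reaction_io import SEP_TOKEN  # noqa: E402  (shared reserved token)

SPECIAL_TOKENS = [PAD, BOS, EOS, UNK, SEP_TOKEN]

#: end-of-word marker appended to the last symbol of every word before
#: BPE merging, so merges never cross word boundaries and detokenization
#: can restore spaces.
EOW = "</w>"

SMILES_TOKEN_PATTERN = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[a-zA-Z]|\d|[()=#\-+.\\/:~@?>*$])"
)


class TokenizationError(ValueError):
    """Raised when a string cannot be tokenized losslessly."""


@dataclass
class TokenSequence:
    """A tokenized string with ids resolved against the owning vocabulary."""

    tokens: list[str]
    ids: list[int]
    segment: str = "smiles"  # {"smiles", "text", "mixed"}

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.ids):
            raise ValueError("tokens and ids must have equal length")

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize_smiles(s: str) -> TokenSequence:
    """Split a SMILES string into atomic tokens.

    The concatenation of the returned tokens equals ``s``; any character
    run the pattern cannot account for (e.g. an unbalanced ``[``) raises
    :class:`TokenizationError`.
    """
    tokens = SMILES_TOKEN_PATTERN.findall(s)
    if "".join(tokens) != s:
        raise TokenizationError(f"SMILES does not tokenize losslessly: {s!r}")
    return TokenSequence(tokens, ids=list(range(len(tokens))), segment="smiles")


def detokenize_smiles(tokens: Sequence[str]) -> str:
    return "".join(tokens)


@dataclass
class SmilesTokenizer:
    """Atomic SMILES tokenizer with a closed vocabulary fitted on a corpus."""

    vocabulary: dict[str, int] = field(default_factory=dict)

    @classmethod
    def fit(cls, smiles: Iterable[str]) -> "SmilesTokenizer":
        """Collect the atomic-token vocabulary of a SMILES corpus.

        Tokens are id-ordered by first occurrence; the vocabulary size is
        the number of distinct atomic tokens the corpus requires.
        """
        vocab: dict[str, int] = {}
        for s in smiles:
            for tok in tokenize_smiles(s).tokens:
                if tok not in vocab:
                    vocab[tok] = len(vocab)
        return cls(vocabulary=vocab)

    def __len__(self) -> int:
        return len(self.vocabulary)

    def encode(self, s: str, strict: bool = True) -> TokenSequence:
        """Tokenize and map to ids.

        Unseen atomic tokens are an error when ``strict`` (training-time:
        the chemical vocabulary is closed) and ``UNK`` (id ``-1`` here;
        remapped by the combined vocabulary) with a warning otherwise.
        """
        seq = tokenize_smiles(s)
        ids = []
        for tok in seq.tokens:
            if tok in self.vocabulary:
                ids.append(self.vocabulary[tok])
            elif strict:
                raise TokenizationError(f"SMILES token {tok!r} not in closed vocabulary")
            else:
                logger.warning("unseen SMILES token %r mapped to UNK", tok)
                ids.append(-1)
        return TokenSequence(seq.tokens, ids, segment="smiles")


def _word_symbols(word: str) -> tuple[str, ...]:
    chars = list(word)
    chars[-1] = chars[-1] + EOW
    return tuple(chars)


def _count_pairs(word_freqs: dict[tuple[str, ...], int]) -> Counter:
    pairs: Counter = Counter()
    for symbols, freq in word_freqs.items():
        for a, b in zip(symbols, symbols[1:]):
            pairs[(a, b)] += freq
    return pairs


@dataclass
class TextTokenizer:
    """BPE subword tokenizer with top-K vocabulary truncation.

    ``merges`` is the ordered list of learned merge rules; ``vocabulary``
    maps retained tokens to ids; ``frequencies`` holds training-corpus
    occurrence counts for every token the full (untruncated) tokenizer
    produces; ``coverage`` is the fraction of those occurrences that the
    retained vocabulary still represents.
    """

    merges: list[tuple[str, str]] = field(default_factory=list)
    vocabulary: dict[str, int] = field(default_factory=dict)
    frequencies: dict[str, int] = field(default_factory=dict)
    max_vocab: int | None = None
    coverage: float = 1.0

    @property
    def full_vocab_size(self) -> int:
        """Vocabulary size before any truncation."""
        return len(self.frequencies)

    def __len__(self) -> int:
        return len(self.vocabulary)

    def _apply_merges(self, word: str) -> list[str]:
        symbols = list(_word_symbols(word))
        # merge ranks give priority; repeatedly merge the best-ranked pair
        ranks = {pair: i for i, pair in enumerate(self.merges)}
        while len(symbols) > 1:
            best, best_rank = None, None
            for i, pair in enumerate(zip(symbols, symbols[1:])):
                r = ranks.get(pair)
                if r is not None and (best_rank is None or r < best_rank):
                    best, best_rank = i, r
            if best is None:
                break
            symbols[best : best + 2] = [symbols[best] + symbols[best + 1]]
        return symbols

    def encode_word(self, word: str) -> list[str]:
        """Subword tokens for one word; dropped/unseen tokens become UNK."""
        return [t if t in self.vocabulary else UNK for t in self._apply_merges(word)]

    def encode(self, text: str) -> TokenSequence:
        """Encode a whitespace-separated sentence (caller handles casing)."""
        tokens: list[str] = []
        for word in text.split():
            tokens.extend(self.encode_word(word))
        ids = [self.vocabulary.get(t, self.vocabulary.get(UNK, -1)) for t in tokens]
        return TokenSequence(tokens, ids, segment="text")

    def decode(self, tokens: Sequence[str]) -> str:
        return "".join(tokens).replace(EOW, " ").strip()


def train_bpe(sentences: Sequence[str], target_vocab: int) -> TextTokenizer:
    """Learn a BPE tokenizer by greedy most-frequent-pair merging.

    Merging continues until the vocabulary (base symbols + merged tokens)
    reaches ``target_vocab`` or no adjacent pair occurs at least twice.
    Ties on pair count are broken lexicographically on the merged string,
    so identical corpora always yield identical merge lists. Token
    occurrence frequencies over the training corpus are recorded for
    later truncation.
    """
    sentences = [s for s in sentences if s.strip()]
    if not sentences:
        raise ValueError("cannot train BPE on an empty corpus")

    word_freqs: dict[tuple[str, ...], int] = {}
    for sent in sentences:
        for word in sent.split():
            key = _word_symbols(word)
            word_freqs[key] = word_freqs.get(key, 0) + 1

    base_symbols = {sym for word in word_freqs for sym in word}
    vocab_size = len(base_symbols)
    merges: list[tuple[str, str]] = []

    current = dict(word_freqs)
    while vocab_size < target_vocab:
        pairs = _count_pairs(current)
        if not pairs:
            break
        best_count = max(pairs.values())
        if best_count < 2:
            break
        best = min((p for p, c in pairs.items() if c == best_count), key=lambda p: p[0] + p[1])
        merges.append(best)
        merged_tok = best[0] + best[1]
        vocab_size += 1
        new_current: dict[tuple[str, ...], int] = {}
        for symbols, freq in current.items():
            out: list[str] = []
            i = 0
            while i < len(symbols):
                if i + 1 < len(symbols) and (symbols[i], symbols[i + 1]) == best:
                    out.append(merged_tok)
                    i += 2
                else:
                    out.append(symbols[i])
                    i += 1
            key = tuple(out)
            new_current[key] = new_current.get(key, 0) + freq
        current = new_current

    frequencies: Counter = Counter()
    for symbols, freq in current.items():
        for sym in symbols:
            frequencies[sym] += freq
    # base symbols that were fully absorbed by merges keep a zero count so
    # the pre-truncation vocabulary size still reflects every known token
    for sym in base_symbols:
        frequencies.setdefault(sym, 0)
    for a, b in merges:
        frequencies.setdefault(a + b, 0)

    vocabulary = {tok: i for i, tok in enumerate(sorted(frequencies))}
    return TextTokenizer(
        merges=merges,
        vocabulary=vocabulary,
        frequencies=dict(frequencies),
        max_vocab=None,
        coverage=1.0,
    )


def truncate_vocab(tok: TextTokenizer, k: int) -> TextTokenizer:
    """Keep the ``k`` most frequent tokens (ties lexicographic).

    Returns a new tokenizer whose encoding maps dropped tokens to ``UNK``
    and whose ``coverage`` reports the retained fraction of training-corpus
    token occurrences. ``k`` at or above the full vocabulary size is a
    no-op with coverage 1.0.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    items = sorted(tok.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = [t for t, _ in items[:k]]
    total = sum(tok.frequencies.values())
    kept_occurrences = sum(tok.frequencies[t] for t in kept)
    coverage = kept_occurrences / total if total else 1.0
    vocabulary = {t: i for i, t in enumerate(sorted(kept))}
    return TextTokenizer(
        merges=list(tok.merges),
        vocabulary=vocabulary,
        frequencies=dict(tok.frequencies),
        max_vocab=k,
        coverage=coverage,
    )


@dataclass
class TokenizerPair:
    """Atomic SMILES tokenizer + BPE text tokenizer sharing one vocabulary.

    The combined vocabulary lays out ids as
    ``[specials | SMILES tokens | text tokens]`` with zero collisions, the
    shared-vocabulary contract of joint source/target training.
    """

    smiles: SmilesTokenizer
    text: TextTokenizer

    def __post_init__(self) -> None:
        self._special_ids = {tok: i for i, tok in enumerate(SPECIAL_TOKENS)}
        base = len(SPECIAL_TOKENS)
        self._smiles_offset = base
        self._text_offset = base + len(self.smiles.vocabulary)

    @property
    def vocab_size(self) -> int:
        return len(SPECIAL_TOKENS) + len(self.smiles.vocabulary) + len(self.text.vocabulary)

    @property
    def pad_id(self) -> int:
        return self._special_ids[PAD]

    @property
    def bos_id(self) -> int:
        return self._special_ids[BOS]

    @property
    def eos_id(self) -> int:
        return self._special_ids[EOS]

    @property
    def unk_id(self) -> int:
        return self._special_ids[UNK]

    @property
    def sep_id(self) -> int:
        return self._special_ids[SEP_TOKEN]

    def smiles_id(self, token: str) -> int:
        return self._smiles_offset + self.smiles.vocabulary[token]

    def id_to_token(self, i: int) -> str:
        if i < len(SPECIAL_TOKENS):
            return SPECIAL_TOKENS[i]
        if i < self._text_offset:
            return self._smiles_tokens_by_id()[i - self._smiles_offset]
        return self._text_tokens_by_id()[i - self._text_offset]

    def _smiles_tokens_by_id(self) -> list[str]:
        out = [""] * len(self.smiles.vocabulary)
        for tok, i in self.smiles.vocabulary.items():
            out[i] = tok
        return out

    def _text_tokens_by_id(self) -> list[str]:
        out = [""] * len(self.text.vocabulary)
        for tok, i in self.text.vocabulary.items():
            out[i] = tok
        return out

    def encode_smiles(self, s: str, strict: bool = True) -> TokenSequence:
        seq = self.smiles.encode(s, strict=strict)
        ids = [self._smiles_offset + i if i >= 0 else self.unk_id for i in seq.ids]
        return TokenSequence(seq.tokens, ids, segment="smiles")

    def encode_text(self, text: str) -> TokenSequence:
        seq = self.text.encode(text.lower())
        tokens = [t if i >= 0 else UNK for t, i in zip(seq.tokens, seq.ids)]
        ids = [self._text_offset + i if i >= 0 else self.unk_id for i in seq.ids]
        return TokenSequence(tokens, ids, segment="text")

    def encode_source(self, reaction, mode: str = "full_sentence", strict: bool = True) -> TokenSequence:
        """Encode precursor SMILES plus (optionally) the enzyme sentence.

        ``mode`` selects how much enzyme information enters the source
        sequence: ``no_text`` drops it entirely, ``ase_only`` keeps only
        the "-ase" words of the sentence, ``full_sentence`` keeps all of
        it. Text is lowercased before BPE; SMILES casing is untouched
        (aromaticity and element symbols are case-sensitive).
        """
        if mode not in ("no_text", "ase_only", "full_sentence"):
            raise ValueError(f"unknown source mode: {mode!r}")
        smiles_seq = self.encode_smiles(reaction.reactants, strict=strict)
        text = reaction.enzyme_text
        if mode == "ase_only" and text:
            from .curation import extract_ase_words

            text = " ".join(extract_ase_words(text).ase_words)
        if mode == "no_text" or not text:
            return TokenSequence(list(smiles_seq.tokens), list(smiles_seq.ids), segment="mixed")
        text_seq = self.encode_text(text)
        return TokenSequence(
            smiles_seq.tokens + [SEP_TOKEN] + text_seq.tokens,
            smiles_seq.ids + [self.sep_id] + text_seq.ids,
            segment="mixed",
        )

    def encode_target(self, products: str, strict: bool = True) -> TokenSequence:
        return self.encode_smiles(products, strict=strict)

    # -- persistence --------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "smiles_vocab": self._smiles_tokens_by_id(),
            "bpe_merges": [list(m) for m in self.text.merges],
            "text_vocab": self._text_tokens_by_id(),
            "text_frequencies": self.text.frequencies,
            "special_tokens": {t: i for i, t in enumerate(SPECIAL_TOKENS)},
            "coverage": self.text.coverage,
            "max_vocab": self.text.max_vocab,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()), encoding="utf-8")

    @classmethod
    def from_json(cls, payload: dict) -> "TokenizerPair":
        smiles = SmilesTokenizer({t: i for i, t in enumerate(payload["smiles_vocab"])})
        text = TextTokenizer(
            merges=[tuple(m) for m in payload["bpe_merges"]],
            vocabulary={t: i for i, t in enumerate(payload["text_vocab"])},
            frequencies={k: int(v) for k, v in payload.get("text_frequencies", {}).items()},
            max_vocab=payload.get("max_vocab"),
            coverage=float(payload.get("coverage", 1.0)),
        )
        return cls(smiles=smiles, text=text)

    @classmethod
    def load(cls, path: str | Path) -> "TokenizerPair":
        return cls.from_json(json.loads(Path(path).read_text(encoding="utf-8")))


def build_tokenizer_pair(
    corpora, text_target_vocab: int = 300, text_top_k: int | None = None
) -> TokenizerPair:
    """Fit both tokenizers on training corpora.

    The SMILES vocabulary is collected from every reactant and product
    string; the BPE tokenizer is trained on the lowercased enzyme
    sentences and optionally truncated to the ``text_top_k`` most
    frequent tokens.
    """
    smiles_strings: list[str] = []
    sentences: list[str] = []
    for corpus in corpora:
        for rec in corpus:
            smiles_strings.append(rec.reactants)
            smiles_strings.append(rec.products)
            if rec.enzyme_text:
                sentences.append(rec.enzyme_text.lower())
    smiles_tok = SmilesTokenizer.fit(smiles_strings)
    if sentences:
        text_tok = train_bpe(sentences, target_vocab=text_target_vocab)
        if text_top_k is not None:
            text_tok = truncate_vocab(text_tok, text_top_k)
    else:
        text_tok = TextTokenizer()
    return TokenizerPair(smiles=smiles_tok, text=text_tok)
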