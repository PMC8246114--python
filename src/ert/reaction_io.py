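"""Enzyme-annotated reaction records and parallel training corpora.

A curated record couples precursor and product SMILES with the free-text
sentence describing the enzyme (name, source organism, strain, mutations).
Two on-disk layouts are supported:

* **tabular** — UTF-8 TSV with header
  ``reactants\tproducts\tenzyme_text\tsource_id``, one record per line;
* **parallel** — machine-translation-style ``<name>.src.txt`` /
  ``<name>.tgt.txt``
  pairs, one space-separated pre-tokenized line per record, with the
  reserved ``[SEP]`` token separating the SMILES segment from the enzyme
  sentence on the source side.

All SMILES handling goes through RDKit. Canonical forms sort dot-separated
molecules by their canonical SMILES so that reagent order can never create
spurious "unique" reactions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: reserved token separating the SMILES and text segments on a source line
SEP_TOKEN = "[SEP]"

_WS = re.compile(r"\s+")


class SmilesParseError(ValueError):
    """Raised when a string cannot be parsed as SMILES."""


def _normalize_text(text: str) -> str:
    """Strip and collapse internal whitespace; reject reserved separators."""
    text = _WS.sub(" ", text.strip())
    return text


@dataclass(frozen=True)
class EnzymaticReaction:
    """One curated enzymatic reaction record.

    Parameters
    ----------
    reactants, products:
        SMILES, possibly multi-molecule (dot-separated).
    enzyme_text:
        Free-text enzyme description; empty string when no enzyme
        annotation exists (general-chemistry records).
    source_id:
        Opaque provenance string.
    """

    reactants: str
    products: str
    enzyme_text: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        if "\n" in self.enzyme_text or "\t" in self.enzyme_text:
            raise ValueError("enzyme_text may not contain newline/tab characters")
        object.__setattr__(self, "enzyme_text", _normalize_text(self.enzyme_text))

    def canonicalized(self) -> "EnzymaticReaction":
        """Return a copy with both SMILES fields canonicalized."""
        return replace(
            self,
            reactants=canonicalize_smiles(self.reactants),
            products=canonicalize_smiles(self.products),
        )

    def dedup_key(self) -> tuple[str, str, str]:
        """Key identifying duplicate entries.

        Duplicates are records with identical reactants, products and
        enzyme description; the text is compared case-insensitively after
        whitespace normalization (the stored text keeps its casing).
        """
        return (self.reactants, self.products, self.enzyme_text.lower())


@dataclass
class ReactionCorpus:
    """Ordered collection of :class:`EnzymaticReaction` records."""

    records: list[EnzymaticReaction] = field(default_factory=list)
    name: str = "corpus"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EnzymaticReaction]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def canonicalize_smiles(s: str) -> str:
    """Return the RDKit-canonical form of ``s``, preserving stereochemistry.

    Dot-separated components are canonicalized individually and sorted by
    their canonical string, making the result independent of the order in
    which molecules were written. Idempotent.

    Raises
    ------
    SmilesParseError
        If ``s`` (or any dot-separated component) is not valid SMILES.
    """
    if not s:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {s!r}")
    canonical = Chem.MolToSmiles(mol, canonical=True)
    parts = sorted(canonical.split("."))
    return ".".join(parts)


def randomize_smiles(s: str, seed: int) -> str:
    """Return a seeded random atom-order rendering of ``s``.

    The output is a valid SMILES for the same molecule(s) — it maps back to
    ``canonicalize_smiles(s)`` — but generally differs from the canonical
    string. Deterministic for a fixed seed.
    """
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {s!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise SmilesParseError(f"no atoms in SMILES: {s!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n).tolist()
    shuffled = Chem.RenumberAtoms(mol, order)
    return Chem.MolToSmiles(shuffled, canonical=False)


def canonicalize_corpus(corpus: ReactionCorpus, drop_invalid: bool = True) -> ReactionCorpus:
    """Canonicalize every record; drop (and count) unparsable ones.

    Records whose reactants or products fail to parse are removed, the same
    treatment given to entries lacking either side altogether.
    """
    kept: list[EnzymaticReaction] = []
    dropped = 0
    for rec in corpus:
        try:
            kept.append(rec.canonicalized())
        except SmilesParseError:
            if not drop_invalid:
                raise
            dropped += 1
    if dropped:
        logger.info("canonicalize_corpus(%s): dropped %d unparsable records", corpus.name, dropped)
    return ReactionCorpus(kept, name=corpus.name)


def deduplicate(corpus: ReactionCorpus) -> ReactionCorpus:
    """Remove duplicate entries, keeping the first occurrence.

    Two records are duplicates when canonical reactants, canonical products
    and normalized enzyme description all coincide. Order-stable; a
    projection (applying it twice changes nothing).
    """
    seen: set[tuple[str, str, str]] = set()
    kept: list[EnzymaticReaction] = []
    for rec in corpus:
        key = rec.dedup_key()
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    return ReactionCorpus(kept, name=corpus.name)


# ---------------------------------------------------------------------------
# serialization

_TABULAR_HEADER = ["reactants", "products", "enzyme_text", "source_id"]


def _parallel_paths(prefix: Path) -> tuple[Path, Path]:
    return (
        prefix.parent / (prefix.name + ".src.txt"),
        prefix.parent / (prefix.name + ".tgt.txt"),
    )


def write_corpus(corpus: ReactionCorpus, path: str | Path, format: str = "tabular") -> None:
    """Serialize a corpus.

    ``format="tabular"`` writes a single TSV at ``path``.
    ``format="parallel"`` treats ``path`` as a prefix and writes
    ``<path>.src.txt`` / ``<path>.tgt.txt`` with pre-tokenized lines
    (atomic SMILES tokens; ``[SEP]`` plus the sentence words when an
    enzyme description is present).
    """
    path = Path(path)
    if format == "tabular":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_TABULAR_HEADER) + "\n")
            for rec in corpus:
                fh.write(
                    f"{rec.reactants}\t{rec.products}\t{rec.enzyme_text}\t{rec.source_id}\n"
                )
    elif format == "parallel":
        from .tokenization import tokenize_smiles

        src_path, tgt_path = _parallel_paths(path)
        with open(src_path, "w", encoding="utf-8") as src, open(
            tgt_path, "w", encoding="utf-8"
        ) as tgt:
            for rec in corpus:
                src_tokens = tokenize_smiles(rec.reactants).tokens
                if rec.enzyme_text:
                    src_tokens = src_tokens + [SEP_TOKEN] + rec.enzyme_text.split(" ")
                src.write(" ".join(src_tokens) + "\n")
                tgt.write(" ".join(tokenize_smiles(rec.products).tokens) + "\n")
    else:
        raise ValueError(f"unknown corpus format: {format!r}")


def read_corpus(path: str | Path, format: str = "tabular", name: str | None = None) -> ReactionCorpus:
    """Read a corpus written by :func:`write_corpus`.

    Malformed lines raise :class:`ValueError` naming the offending line
    number; a parallel pair with differing line counts is rejected.
    """
    path = Path(path)
    if name is None:
        name = path.stem.replace(".src", "").replace(".tgt", "")
    records: list[EnzymaticReaction] = []
    if format == "tabular":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _TABULAR_HEADER:
                raise ValueError(f"{path}: unexpected header {header!r}")
            for lineno, line in enumerate(fh, start=2):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
                records.append(EnzymaticReaction(*fields))
    elif format == "parallel":
        src_path, tgt_path = _parallel_paths(path)
        src_lines = src_path.read_text(encoding="utf-8").splitlines()
        tgt_lines = tgt_path.read_text(encoding="utf-8").splitlines()
        if len(src_lines) != len(tgt_lines):
            raise ValueError(
                f"{src_path} and {tgt_path} differ in length ({len(src_lines)} vs {len(tgt_lines)})"
            )
        for lineno, (src, tgt) in enumerate(zip(src_lines, tgt_lines), start=1):
            if not src or not tgt:
                raise ValueError(f"{src_path}:{lineno}: empty line")
            src_tokens = src.split(" ")
            if SEP_TOKEN in src_tokens:
                sep = src_tokens.index(SEP_TOKEN)
                reactants = "".join(src_tokens[:sep])
                enzyme_text = " ".join(src_tokens[sep + 1 :])
            else:
                reactants = "".join(src_tokens)
                enzyme_text = ""
            records.append(
                EnzymaticReaction(
                    reactants=reactants,
                    products="".join(tgt.split(" ")),
                    enzyme_text=enzyme_text,
                    source_id=f"{name}-{lineno - 1}",
                )
            )
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
    return ReactionCorpus(records, name=name)


def corpus_from_records(
    rows: Iterable[tuple[str, str, str, str]], name: str = "corpus"
) -> ReactionCorpus:
    """Build a corpus from (reactants, products, enzyme_text, source_id) rows."""
    return ReactionCorpus([EnzymaticReaction(*row) for row in rows], name=name)
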