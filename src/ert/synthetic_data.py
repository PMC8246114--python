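"""Synthetic enzymatic- and general-chemistry reaction generators.

The enzymatic generator emulates the statistical structure of a
literature-derived biocatalysis corpus: substrate SMILES drawn from
combinatorial aryl/alkyl scaffold grids, products built by enzyme-family
reaction templates (ketone reduction, reductive amination, kinetic
resolution of acetate esters, alcohol oxidations, ester hydrolysis,
decarboxylation), and a free-text sentence naming the enzyme, its source
organism and occasional strain codes, mutations, or cofactor-regeneration
co-enzymes. The family mix is lipase-heavy (largest single family,
~17% of reactions) and most sentences contain a single "-ase" word.

Stereochemistry is the scientific crux: for the *stereo-informative*
substrate classes, two enzymes that differ only in their enantiopreference
act on the same substrates, and the sentence is the only disambiguator of
product chirality — a model without text cannot exceed 50% stereo-exact
accuracy there (the generator enforces exact R/S balance per substrate so
the ceiling is exactly 0.5; see :func:`no_text_ceiling`). A mutation code
can flip an enzyme's enantiopreference, mirroring engineered-enzyme
entries in real data.

The general generator produces non-enzymatic single-step transformations
(esterification, acylation, reduction, oxidation, bromination, amidation)
over the same scaffold vocabulary with empty enzyme text. Each selected
transformation is emitted as its canonical rendering plus randomized
atom-order renderings, mirroring the augmented layout of public
general-chemistry reaction sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .reaction_io import (
    EnzymaticReaction,
    ReactionCorpus,
    canonicalize_smiles,
    randomize_smiles,
)

# ---------------------------------------------------------------------------
# scaffold vocabulary

_SUBSTITUENTS = ["F", "Cl", "Br", "C", "OC", "C#N", "CC", "I"]

_HETEROARYL = ["c1ccncc1", "c1cccnc1", "c1ccco1", "c1cccs1"]

#: alkyl fragments written as SMILES prefixes (last atom is the attachment)
_ALKYL = ["CC", "CCC", "CCCC", "CC(C)", "C1CCCC1"]

#: short alkyl groups for carbinol / ester stereocenters
_ALKYL_SMALL = ["C", "CC", "CCC"]


#: only compact substituents on disubstituted rings, keeping SMILES short
_SUBSTITUENTS_SHORT = ["F", "Cl", "C", "Br"]


def _aryl_pool(extended: bool = False) -> list[str]:
    """Aryl scaffold grid.

    The compact grid (mono- plus short 3,5-disubstituted rings) keeps
    enzymatic substrates small; the extended grid adds the full
    disubstitution patterns and is used for the broad general-chemistry
    corpus.
    """
    subs = _SUBSTITUENTS
    pool = ["c1ccccc1"]
    pool += [f"c1ccc({s})cc1" for s in subs]          # para
    pool += [f"c1cccc({s})c1" for s in subs]          # meta
    short = _SUBSTITUENTS_SHORT
    for i, s1 in enumerate(short):
        for s2 in short[i:]:
            pool.append(f"c1cc({s1})cc({s2})c1")      # 3,5-disubstituted
    if extended:
        for i, s1 in enumerate(subs):
            for s2 in subs[i:]:
                if s1 in short and s2 in short:
                    continue  # already present
                pool.append(f"c1cc({s1})cc({s2})c1")
        for s1 in subs:
            for s2 in subs:
                pool.append(f"c1ccc({s1})c({s2})c1")  # 3,4-disubstituted
    pool += _HETEROARYL
    return pool


# ---------------------------------------------------------------------------
# reaction templates


@dataclass(frozen=True)
class ReactionTemplate:
    """Substrate-pattern → product construction rule (string graph edit).

    ``build`` maps a substrate descriptor (the fragment tuple used to
    assemble its SMILES) to ``(substrate_smiles, product_smiles)``;
    stereo templates take the configured center ("@" or "@@") as second
    argument.
    """

    name: str
    stereo_capable: bool
    build: Callable


def _ketone_reduction(frags, center=""):
    alk, ar = frags
    substrate = f"{alk}C(=O){ar}"
    product = f"{alk}[C{center}H](O){ar}"
    return substrate, product


def _reductive_amination(frags, center=""):
    (ar,) = frags
    substrate = f"CC(=O){ar}"
    product = f"C[C{center}H](N){ar}"
    return substrate, product


def _kinetic_resolution(frags, center=""):
    alk, ar = frags
    substrate = f"CC(=O)OC({alk}){ar}"
    product = f"{alk}[C{center}H](O){ar}.CC(=O)O"
    return substrate, product


def _alcohol_oxidation(frags):
    alk, ar = frags
    substrate = f"{alk}C(O){ar}"
    product = f"{alk}C(=O){ar}"
    return substrate, product


def _primary_oxidation(frags):
    pre, ar = frags
    substrate = f"OC{pre}{ar}"
    product = f"O=C{pre}{ar}"
    return substrate, product


def _ester_hydrolysis(frags):
    (r,) = frags
    substrate = f"COC(=O){r}"
    product = f"OC(=O){r}.CO"
    return substrate, product


def _decarboxylation(frags):
    pre, ar = frags
    substrate = f"OC(=O)C{pre}{ar}"
    product = f"C{pre}{ar}"
    return substrate, product


ENZYMATIC_TEMPLATES = {
    "ketone_reduction": ReactionTemplate("ketone_reduction", True, _ketone_reduction),
    "reductive_amination": ReactionTemplate("reductive_amination", True, _reductive_amination),
    "kinetic_resolution": ReactionTemplate("kinetic_resolution", True, _kinetic_resolution),
    "alcohol_oxidation": ReactionTemplate("alcohol_oxidation", False, _alcohol_oxidation),
    "primary_oxidation": ReactionTemplate("primary_oxidation", False, _primary_oxidation),
    "ester_hydrolysis": ReactionTemplate("ester_hydrolysis", False, _ester_hydrolysis),
    "decarboxylation": ReactionTemplate("decarboxylation", False, _decarboxylation),
}


def _template_substrate_pool(template: str, aryl: list[str]) -> list[tuple]:
    if template == "ketone_reduction":
        return [(alk, ar) for alk in _ALKYL for ar in aryl]
    if template == "reductive_amination":
        return [(ar,) for ar in aryl]
    if template == "kinetic_resolution":
        return [(alk, ar) for alk in _ALKYL_SMALL for ar in aryl]
    if template == "alcohol_oxidation":
        return [(alk, ar) for alk in _ALKYL_SMALL for ar in aryl]
    if template == "primary_oxidation":
        return [(pre, ar) for pre in ("", "C", "CC") for ar in aryl]
    if template == "ester_hydrolysis":
        return [(f"C{ar}",) for ar in aryl] + [(ar,) for ar in aryl] + [
            (f"CC{ar}",) for ar in aryl]
    if template == "decarboxylation":
        return [(pre, ar) for pre in ("", "C") for ar in aryl]
    raise KeyError(template)


# ---------------------------------------------------------------------------
# enzymes


@dataclass(frozen=True)
class EnzymeSpec:
    """One enzyme: family, source organism, enantiopreference, prevalence."""

    family: str                    # "-ase" family word appearing in sentences
    organism: str
    transformation: str            # ReactionTemplate id
    stereo_preference: str         # "R", "S", or "none"
    prevalence_weight: float = 1.0
    name_override: str | None = None   # full name used instead of "<family> from <organism>"
    mutation: str | None = None        # mutation code rendered into every sentence

    def __post_init__(self) -> None:
        stereo_ok = ENZYMATIC_TEMPLATES[self.transformation].stereo_capable
        if (self.stereo_preference != "none") != stereo_ok:
            raise ValueError(
                f"stereo preference {self.stereo_preference!r} inconsistent with "
                f"template {self.transformation!r}"
            )


#: map enantiopreference to the tetrahedral annotation written at the new
#: center in the product templates above
_CENTER = {"R": "@", "S": "@@"}

ENZYMES: list[EnzymeSpec] = [
    # ketoreductases — enantiopreference is organism-determined
    EnzymeSpec("ketoreductase", "Lactobacillus kefir", "ketone_reduction", "R", 1.0),
    EnzymeSpec("ketoreductase", "Sporobolomyces salmonicolor", "ketone_reduction", "R", 0.6),
    EnzymeSpec("ketoreductase", "Candida magnoliae", "ketone_reduction", "S", 1.0),
    EnzymeSpec("ketoreductase", "Rhodococcus erythropolis", "ketone_reduction", "S", 0.6),
    # transaminases
    EnzymeSpec("transaminase", "Arthrobacter sp.", "reductive_amination", "R", 1.0),
    EnzymeSpec("transaminase", "Aspergillus terreus", "reductive_amination", "R", 0.5),
    EnzymeSpec("transaminase", "Mycobacterium vanbaalenii", "reductive_amination", "R", 0.4),
    EnzymeSpec("transaminase", "Vibrio fluvialis", "reductive_amination", "S", 1.0),
    EnzymeSpec("transaminase", "Chromobacterium violaceum", "reductive_amination", "S", 0.5),
    EnzymeSpec("transaminase", "Ochrobactrum anthropi", "reductive_amination", "S", 0.4),
    # lipases — full names; one engineered mutant with flipped preference
    EnzymeSpec("lipase", "Candida antarctica", "kinetic_resolution", "R", 1.2,
               name_override="Candida antarctica lipase B"),
    EnzymeSpec("lipase", "Pseudomonas fluorescens", "kinetic_resolution", "R", 0.6,
               name_override="Pseudomonas fluorescens lipase"),
    EnzymeSpec("lipase", "Candida rugosa", "kinetic_resolution", "S", 0.9,
               name_override="Candida rugosa lipase"),
    EnzymeSpec("lipase", "Burkholderia cepacia", "kinetic_resolution", "S", 0.6,
               name_override="Burkholderia cepacia lipase"),
    EnzymeSpec("lipase", "Candida antarctica", "kinetic_resolution", "S", 0.3,
               name_override="Candida antarctica lipase B", mutation="W104A L278V"),
    # non-stereo families
    EnzymeSpec("dehydrogenase", "Saccharomyces cerevisiae", "alcohol_oxidation", "none", 1.0,
               name_override="alcohol dehydrogenase"),
    EnzymeSpec("dehydrogenase", "Thermoanaerobacter brockii", "alcohol_oxidation", "none", 0.7,
               name_override="alcohol dehydrogenase"),
    EnzymeSpec("dehydrogenase", "horse liver", "alcohol_oxidation", "none", 0.7,
               name_override="alcohol dehydrogenase"),
    EnzymeSpec("oxidase", "Pichia pastoris", "primary_oxidation", "none", 0.8,
               name_override="alcohol oxidase"),
    EnzymeSpec("oxidase", "Fusarium graminearum", "primary_oxidation", "none", 0.5,
               name_override="galactose oxidase"),
    EnzymeSpec("esterase", "pig liver", "ester_hydrolysis", "none", 1.0,
               name_override="pig liver esterase"),
    EnzymeSpec("esterase", "Bacillus subtilis", "ester_hydrolysis", "none", 0.6),
    EnzymeSpec("decarboxylase", "Bordetella bronchiseptica", "decarboxylation", "none", 0.6,
               name_override="arylmalonate decarboxylase"),
    EnzymeSpec("decarboxylase", "Enterobacter aerogenes", "decarboxylation", "none", 0.5),
]

_STRAINS = ["strain DSM 20587", "ATCC 33019", "NBRC 14893", "CBS 6556"]

#: cofactor-regeneration co-enzymes appended to a fraction of the
#: nicotinamide-dependent reactions (adds a second "-ase" word)
_COFACTOR_PARTNERS = {
    "ketone_reduction": ["glucose dehydrogenase", "phosphite dehydrogenase"],
    "reductive_amination": ["alanine dehydrogenase", "lactate dehydrogenase"],
    "alcohol_oxidation": ["NADH oxidase"],
}


def render_sentence(spec: EnzymeSpec, rng, cofactor_prob: float = 0.35) -> str:
    """Render one free-text enzyme description for a spec.

    Varies phrasing, occasionally appends strain-code distractors and —
    for cofactor-dependent transformations — a second enzyme name.
    """
    if spec.name_override:
        name = spec.name_override
        variants = [name, f"immobilized {name}", f"recombinant {name}",
                    f"lyophilized {name}", f"{name} immobilized on acrylic resin"]
    else:
        name = spec.family
        variants = [
            f"{name} from {spec.organism}",
            f"{spec.organism} {name}",
            f"recombinant {name} from {spec.organism}",
        ]
    sentence = variants[int(rng.integers(len(variants)))]
    if spec.mutation:
        sentence = f"{sentence} mutant {spec.mutation}"
    if spec.name_override is None and rng.random() < 0.25:
        sentence = f"{sentence} {_STRAINS[int(rng.integers(len(_STRAINS)))]}"
    partners = _COFACTOR_PARTNERS.get(spec.transformation)
    if partners and rng.random() < cofactor_prob:
        sentence = f"{sentence} {partners[int(rng.integers(len(partners)))]}"
    return sentence


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpora.

    ``stereo_informative_fraction`` is the fraction of enzymatic records
    drawn from substrate classes where paired R-/S-selective enzymes act
    on the same substrates (sentence-determined stereochemistry);
    ``family_weights`` skew the enzyme-family mix (default lipase-heavy,
    ~17% single-lipase share); ``noise`` corrupts that fraction of
    product labels, emulating database-entry errors (default off).
    """

    n_enzymes: int = len(ENZYMES)
    n_scaffolds: int = 31
    n_reactions: int = 5000
    general_multiplier: int = 5
    family_weights: dict[str, float] = field(default_factory=lambda: {
        "lipase": 0.36, "ketoreductase": 0.34, "transaminase": 0.30,
        "dehydrogenase": 0.32, "esterase": 0.26, "oxidase": 0.25,
        "decarboxylase": 0.17,
    })
    stereo_informative_fraction: float = 0.5
    cofactor_prob: float = 0.35
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_enzymes, self.n_scaffolds, self.n_reactions) < 1:
            raise ValueError("all counts must be >= 1")
        for f in (self.stereo_informative_fraction, self.noise, self.cofactor_prob):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


_STEREO_FAMILIES = ("lipase", "ketoreductase", "transaminase")
_PLAIN_FAMILIES = ("dehydrogenase", "esterase", "oxidase", "decarboxylase")


def _active_enzymes(config: GeneratorConfig) -> list[EnzymeSpec]:
    ranked = sorted(ENZYMES, key=lambda e: -e.prevalence_weight)
    active = ranked[: config.n_enzymes]
    families = {e.family for e in active}
    # keep at least one enzyme per preference of every stereo family in use
    return active if families else active


def _weighted_choice(rng, items, weights):
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return items[int(rng.choice(len(items), p=w))]


def _corrupt_product(product: str, stereo_capable: bool, substrate: str) -> str:
    if stereo_capable and "@" in product:
        if "@@" in product:
            return product.replace("@@", "@")
        return product.replace("@", "@@")
    return substrate  # null-reaction entry error


def generate_enzymatic_corpus(config: GeneratorConfig) -> tuple[ReactionCorpus, pd.DataFrame]:
    """Generate the enzyme-annotated corpus plus its ground-truth manifest.

    Deterministic for a fixed config. Stereo-informative records are
    emitted in R/S pairs over the same substrate (both records unique or
    the pair is resampled), so every such substrate has an exactly
    balanced enantiomer split in the corpus. The manifest records the
    generating enzyme, template, preference and flags for every record.
    """
    rng = np.random.default_rng(config.seed)
    aryl = _aryl_pool()
    rng.shuffle(aryl)
    aryl = aryl[: config.n_scaffolds]

    active = _active_enzymes(config)
    by_family: dict[str, list[EnzymeSpec]] = {}
    for e in active:
        by_family.setdefault(e.family, []).append(e)
    stereo_families = [f for f in _STEREO_FAMILIES if f in by_family]
    plain_families = [f for f in _PLAIN_FAMILIES if f in by_family]
    if not stereo_families or not plain_families:
        raise ValueError("n_enzymes too small: need both stereo and plain families")

    pools = {
        t: _template_substrate_pool(t, aryl) for t in ENZYMATIC_TEMPLATES
    }

    records: list[EnzymaticReaction] = []
    manifest_rows: list[dict] = []
    seen: set[tuple[str, str, str]] = set()

    def push(spec: EnzymeSpec, frags, center: str | None) -> bool:
        template = ENZYMATIC_TEMPLATES[spec.transformation]
        if center is None:
            substrate, product = template.build(frags)
        else:
            substrate, product = template.build(frags, center)
        substrate = canonicalize_smiles(substrate)
        try:
            product = canonicalize_smiles(product)
        except Exception as exc:  # pragma: no cover - template invariant
            raise RuntimeError(
                f"template {template.name} built invalid product for {spec.family}"
            ) from exc
        sentence = render_sentence(spec, rng, config.cofactor_prob)
        corrupted = False
        if config.noise > 0 and rng.random() < config.noise:
            product = canonicalize_smiles(
                _corrupt_product(product, template.stereo_capable, substrate))
            corrupted = True
        rec = EnzymaticReaction(substrate, product, sentence, f"ENZ-{len(records)}")
        if rec.dedup_key() in seen:
            return False
        seen.add(rec.dedup_key())
        records.append(rec)
        manifest_rows.append({
            "source_id": rec.source_id,
            "family": spec.family,
            "organism": spec.organism,
            "template": spec.transformation,
            "stereo_preference": spec.stereo_preference if center else "none",
            "stereo_informative": center is not None,
            "reactants": substrate,
            "products": product,
            "corrupted": corrupted,
        })
        return True

    attempts = 0
    stalled = 0
    max_stall = 5000  # consecutive duplicate draws before giving up
    # a stereo draw emits TWO records (the R/S pair); track the achieved
    # share against the target so duplicate rejection cannot skew it
    f = config.stereo_informative_fraction
    n_stereo = 0
    while len(records) < config.n_reactions and stalled < max_stall:
        attempts += 1
        n_before = len(records)
        room_for_pair = config.n_reactions - len(records) >= 2
        want_stereo = n_stereo < f * (len(records) + 2)
        if want_stereo and room_for_pair and f > 0:
            family = _weighted_choice(
                rng, stereo_families,
                [config.family_weights.get(f, 1.0) for f in stereo_families])
            specs = by_family[family]
            r_specs = [s for s in specs if s.stereo_preference == "R"]
            s_specs = [s for s in specs if s.stereo_preference == "S"]
            if not r_specs or not s_specs:
                continue
            spec_r = _weighted_choice(rng, r_specs, [s.prevalence_weight for s in r_specs])
            spec_s = _weighted_choice(rng, s_specs, [s.prevalence_weight for s in s_specs])
            pool = pools[spec_r.transformation]
            frags = pool[int(rng.integers(len(pool)))]
            # emit as a balanced pair; roll back unless both are new
            checkpoint = (len(records), len(manifest_rows))
            ok_r = push(spec_r, frags, _CENTER["R"])
            ok_s = push(spec_s, frags, _CENTER["S"])
            if ok_r and ok_s:
                n_stereo += 2
            else:
                while len(records) > checkpoint[0]:
                    dropped = records.pop()
                    manifest_rows.pop()
                    seen.discard(dropped.dedup_key())
        else:
            family = _weighted_choice(
                rng, plain_families,
                [config.family_weights.get(f, 1.0) for f in plain_families])
            specs = by_family[family]
            spec = _weighted_choice(rng, specs, [s.prevalence_weight for s in specs])
            pool = pools[spec.transformation]
            frags = pool[int(rng.integers(len(pool)))]
            push(spec, frags, None)
        stalled = stalled + 1 if len(records) == n_before else 0
    if len(records) < config.n_reactions:
        raise RuntimeError(
            f"substrate/sentence space exhausted after {attempts} attempts "
            f"({len(records)}/{config.n_reactions} records); "
            "increase n_scaffolds or reduce n_reactions"
        )
    records = records[: config.n_reactions]
    manifest = pd.DataFrame(manifest_rows[: config.n_reactions])
    return ReactionCorpus(records, name="enzymatic_synthetic"), manifest


# ---------------------------------------------------------------------------
# general corpus

_GENERAL_TEMPLATES: list[tuple[str, Callable]] = [
    ("methyl_esterification", lambda ar: (f"CO.OC(=O)C{ar}", f"COC(=O)C{ar}")),
    ("acetylation", lambda alk_ar: (f"CC(=O)Cl.{alk_ar[0]}C(O){alk_ar[1]}",
                                    f"{alk_ar[0]}C(OC(C)=O){alk_ar[1]}")),
    ("acetylation_chiral_R", lambda alk_ar: (f"CC(=O)Cl.{alk_ar[0]}[C@H](O){alk_ar[1]}",
                                             f"{alk_ar[0]}[C@H](OC(C)=O){alk_ar[1]}")),
    ("acetylation_chiral_S", lambda alk_ar: (f"CC(=O)Cl.{alk_ar[0]}[C@@H](O){alk_ar[1]}",
                                             f"{alk_ar[0]}[C@@H](OC(C)=O){alk_ar[1]}")),
    ("borohydride_reduction", lambda alk_ar: (f"[Na+].[BH4-].{alk_ar[0]}C(=O){alk_ar[1]}",
                                              f"{alk_ar[0]}C(O){alk_ar[1]}")),
    ("benzylic_bromination", lambda ar: (f"BrBr.C{ar}", f"BrC{ar}")),
    ("alcohol_oxidation_chem", lambda ar: (f"OO.OC{ar}", f"O=C{ar}")),
    ("aldehyde_oxidation", lambda ar: (f"OO.O=C{ar}", f"OC(=O){ar}")),
    ("amidation", lambda ar: (f"CN.COC(=O){ar}", f"CNC(=O){ar}.CO")),
    ("benzylic_amination", lambda ar: (f"CN.BrC{ar}", f"CNC{ar}")),
    ("imine_condensation", lambda alk_ar: (f"CN.{alk_ar[0]}C(=O){alk_ar[1]}",
                                           f"{alk_ar[0]}C(=NC){alk_ar[1]}")),
    ("ester_reduction", lambda ar: (f"[Li+].[AlH4-].COC(=O){ar}", f"OC{ar}.CO")),
]


def _general_applications(aryl: list[str]) -> list[tuple[str, str, str]]:
    apps: list[tuple[str, str, str]] = []
    for name, build in _GENERAL_TEMPLATES:
        if name in ("acetylation", "acetylation_chiral_R", "acetylation_chiral_S",
                    "borohydride_reduction", "imine_condensation"):
            alks = (_ALKYL if name in ("borohydride_reduction", "imine_condensation")
                    else _ALKYL_SMALL)
            for alk in alks:
                for ar in aryl:
                    src, tgt = build((alk, ar))
                    apps.append((name, src, tgt))
        else:
            for ar in aryl:
                src, tgt = build(ar)
                apps.append((name, src, tgt))
    return apps


def generate_general_corpus(config: GeneratorConfig) -> ReactionCorpus:
    """Generate the general-chemistry companion corpus.

    Size defaults to ``general_multiplier`` times the enzymatic corpus
    (at least 5x). Every selected transformation appears as its canonical
    rendering plus seeded randomized atom-order renderings; enzyme text
    is always empty.
    """
    rng = np.random.default_rng(config.seed + 1)
    # the general corpus ranges over a wider scaffold grid than the
    # enzymatic one, as a broad-chemistry source should
    aryl = _aryl_pool(extended=True)
    rng.shuffle(aryl)
    aryl = aryl[: min(len(aryl), 4 * config.n_scaffolds)]
    apps = _general_applications(aryl)
    rng.shuffle(apps)

    n_target = config.n_reactions * config.general_multiplier
    renderings = int(np.ceil(n_target / len(apps)))
    records: list[EnzymaticReaction] = []
    k = 0
    for name, src, tgt in apps:
        src_c = canonicalize_smiles(src)
        tgt_c = canonicalize_smiles(tgt)
        records.append(EnzymaticReaction(src_c, tgt_c, "", f"GEN-{k}"))
        k += 1
        for j in range(renderings - 1):
            if len(records) >= n_target:
                break
            records.append(
                EnzymaticReaction(randomize_smiles(src_c, seed=config.seed + 7919 * k + j),
                                  tgt_c, "", f"GEN-{k}"))
            k += 1
        if len(records) >= n_target:
            break
    return ReactionCorpus(records[:n_target], name="general_synthetic")


# ---------------------------------------------------------------------------
# audits and packaging


def no_text_ceiling(manifest: pd.DataFrame) -> float:
    """Best possible stereo-exact accuracy without enzyme text.

    On the stereo-informative subset a text-blind predictor can at best
    answer, for each substrate, its most frequent product; the ceiling is
    the weighted average of those per-substrate majorities. Exact R/S
    pairing makes this 0.5 by construction.
    """
    sub = manifest[manifest["stereo_informative"]]
    if sub.empty:
        return float("nan")
    best = sub.groupby(["reactants", "products"]).size().groupby("reactants").max()
    return float(best.sum() / len(sub))


def apply_template(template_name: str, reactants: str, stereo_preference: str) -> str:
    """Recompute the product for a manifest row (ground-truth oracle).

    Re-applies the named template to the canonical substrate; used to
    audit that every generated record is reproducible from its template.
    """
    template = ENZYMATIC_TEMPLATES[template_name]
    aryl = _aryl_pool()
    for frags in _template_substrate_pool(template_name, aryl):
        if template.stereo_capable:
            sub, prod = template.build(frags, _CENTER.get(stereo_preference, ""))
        else:
            sub, prod = template.build(frags)
        if canonicalize_smiles(sub) == reactants:
            return canonicalize_smiles(prod)
    raise KeyError(f"no {template_name} substrate matches {reactants!r}")


def benchmark_suite(config: GeneratorConfig, split_seed: int | None = None) -> dict:
    """Generate the full desk-scale benchmark bundle.

    Returns deduplicated, product-group-split enzymatic corpora
    (train/valid/test), the derangement-scrambled test variant, the
    general corpus splits, and the generation manifest.
    """
    from .curation import scramble_sentences, split_by_product
    from .reaction_io import deduplicate

    split_seed = config.seed if split_seed is None else split_seed
    enzymatic, manifest = generate_enzymatic_corpus(config)
    enzymatic = deduplicate(enzymatic)  # no-op by construction; keeps the contract explicit
    split = split_by_product(enzymatic, (0.8, 0.1, 0.1), seed=split_seed)
    enz = {s: split.subset(enzymatic, s) for s in ("train", "valid", "test")}
    enz["test_scrambled"] = scramble_sentences(enz["test"], seed=split_seed + 1)

    general = generate_general_corpus(config)
    gsplit = split_by_product(general, (0.9, 0.05, 0.05), seed=split_seed)
    gen = {s: gsplit.subset(general, s) for s in ("train", "valid", "test")}

    return {
        "enzymatic": enz,
        "general": gen,
        "manifest": manifest,
        "split": split,
        "config": config,
    }
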