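"""Readers, writers and validators for the study's input tables.

The analysis consumes six kinds of input:

* a species metadata table (oxygen requirement, multicellularity, lifestyle,
  growth-temperature class, genome-completion year),
* oxic/anoxic classification lists keyed by EC numbers and by KEGG-style
  reaction (R) numbers,
* reaction→compound links in the ``reaction_mapformula.lst`` dialect
  (primary substrates/products only, no cofactors),
* a rooted newick phylogeny (handled by :mod:`oxymet.phylo_comparative`),
* a compound × chemoinformatic-descriptor property table,
* per-genome protein annotation tables.

This module owns the file dialects, the domain containers, the metabolite
oxic/anoxic derivation and the species-selection filters (tree-restricted
mode and the non-redundant one-species-per-genus group mode).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger("oxymet")

# ---------------------------------------------------------------------------
# Controlled vocabularies and identifier syntax
# ---------------------------------------------------------------------------

DOMAINS = frozenset({"bacteria", "archaea", "eukaryote"})
OXYGEN_REQUIREMENTS = frozenset({"aerobic", "facultative", "anaerobic"})
LIFESTYLES = frozenset({"free_living", "symbiotic_or_parasitic"})
THERMO_CLASSES = frozenset({"mesophile", "other"})

#: Descriptors reported in the six-descriptor summary table; property tables
#: may carry up to 84 columns, but these must be recognised.
CANONICAL_DESCRIPTORS = ("AlogP98", "SOL", "FNSA", "FPSA", "pLC50", "RotBonds")

# EC dotted quad; trailing fields may be '-' wildcards.  Wildcards are matched
# only exactly, never expanded as prefixes.
EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")
R_RE = re.compile(r"^R\d{5}$")
C_RE = re.compile(r"^C\d{5}$")

METADATA_COLUMNS = (
    "organism_id",
    "domain",
    "oxygen_requirement",
    "multicellular",
    "lifestyle",
    "thermo_class",
    "genome_year",
)

_BOOL_CODES = {
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "yes": True,
    "no": False,
}


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesRecord:
    """Phenotype metadata for one organism."""

    organism_id: str
    domain: str
    oxygen_requirement: str
    multicellular: bool
    lifestyle: str
    thermo_class: str
    genome_year: int
    species_name: str | None = None
    genus: str | None = None

    def genus_key(self) -> str:
        """Genus used for the one-species-per-genus redundancy filter.

        An explicit genus column wins; otherwise the first whitespace token
        of the species name is used.
        """
        if self.genus:
            return self.genus
        if self.species_name:
            return self.species_name.split()[0]
        raise ValidationError(
            f"no genus derivable for {self.organism_id!r}: "
            "need a 'genus' or 'species_name' column"
        )


@dataclass
class OxygenClassification:
    """Global oxic/anoxic partition of enzymes, reactions and metabolites."""

    oxic_enzymes: frozenset[str] = frozenset()
    anoxic_enzymes: frozenset[str] = frozenset()
    oxic_reactions: frozenset[str] = frozenset()
    anoxic_reactions: frozenset[str] = frozenset()
    oxic_metabolites: frozenset[str] = frozenset()
    anoxic_metabolites: frozenset[str] = frozenset()
    #: reactions whose metabolites are excluded from the metabolite analysis
    #: (oxic intermediates of "augmented" reactions).
    augmented_reactions: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ReactionLink:
    """Primary substrates/products of one reaction (cofactors excluded)."""

    substrates: frozenset[str]
    products: frozenset[str]
    direction: str  # forward | reverse | reversible

    @property
    def metabolites(self) -> frozenset[str]:
        return self.substrates | self.products


@dataclass(frozen=True)
class SpeciesNetwork:
    """One species' metabolic repertoire as plain identifier sets."""

    organism_id: str
    enzymes: frozenset[str]
    reactions: frozenset[str]
    metabolites: frozenset[str]


# ---------------------------------------------------------------------------
# Species metadata
# ---------------------------------------------------------------------------

def _sniff_delimiter(header_line: str) -> str:
    # UTF-8 text; tab preferred over comma when both occur.
    return "\t" if "\t" in header_line else ","


def _norm_enum(value: str, vocabulary: frozenset[str], column: str):
    v = str(value).strip().lower()
    if v in vocabulary:
        return v
    raise ValueError(f"unmappable {column} value {value!r}")


def read_species_metadata(path, dialect: str | None = None) -> list[SpeciesRecord]:
    """Read a species metadata table (TSV or CSV).

    Enum-like columns are normalised case-insensitively to their canonical
    codes.  Rows whose enum values cannot be mapped are rejected and reported
    in a single warning (never silently dropped); duplicated organism ids are
    a hard validation error.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    sep = dialect or _sniff_delimiter(first)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[SpeciesRecord] = []
    rejected: list[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = SpeciesRecord(
                organism_id=str(row.organism_id).strip(),
                domain=_norm_enum(row.domain, DOMAINS, "domain"),
                oxygen_requirement=_norm_enum(
                    row.oxygen_requirement, OXYGEN_REQUIREMENTS, "oxygen_requirement"
                ),
                multicellular=_parse_bool(row.multicellular),
                lifestyle=_norm_enum(row.lifestyle, LIFESTYLES, "lifestyle"),
                thermo_class=_norm_enum(row.thermo_class, THERMO_CLASSES, "thermo_class"),
                genome_year=int(row.genome_year),
                species_name=_opt(getattr(row, "species_name", None)),
                genus=_opt(getattr(row, "genus", None)),
            )
        except (ValueError, TypeError) as exc:
            rejected.append(f"line {row_no}: {exc}")
            continue
        records.append(rec)
    if rejected:
        logger.warning(
            "%s: rejected %d row(s) with unmappable values: %s",
            path, len(rejected), "; ".join(rejected),
        )
    ids = [r.organism_id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate organism_id(s): {', '.join(dupes)}")
    return records


def _parse_bool(value) -> bool:
    v = str(value).strip().lower()
    if v not in _BOOL_CODES:
        raise ValueError(f"unmappable boolean value {value!r}")
    return _BOOL_CODES[v]


def _opt(value) -> str | None:
    if value is None:
        return None
    v = str(value).strip()
    return v if v and v.lower() != "nan" else None


def write_species_metadata(records: Iterable[SpeciesRecord], path) -> None:
    records = list(records)
    has_name = any(r.species_name for r in records)
    has_genus = any(r.genus for r in records)
    cols = list(METADATA_COLUMNS)
    if has_name:
        cols.append("species_name")
    if has_genus:
        cols.append("genus")
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [
                r.organism_id, r.domain, r.oxygen_requirement,
                "true" if r.multicellular else "false",
                r.lifestyle, r.thermo_class, str(r.genome_year),
            ]
            if has_name:
                row.append(r.species_name or "")
            if has_genus:
                row.append(r.genus or "")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Classification lists (one identifier per line)
# ---------------------------------------------------------------------------

def read_id_list(path, pattern: re.Pattern, kind: str) -> frozenset[str]:
    """Read a one-identifier-per-line file; '#' comments and blanks allowed."""
    path = Path(path)
    ids: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if not pattern.match(line):
                raise ParseError(f"invalid {kind} identifier {line!r}", path, line_no)
            ids.add(line)
    return frozenset(ids)


def write_id_list(ids: Iterable[str], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for i in sorted(ids):
            fh.write(i + "\n")


def read_classification_lists(
    oxic_enzymes_path,
    anoxic_enzymes_path,
    oxic_reactions_path,
    anoxic_reactions_path,
    augmented_reactions_path=None,
) -> OxygenClassification:
    """Load the oxic/anoxic EC and R lists into an :class:`OxygenClassification`.

    Every loaded set must be non-empty (an empty list means the analysis
    cannot proceed); the augmented-reaction list is optional and may be empty.
    """
    cls = OxygenClassification(
        oxic_enzymes=read_id_list(oxic_enzymes_path, EC_RE, "EC"),
        anoxic_enzymes=read_id_list(anoxic_enzymes_path, EC_RE, "EC"),
        oxic_reactions=read_id_list(oxic_reactions_path, R_RE, "R"),
        anoxic_reactions=read_id_list(anoxic_reactions_path, R_RE, "R"),
        augmented_reactions=(
            read_id_list(augmented_reactions_path, R_RE, "R")
            if augmented_reactions_path is not None
            else frozenset()
        ),
    )
    for name in ("oxic_enzymes", "anoxic_enzymes", "oxic_reactions", "anoxic_reactions"):
        members = getattr(cls, name)
        if not members:
            raise ValidationError(f"classification list {name} is empty")
        logger.info("loaded %d %s", len(members), name)
    return cls


# ---------------------------------------------------------------------------
# reaction_mapformula.lst dialect
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "=>", "<=")  # longest token first
_DIRECTION = {"=>": "forward", "<=": "reverse", "<=>": "reversible"}


def _parse_side(text: str, path, line_no: int) -> frozenset[str]:
    compounds = set()
    for token in text.split("+"):
        token = token.strip()
        if not C_RE.match(token):
            raise ParseError(f"invalid compound identifier {token!r}", path, line_no)
        compounds.add(token)
    return frozenset(compounds)


def parse_reaction_links(path) -> dict[str, ReactionLink]:
    """Parse reaction→primary-metabolite links.

    Dialect: ``R#####: <map id>: C##### [+ C#####...] <arrow> C##### [...]``
    with arrow one of ``=>``, ``<=``, ``<=>``.  A reaction listed on several
    lines (it appears on several pathway maps) is merged by set union;
    direction is retained (``reversible`` if lines disagree) but is not used
    by any downstream metric.
    """
    path = Path(path)
    links: dict[str, ReactionLink] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(":", 2)
            if len(parts) != 3:
                raise ParseError("expected 'R#####: map: formula'", path, line_no)
            rid = parts[0].strip()
            if not R_RE.match(rid):
                raise ParseError(f"invalid reaction identifier {rid!r}", path, line_no)
            formula = parts[2].strip()
            arrow = next((a for a in _ARROWS if a in formula), None)
            if arrow is None:
                raise ParseError("no arrow token (=>, <=, <=>) in formula", path, line_no)
            lhs, rhs = formula.split(arrow, 1)
            link = ReactionLink(
                substrates=_parse_side(lhs, path, line_no),
                products=_parse_side(rhs, path, line_no),
                direction=_DIRECTION[arrow],
            )
            if rid in links:
                prev = links[rid]
                link = ReactionLink(
                    substrates=prev.substrates | link.substrates,
                    products=prev.products | link.products,
                    direction=prev.direction
                    if prev.direction == link.direction
                    else "reversible",
                )
            links[rid] = link
    return links


_ARROW_OF = {"forward": "=>", "reverse": "<=", "reversible": "<=>"}


def write_reaction_links(links: Mapping[str, ReactionLink], path, map_id: str = "00001") -> None:
    """Write links in the same dialect (one merged line per reaction)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rid in sorted(links):
            link = links[rid]
            lhs = " + ".join(sorted(link.substrates))
            rhs = " + ".join(sorted(link.products))
            fh.write(f"{rid}: {map_id}: {lhs} {_ARROW_OF[link.direction]} {rhs}\n")


# ---------------------------------------------------------------------------
# Reaction → enzyme map and species networks
# ---------------------------------------------------------------------------

def read_reaction_enzymes(path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV mapping R numbers to EC numbers (may repeat)."""
    path = Path(path)
    r2ec: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError("expected 'R<tab>EC'", path, line_no)
            rid, ec = fields[0].strip(), fields[1].strip()
            if not R_RE.match(rid):
                raise ParseError(f"invalid reaction identifier {rid!r}", path, line_no)
            if not EC_RE.match(ec):
                raise ParseError(f"invalid EC identifier {ec!r}", path, line_no)
            r2ec.setdefault(rid, set()).add(ec)
    return {r: frozenset(v) for r, v in r2ec.items()}


def write_reaction_enzymes(r2ec: Mapping[str, Iterable[str]], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for rid in sorted(r2ec):
            for ec in sorted(r2ec[rid]):
                fh.write(f"{rid}\t{ec}\n")


def build_species_network(
    organism_id: str,
    reactions: Iterable[str],
    links: Mapping[str, ReactionLink],
    r2ec: Mapping[str, frozenset[str]],
) -> SpeciesNetwork:
    """Assemble a species network from its reaction repertoire.

    Metabolites derive only from reactions present in the species; enzymes
    are the ECs of those reactions.
    """
    reactions = frozenset(reactions)
    metabolites: set[str] = set()
    enzymes: set[str] = set()
    for rid in reactions:
        if rid in links:
            metabolites |= links[rid].metabolites
        enzymes |= r2ec.get(rid, frozenset())
    net = SpeciesNetwork(
        organism_id=organism_id,
        enzymes=frozenset(enzymes),
        reactions=reactions,
        metabolites=frozenset(metabolites),
    )
    if not net.reactions or not net.metabolites:
        raise ValidationError(f"species network {organism_id!r} is empty")
    return net


# ---------------------------------------------------------------------------
# Metabolite classification (from reaction classification + links)
# ---------------------------------------------------------------------------

OVERLAP_POLICIES = ("anoxic_priority", "oxic_priority", "drop_overlap")


def derive_metabolite_classification(
    cls: OxygenClassification,
    links: Mapping[str, ReactionLink],
    policy: str = "anoxic_priority",
) -> OxygenClassification:
    """Fill the oxic/anoxic metabolite sets from the reaction classification.

    A side's metabolites are the union over its classified reactions of each
    reaction's primary substrates and products, minus the metabolites of
    augmented reactions (intermediates excluded from the chemical analysis).
    A compound reachable from both sides is resolved by ``policy``:

    ``anoxic_priority`` (default)
        assign to the anoxic set — "available without oxygen" is the
        conservative baseline;
    ``oxic_priority``
        assign to the oxic set;
    ``drop_overlap``
        remove from both.

    The returned sets are always disjoint.
    """
    if policy not in OVERLAP_POLICIES:
        raise ValidationError(f"unknown overlap policy {policy!r}")
    if not cls.oxic_reactions or not cls.anoxic_reactions:
        raise ValidationError("oxic/anoxic reaction sets must be non-empty")

    def side(reactions: frozenset[str], label: str) -> set[str]:
        mets: set[str] = set()
        missing = 0
        for rid in reactions:
            if rid in cls.augmented_reactions:
                continue
            if rid not in links:
                missing += 1
                continue
            mets |= links[rid].metabolites
        if missing:
            logger.warning(
                "%d %s reaction(s) absent from reaction links; skipped", missing, label
            )
        return mets

    oxic = side(cls.oxic_reactions, "oxic")
    anoxic = side(cls.anoxic_reactions, "anoxic")
    augmented_mets: set[str] = set()
    for rid in cls.augmented_reactions:
        if rid in links:
            augmented_mets |= links[rid].metabolites
    oxic -= augmented_mets
    anoxic -= augmented_mets

    overlap = oxic & anoxic
    if overlap:
        logger.info("%d compound(s) in both oxic and anoxic sets; policy=%s", len(overlap), policy)
        if policy == "anoxic_priority":
            oxic -= overlap
        elif policy == "oxic_priority":
            anoxic -= overlap
        else:
            oxic -= overlap
            anoxic -= overlap
    return replace(
        cls,
        oxic_metabolites=frozenset(oxic),
        anoxic_metabolites=frozenset(anoxic),
    )


# ---------------------------------------------------------------------------
# Property and annotation tables
# ---------------------------------------------------------------------------

def read_property_table(path, dialect: str | None = None) -> pd.DataFrame:
    """Read the compound × descriptor table; index = compound id.

    Missing values are allowed per compound; present values must be finite.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    sep = dialect or _sniff_delimiter(first)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "compound_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'compound_id'")
    bad = [c for c in df["compound_id"] if not C_RE.match(str(c))]
    if bad:
        raise ValidationError(f"{path}: invalid compound id(s): {bad[:5]}")
    df = df.set_index("compound_id")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate compound id(s): {dupes[:5]}")
    values = df.to_numpy(dtype=float)
    if np.isinf(values).any():
        raise ValidationError(f"{path}: non-finite descriptor values present")
    return df


def write_property_table(df: pd.DataFrame, path) -> None:
    # %.17g keeps doubles exact across a write/read cycle
    df.to_csv(path, sep="\t", index=True, index_label="compound_id", float_format="%.17g")


def read_annotations(path) -> dict[str, list[str]]:
    """Read a two-column TSV ``organism_id<TAB>annotation`` into lists per genome."""
    path = Path(path)
    table: dict[str, list[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t", 1)
            if len(fields) != 2:
                raise ParseError("expected 'organism_id<TAB>annotation'", path, line_no)
            table.setdefault(fields[0].strip(), []).append(fields[1])
    return table


def write_annotations(table: Mapping[str, list[str]], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for org in sorted(table):
            for ann in table[org]:
                fh.write(f"{org}\t{ann}\n")


# ---------------------------------------------------------------------------
# Species selection
# ---------------------------------------------------------------------------

def select_species(
    records: Iterable[SpeciesRecord],
    mode: str,
    tree_tip_labels: Iterable[str] | None = None,
) -> dict[str, list[str]]:
    """Apply the study's species-selection filters.

    ``mode='phylo'``
        restrict to organisms present on the supplied tree (for the
        phylogenetically controlled expansion analysis); returns a single
        group ``{'phylo': [...]}``.  Organisms absent from the tree are
        reported in a warning and dropped.

    ``mode='nonredundant_groups'``
        keep free-living mesophiles only, one species per genus (the one
        with the earliest genome-completion year; ties broken by the
        lexicographically smallest organism id), then split into strictly
        aerobic bacteria (facultative aerobes excluded), unicellular
        eukaryotes and multicellular eukaryotes.  Archaea are excluded.
        Empty groups are omitted with a warning.
    """
    records = list(records)
    if mode == "phylo":
        if tree_tip_labels is None:
            raise ValidationError("mode 'phylo' requires tree tip labels")
        tips = set(tree_tip_labels)
        kept = [r.organism_id for r in records if r.organism_id in tips]
        missing = [r.organism_id for r in records if r.organism_id not in tips]
        if missing:
            logger.warning(
                "%d organism(s) absent from the tree and dropped: %s",
                len(missing), ", ".join(sorted(missing)[:10]),
            )
        return {"phylo": sorted(kept)}

    if mode != "nonredundant_groups":
        raise ValidationError(f"unknown selection mode {mode!r}")

    candidates = [
        r for r in records
        if r.lifestyle == "free_living" and r.thermo_class == "mesophile"
    ]
    by_genus: dict[str, SpeciesRecord] = {}
    for r in sorted(candidates, key=lambda r: (r.genome_year, r.organism_id)):
        by_genus.setdefault(r.genus_key(), r)
    kept = list(by_genus.values())

    groups = {
        "aerobic_bacteria": sorted(
            r.organism_id for r in kept
            if r.domain == "bacteria" and r.oxygen_requirement == "aerobic"
        ),
        "unicellular_eukaryotes": sorted(
            r.organism_id for r in kept
            if r.domain == "eukaryote" and not r.multicellular
        ),
        "multicellular_eukaryotes": sorted(
            r.organism_id for r in kept
            if r.domain == "eukaryote" and r.multicellular
        ),
    }
    for name in list(groups):
        if not groups[name]:
            logger.warning("group %s is empty after filtering; omitted", name)
            del groups[name]
    return groups
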