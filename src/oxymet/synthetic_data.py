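"""Synthetic study generator: trees, traits, networks, descriptors, annotations.

The real study pulls species metadata, oxic/anoxic classification lists,
per-species reaction repertoires, a reference tree of life, chemoinformatic
descriptor tables and protein annotations from external databases.  This
module generates a complete, self-consistent stand-in study with the
statistical structure the analysis assumes, so every pipeline stage can be
exercised and calibrated without downloads:

* a clade-structured phylogeny (Yule subtrees per domain group joined on a
  backbone) with the aerobic/anaerobic state of prokaryotes evolved along
  the tree by a two-state Markov process — anaerobes come out in
  phylogenetically clustered patches;
* a global reaction universe partitioned into oxic / anoxic / unclassified
  reactions, each carrying one EC number and 2–4 primary compounds;
* per-species networks sampled by per-category retention probabilities, with
  a configurable expansion effect (aerobes retain oxic reactions at a higher
  rate) and a configurable "higher-organism-specific" oxic subset retained
  preferentially by multicellular species — the mechanism that recreates the
  integral-network over/underestimation of chemical differences;
* descriptor tables with a common oxic shift (delta_common) plus an extra
  shift on the specific subset (delta_specific), with per-descriptor signs;
* protein annotations with per-oxygen-class functionally-unknown fractions.

Everything is written in the exact dialects :mod:`oxymet.data_model_io`
reads, and identical seeds produce byte-identical studies.
"""

from __future__ import annotations

import math
import random
import re
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .data_model_io import (
    CANONICAL_DESCRIPTORS,
    OxygenClassification,
    ReactionLink,
    SpeciesNetwork,
    SpeciesRecord,
    build_species_network,
    write_annotations,
    write_id_list,
    write_property_table,
    write_reaction_enzymes,
    write_reaction_links,
    write_species_metadata,
)
from .errors import ValidationError
from .phylo_comparative import write_tree

__all__ = [
    "StudyConfig",
    "StudyBundle",
    "simulate_tree",
    "evolve_binary_trait",
    "simulate_brownian",
    "simulate_study_bundle",
    "simulate_study",
    "write_study",
]


# ---------------------------------------------------------------------------
# Elementary simulators
# ---------------------------------------------------------------------------

def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Simulate a Yule (pure-birth) tree conditioned on ``n_tips`` extant tips.

    The pure-birth simulation stops at the n-th birth event, which would
    leave the youngest cherry with zero-length terminal branches; every tip
    edge is therefore extended by one exponential holding time (rate
    n·birth_rate, the waiting time to the next, unobserved, birth), giving
    an ultrametric tree observed strictly between birth events.
    """
    if n_tips < 2:
        raise ValidationError("need at least 2 tips")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    extra = rng.expovariate(n_tips * birth_rate)
    leaves = list(tree.leaf_node_iter())
    for leaf in leaves:
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    if labels is not None:
        if len(labels) != len(leaves):
            raise ValidationError("label count does not match tip count")
        for leaf, label in zip(leaves, labels):
            leaf.taxon.label = label
    return tree


def evolve_binary_trait(
    tree: dendropy.Tree,
    gain: float,
    loss: float,
    root_state: int = 1,
    seed: int = 0,
) -> dict[str, int]:
    """Evolve a two-state (0/1) trait along the tree.

    Continuous-time Markov simulation with transition rates ``gain``
    (0 → 1) and ``loss`` (1 → 0); returns the tip states keyed by label.
    """
    if gain < 0 or loss < 0 or (gain == 0 and loss == 0):
        raise ValidationError("rates must be nonnegative and not both zero")
    rng = random.Random(seed)
    state: dict[dendropy.Node, int] = {}
    tips: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            s = int(root_state)
        else:
            s = state[node.parent_node]
            t = float(node.edge.length or 0.0)
            while True:
                rate = loss if s == 1 else gain
                if rate == 0.0:
                    break
                wait = rng.expovariate(rate)
                if wait >= t:
                    break
                t -= wait
                s = 1 - s
        state[node] = s
        if node.is_leaf():
            tips[node.taxon.label] = s
    return tips


def simulate_brownian(
    tree: dendropy.Tree,
    sigma: float = 1.0,
    root_value: float = 0.0,
    seed: int = 0,
) -> dict[str, float]:
    """Brownian-motion response on a tree: increments ~ N(0, sigma²·branch)."""
    rng = np.random.default_rng(seed)
    value: dict[dendropy.Node, float] = {}
    tips: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            v = root_value
        else:
            t = float(node.edge.length or 0.0)
            v = value[node.parent_node] + rng.normal(0.0, sigma * math.sqrt(t))
        value[node] = v
        if node.is_leaf():
            tips[node.taxon.label] = v
    return tips


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Knobs of the synthetic study.

    Group sizes default to the study's realized species counts (134
    prokaryotes of which ~1/4 anaerobic at the trait model's stationary
    distribution, 18 archaea, 33 unicellular and 34 multicellular
    eukaryotes).  ``delta_common`` is the oxic descriptor shift shared by all
    species; ``delta_specific`` is the extra shift on the higher-organism-
    specific oxic subset whose preferential retention by multicellular
    species recreates the integral-network estimation bias.
    """

    # tree & traits
    n_bacteria: int = 134
    n_archaea: int = 18
    n_unicellular_eukaryotes: int = 33
    n_multicellular_eukaryotes: int = 34
    birth_rate: float = 1.0
    clade_stem_length: float = 1.0
    trait_gain: float = 0.45  # anaerobic -> aerobic, per unit branch length
    trait_loss: float = 0.15  # aerobic -> anaerobic
    facultative_fraction: float = 0.3
    symbiotic_fraction: float = 0.1
    thermophile_fraction: float = 0.1
    genus_size: int = 2
    year_min: int = 1996
    year_max: int = 2013
    # reaction universe (counts mirror the classified enzyme/metabolite
    # universe of the real oxic/anoxic database: ~2850 classified reactions,
    # ~2900 compounds of which ~60% have resolvable structures)
    n_global_reactions: int = 3200
    n_global_compounds: int = 2900
    oxic_fraction: float = 0.57  # of classified reactions (≈ 1627/(1627+1225))
    unclassified_fraction: float = 0.10
    augmented_fraction: float = 0.05
    specific_fraction: float = 0.20
    min_compounds_per_reaction: int = 2
    max_compounds_per_reaction: int = 4
    cross_pool_fraction: float = 0.05
    # descriptors
    descriptors: tuple[str, ...] = CANONICAL_DESCRIPTORS
    descriptor_signs: tuple[int, ...] = (1, -1, 1, -1, 1, -1)
    descriptor_mean: float = 0.0
    descriptor_sd: float = 1.0
    descriptor_distribution: str = "normal"  # or "lognormal"
    delta_common: float = 0.5
    delta_specific: float = 0.0
    #: compounds without a clearly defined structure carry no descriptors at
    #: all; on top of that, single descriptors can be missing per compound.
    undefined_structure_fraction: float = 0.4
    missing_fraction: float = 0.05
    # network sampling
    p_retain_anoxic: float = 0.7
    p_retain_oxic_aerobe: float = 0.6
    p_retain_oxic_anaerobe: float = 0.25
    p_retain_specific_multicellular: float = 0.7
    p_retain_specific_other: float = 0.05
    p_retain_unclassified: float = 0.5
    #: per-species retention multiplier is drawn from U(1−h, 1): real
    #: genome-scale networks vary severalfold in size, and that size
    #: heterogeneity is what spreads per-species effect sizes.
    retention_heterogeneity: float = 0.6
    # annotations
    n_proteins: int = 200
    unknown_fraction_aerobic: float = 0.35
    unknown_fraction_facultative: float = 0.35
    unknown_fraction_anaerobic: float = 0.35
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        for name in (
            "oxic_fraction", "unclassified_fraction", "augmented_fraction",
            "specific_fraction", "cross_pool_fraction", "facultative_fraction",
            "symbiotic_fraction", "thermophile_fraction", "missing_fraction",
            "undefined_structure_fraction",
            "p_retain_anoxic", "p_retain_oxic_aerobe", "p_retain_oxic_anaerobe",
            "p_retain_specific_multicellular", "p_retain_specific_other",
            "p_retain_unclassified", "retention_heterogeneity", "unknown_fraction_aerobic",
            "unknown_fraction_facultative", "unknown_fraction_anaerobic",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "n_bacteria", "n_archaea", "n_unicellular_eukaryotes",
            "n_multicellular_eukaryotes", "n_global_reactions",
            "n_global_compounds", "n_proteins", "genus_size",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if len(self.descriptor_signs) != len(self.descriptors):
            raise ValidationError("descriptor_signs must match descriptors")
        if self.descriptor_distribution not in ("normal", "lognormal"):
            raise ValidationError("descriptor_distribution must be normal|lognormal")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        for key in ("descriptors", "descriptor_signs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        unknown = set(d) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValidationError(f"unknown StudyConfig field(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StudyBundle:
    """In-memory synthetic study (what :func:`write_study` serialises)."""

    config: StudyConfig
    metadata: list[SpeciesRecord]
    classification: OxygenClassification  # enzyme/reaction sets (+ augmented)
    links: dict[str, ReactionLink]
    r2ec: dict[str, frozenset[str]]
    species_reactions: dict[str, frozenset[str]]
    tree: dendropy.Tree
    properties: pd.DataFrame
    annotations: dict[str, list[str]]
    specific_compounds: frozenset[str]

    def networks(self) -> dict[str, SpeciesNetwork]:
        return {
            org: build_species_network(org, reactions, self.links, self.r2ec)
            for org, reactions in self.species_reactions.items()
        }


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

def _codes(n: int, offset: int = 0) -> list[str]:
    """KEGG-style three-letter organism codes: aaa, aab, ..."""
    out = []
    for i in range(offset, offset + n):
        out.append(
            chr(ord("a") + i // 676) + chr(ord("a") + (i // 26) % 26) + chr(ord("a") + i % 26)
        )
    return out


def _join_clades(subtrees: list[dendropy.Tree], stem: float) -> dendropy.Tree:
    """Join clade subtrees as (((bact, arch):stem, (uni, multi):stem));"""

    def body(t: dendropy.Tree) -> str:
        s = t.as_string(schema="newick", suppress_rooting=True).strip()
        s = s.rstrip(";")
        s = re.sub(r":[0-9.eE+-]+$", "", s)  # drop simulated root edge
        return s

    parts = [f"{body(t)}:{stem}" for t in subtrees]
    prok = f"({parts[0]},{parts[1]}):{stem}"
    euk = f"({parts[2]},{parts[3]}):{stem}"
    newick = f"({prok},{euk});"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def simulate_study_bundle(cfg: StudyConfig) -> StudyBundle:
    """Generate a full in-memory study from a configuration."""
    root = np.random.SeedSequence(cfg.seed)
    seeds = root.generate_state(8) % (2**31)
    rng = np.random.default_rng(root.spawn(1)[0])

    # --- species ids and clades ------------------------------------------------
    n_total = (
        cfg.n_bacteria + cfg.n_archaea
        + cfg.n_unicellular_eukaryotes + cfg.n_multicellular_eukaryotes
    )
    ids = _codes(n_total)
    clades = {
        "bacteria": ids[: cfg.n_bacteria],
        "archaea": ids[cfg.n_bacteria : cfg.n_bacteria + cfg.n_archaea],
        "unicellular_eukaryote": ids[
            cfg.n_bacteria + cfg.n_archaea : cfg.n_bacteria + cfg.n_archaea + cfg.n_unicellular_eukaryotes
        ],
        "multicellular_eukaryote": ids[cfg.n_bacteria + cfg.n_archaea + cfg.n_unicellular_eukaryotes :],
    }

    # --- tree ------------------------------------------------------------------
    subtrees = [
        simulate_tree(len(members), cfg.birth_rate, seed=int(seeds[i]), labels=members)
        for i, members in enumerate(clades.values())
    ]
    tree = _join_clades(subtrees, cfg.clade_stem_length)

    # --- oxygen requirement (1 = aerobic), clustered on the tree --------------
    trait = evolve_binary_trait(
        tree, gain=cfg.trait_gain, loss=cfg.trait_loss, root_state=1, seed=int(seeds[4])
    )
    for org in clades["unicellular_eukaryote"] + clades["multicellular_eukaryote"]:
        trait[org] = 1  # eukaryotes are aerobic in this study design

    # --- metadata --------------------------------------------------------------
    records: list[SpeciesRecord] = []
    genus_counter = 0
    for clade, members in clades.items():
        domain = "bacteria" if clade == "bacteria" else (
            "archaea" if clade == "archaea" else "eukaryote"
        )
        multicellular = clade == "multicellular_eukaryote"
        for j, org in enumerate(members):
            if j % cfg.genus_size == 0:
                genus_counter += 1
            genus = f"Genus{genus_counter:03d}"
            aerobic = trait[org] == 1
            if not aerobic:
                oxy = "anaerobic"
            elif domain != "eukaryote" and rng.random() < cfg.facultative_fraction:
                oxy = "facultative"
            else:
                oxy = "aerobic"
            records.append(
                SpeciesRecord(
                    organism_id=org,
                    domain=domain,
                    oxygen_requirement=oxy,
                    multicellular=multicellular,
                    lifestyle=(
                        "symbiotic_or_parasitic"
                        if rng.random() < cfg.symbiotic_fraction
                        else "free_living"
                    ),
                    thermo_class=(
                        "other" if rng.random() < cfg.thermophile_fraction else "mesophile"
                    ),
                    genome_year=int(rng.integers(cfg.year_min, cfg.year_max + 1)),
                    species_name=f"{genus} species{j % cfg.genus_size + 1}",
                    genus=genus,
                )
            )

    # --- reaction universe -----------------------------------------------------
    n_r = cfg.n_global_reactions
    rids = [f"R{i + 1:05d}" for i in range(n_r)]
    n_unclassified = round(n_r * cfg.unclassified_fraction)
    n_classified = n_r - n_unclassified
    n_oxic = round(n_classified * cfg.oxic_fraction)
    n_anoxic = n_classified - n_oxic
    if n_oxic == 0 or n_anoxic == 0:
        raise ValidationError("configuration yields an empty oxic or anoxic reaction set")
    n_specific = round(n_oxic * cfg.specific_fraction)
    oxic_r = rids[:n_oxic]
    specific_r = set(oxic_r[:n_specific])
    generic_oxic_r = [r for r in oxic_r if r not in specific_r]
    n_augmented = round(len(generic_oxic_r) * cfg.augmented_fraction)
    augmented_r = set(generic_oxic_r[:n_augmented])
    anoxic_r = rids[n_oxic : n_oxic + n_anoxic]
    unclassified_r = rids[n_oxic + n_anoxic :]

    # one EC per reaction; ECs of unclassified reactions stay unlisted
    ec_of = {
        rid: f"{1 + i % 6}.{1 + (i // 6) % 20}.{1 + (i // 120) % 20}.{i + 1}"
        for i, rid in enumerate(rids)
    }

    # compound pools proportional to reaction counts
    n_c = cfg.n_global_compounds
    cids = [f"C{i + 1:05d}" for i in range(n_c)]
    n_c_specific = max(2, round(n_c * n_specific / n_r))
    n_c_oxic = max(2, round(n_c * (n_oxic - n_specific) / n_r))
    pool_specific = cids[:n_c_specific]
    pool_oxic = cids[n_c_specific : n_c_specific + n_c_oxic]
    pool_anoxic = cids[n_c_specific + n_c_oxic :]

    def draw_compounds(pool: list[str], other: list[str], count: int) -> list[str]:
        chosen: set[str] = set()
        while len(chosen) < count:
            if other and rng.random() < cfg.cross_pool_fraction:
                chosen.add(other[int(rng.integers(len(other)))])
            else:
                chosen.add(pool[int(rng.integers(len(pool)))])
        return sorted(chosen)

    links: dict[str, ReactionLink] = {}
    for rid in rids:
        k = int(rng.integers(cfg.min_compounds_per_reaction, cfg.max_compounds_per_reaction + 1))
        if rid in specific_r:
            comp = draw_compounds(pool_specific, [], k)
        elif rid in oxic_r:
            comp = draw_compounds(pool_oxic, pool_anoxic, k)
        elif rid in anoxic_r:
            comp = draw_compounds(pool_anoxic, pool_oxic, k)
        else:
            comp = draw_compounds(cids, [], k)
        n_sub = max(1, k // 2)
        links[rid] = ReactionLink(
            substrates=frozenset(comp[:n_sub]),
            products=frozenset(comp[n_sub:]) or frozenset(comp[:1]),
            direction="forward",
        )

    classification = OxygenClassification(
        oxic_enzymes=frozenset(ec_of[r] for r in oxic_r),
        anoxic_enzymes=frozenset(ec_of[r] for r in anoxic_r),
        oxic_reactions=frozenset(oxic_r),
        anoxic_reactions=frozenset(anoxic_r),
        augmented_reactions=frozenset(augmented_r),
    )

    # --- descriptor table ------------------------------------------------------
    # The oxic shift attaches to compounds reachable only through oxic
    # reactions: anything a classified anoxic reaction also touches belongs to
    # the oxygen-free baseline chemistry and stays unshifted.  This keeps the
    # generated shift aligned with the anoxic-priority classification the
    # analysis derives, for the integral and per-species networks alike.
    oxic_reach: set[str] = set()
    for rid in oxic_r:
        oxic_reach |= links[rid].metabolites
    anoxic_reach: set[str] = set()
    for rid in anoxic_r:
        anoxic_reach |= links[rid].metabolites
    oxic_like = oxic_reach - anoxic_reach
    structureless = rng.random(n_c) < cfg.undefined_structure_fraction
    values = {}
    for d_i, descriptor in enumerate(cfg.descriptors):
        base = rng.normal(cfg.descriptor_mean, cfg.descriptor_sd, size=n_c)
        if cfg.descriptor_distribution == "lognormal":
            base = np.exp(base)
        sign = cfg.descriptor_signs[d_i]
        shift = np.zeros(n_c)
        for i, cid in enumerate(cids):
            if cid in oxic_like:
                shift[i] += sign * cfg.delta_common
            if cid in set(pool_specific):
                shift[i] += sign * cfg.delta_specific
        col = base + shift
        miss = structureless | (rng.random(n_c) < cfg.missing_fraction)
        col = np.where(miss, np.nan, col)
        values[descriptor] = col
    properties = pd.DataFrame(values, index=pd.Index(cids, name="compound_id"))

    # --- species networks ------------------------------------------------------
    category = np.empty(n_r, dtype=object)
    for i, rid in enumerate(rids):
        if rid in specific_r:
            category[i] = "specific"
        elif rid in oxic_r:
            category[i] = "oxic"
        elif rid in anoxic_r:
            category[i] = "anoxic"
        else:
            category[i] = "unclassified"
    rid_arr = np.array(rids)

    species_reactions: dict[str, frozenset[str]] = {}
    for rec in records:
        aerobe = rec.oxygen_requirement in ("aerobic", "facultative")
        p = np.empty(n_r)
        p[category == "anoxic"] = cfg.p_retain_anoxic
        p[category == "oxic"] = (
            cfg.p_retain_oxic_aerobe if aerobe else cfg.p_retain_oxic_anaerobe
        )
        p[category == "specific"] = (
            cfg.p_retain_specific_multicellular
            if rec.multicellular
            else cfg.p_retain_specific_other
        )
        p[category == "unclassified"] = cfg.p_retain_unclassified
        p *= 1.0 - cfg.retention_heterogeneity * rng.random()
        keep = rng.random(n_r) < p
        species_reactions[rec.organism_id] = frozenset(rid_arr[keep])

    # --- annotations -----------------------------------------------------------
    unknown_templates = [
        "hypothetical protein {i:04d}",
        "predicted oxidoreductase {i:04d}",
        "putative membrane transporter {i:04d}",
        "protein of unknown function {i:04d}",
        "iron-related transport protein {i:04d}",
        "GGDEF-family signalling protein {i:04d}",
        "flagellin-like surface protein {i:04d}",
        "probable ATP-dependent helicase {i:04d}",
    ]
    known_templates = [
        "DNA polymerase subunit {i:04d}",
        "ATP synthase chain {i:04d}",
        "50S ribosomal protein L{i}",
        "citrate synthase {i:04d}",
        "elongation factor Tu {i:04d}",
        "glyceraldehyde-3-phosphate dehydrogenase {i:04d}",
    ]
    unknown_rate = {
        "aerobic": cfg.unknown_fraction_aerobic,
        "facultative": cfg.unknown_fraction_facultative,
        "anaerobic": cfg.unknown_fraction_anaerobic,
    }
    annotations: dict[str, list[str]] = {}
    for rec in records:
        rate = unknown_rate[rec.oxygen_requirement]
        flags = rng.random(cfg.n_proteins) < rate
        anns = []
        for i, unknown in enumerate(flags):
            pool = unknown_templates if unknown else known_templates
            anns.append(pool[i % len(pool)].format(i=i + 1))
        annotations[rec.organism_id] = anns

    return StudyBundle(
        config=cfg,
        metadata=records,
        classification=classification,
        links=links,
        r2ec={rid: frozenset({ec}) for rid, ec in ec_of.items()},
        species_reactions=species_reactions,
        tree=tree,
        properties=properties,
        annotations=annotations,
        specific_compounds=frozenset(pool_specific),
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_study(bundle: StudyBundle, out_dir) -> dict[str, Path]:
    """Write a bundle to disk in the exact dialects the readers expect."""
    out = Path(out_dir)
    (out / "classification").mkdir(parents=True, exist_ok=True)
    (out / "networks").mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": out / "metadata.tsv",
        "oxic_enzymes": out / "classification" / "oxic_enzymes.txt",
        "anoxic_enzymes": out / "classification" / "anoxic_enzymes.txt",
        "oxic_reactions": out / "classification" / "oxic_reactions.txt",
        "anoxic_reactions": out / "classification" / "anoxic_reactions.txt",
        "augmented_reactions": out / "classification" / "augmented_reactions.txt",
        "reaction_links": out / "reaction_links.lst",
        "reaction_enzymes": out / "reaction_enzymes.tsv",
        "tree": out / "tree.nwk",
        "properties": out / "properties.tsv",
        "annotations": out / "annotations.tsv",
    }
    write_species_metadata(bundle.metadata, paths["metadata"])
    cls = bundle.classification
    write_id_list(cls.oxic_enzymes, paths["oxic_enzymes"])
    write_id_list(cls.anoxic_enzymes, paths["anoxic_enzymes"])
    write_id_list(cls.oxic_reactions, paths["oxic_reactions"])
    write_id_list(cls.anoxic_reactions, paths["anoxic_reactions"])
    write_id_list(cls.augmented_reactions, paths["augmented_reactions"])
    write_reaction_links(bundle.links, paths["reaction_links"])
    write_reaction_enzymes(bundle.r2ec, paths["reaction_enzymes"])
    write_tree(bundle.tree, paths["tree"])
    write_property_table(bundle.properties, paths["properties"])
    write_annotations(bundle.annotations, paths["annotations"])
    for org in sorted(bundle.species_reactions):
        sub = {r: bundle.links[r] for r in bundle.species_reactions[org] if r in bundle.links}
        path = out / "networks" / f"{org}.lst"
        write_reaction_links(sub, path)
        paths[f"network:{org}"] = path
    return paths


def simulate_study(cfg: StudyConfig, out_dir) -> StudyBundle:
    """Generate a study and write it under ``out_dir``."""
    bundle = simulate_study_bundle(cfg)
    write_study(bundle, out_dir)
    return bundle
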