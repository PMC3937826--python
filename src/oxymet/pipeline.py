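"""End-to-end orchestration: simulate → expansion → phylo → diversity → unknown.

A single YAML/JSON config drives every stage; all randomness flows from one
master seed.  Each run writes a manifest (config hash, input digests, output
paths, warning count) so that re-running with identical inputs reproduces
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .annotation_unknown import kruskal_wallis, unknown_fraction
from .chem_diversity import build_diversity_report
from .data_model_io import (
    OxygenClassification,
    SpeciesNetwork,
    SpeciesRecord,
    build_species_network,
    derive_metabolite_classification,
    parse_reaction_links,
    read_annotations,
    read_classification_lists,
    read_property_table,
    read_reaction_enzymes,
    read_species_metadata,
    select_species,
)
from .errors import OxymetError, ValidationError
from .network_expansion import compare_groups, compute_increase_rate
from .phylo_comparative import (
    brunch_contrasts,
    prune_to,
    read_tree,
    resolve_polytomies,
    tip_labels,
)
from .synthetic_data import StudyConfig, simulate_study

logger = logging.getLogger("oxymet")

DEFAULT_CONFIG = {
    "seed": 0,
    "study_dir": "study",
    "out_dir": "results",
    "simulate": None,  # StudyConfig overrides, or None to use existing inputs
    "policy": "anoxic_priority",
    "unclassified": "exclude",
    "epsilon": 1e-6,
    "descriptors": None,  # None -> the six canonical descriptors
    "log_level": "INFO",
}


class StageError(OxymetError):
    """A pipeline stage failed; carries the stage name for the exit message."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage}: {cause}")


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):
        self.count += 1


@dataclass
class LoadedStudy:
    metadata: list[SpeciesRecord]
    classification: OxygenClassification  # metabolite sets already derived
    networks: dict[str, SpeciesNetwork]
    tree: Any
    properties: Any
    annotations: dict[str, list[str]]
    input_paths: dict[str, Path]


def load_study(study_dir, policy: str = "anoxic_priority") -> LoadedStudy:
    """Load a study directory laid out as :func:`oxymet.synthetic_data.write_study`."""
    d = Path(study_dir)
    cls = read_classification_lists(
        d / "classification" / "oxic_enzymes.txt",
        d / "classification" / "anoxic_enzymes.txt",
        d / "classification" / "oxic_reactions.txt",
        d / "classification" / "anoxic_reactions.txt",
        (d / "classification" / "augmented_reactions.txt")
        if (d / "classification" / "augmented_reactions.txt").exists()
        else None,
    )
    links = parse_reaction_links(d / "reaction_links.lst")
    cls = derive_metabolite_classification(cls, links, policy=policy)
    r2ec = read_reaction_enzymes(d / "reaction_enzymes.tsv")
    metadata = read_species_metadata(d / "metadata.tsv")
    networks: dict[str, SpeciesNetwork] = {}
    input_paths: dict[str, Path] = {
        "metadata": d / "metadata.tsv",
        "reaction_links": d / "reaction_links.lst",
        "reaction_enzymes": d / "reaction_enzymes.tsv",
        "tree": d / "tree.nwk",
        "properties": d / "properties.tsv",
        "annotations": d / "annotations.tsv",
    }
    for rec in metadata:
        path = d / "networks" / f"{rec.organism_id}.lst"
        if not path.exists():
            logger.warning("no network file for %s; skipped", rec.organism_id)
            continue
        sp_links = parse_reaction_links(path)
        networks[rec.organism_id] = build_species_network(
            rec.organism_id, sp_links.keys(), links, r2ec
        )
        input_paths[f"network:{rec.organism_id}"] = path
    return LoadedStudy(
        metadata=metadata,
        classification=cls,
        networks=networks,
        tree=read_tree(d / "tree.nwk"),
        properties=read_property_table(d / "properties.tsv"),
        annotations=read_annotations(d / "annotations.tsv"),
        input_paths=input_paths,
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_expansion(
    study: LoadedStudy,
    basis: str,
    unclassified: str = "exclude",
    organisms: list[str] | None = None,
):
    """Per-species increase rates plus the aerobe/anaerobe comparison."""
    oxy = {r.organism_id: r.oxygen_requirement for r in study.metadata}
    orgs = organisms if organisms is not None else sorted(study.networks)
    results = [
        compute_increase_rate(study.networks[o], study.classification, basis, unclassified)
        for o in orgs
        if o in study.networks
    ]
    rates = {r.organism_id: r.increase_rate for r in results if not r.undefined}
    aerobes = [v for o, v in rates.items() if oxy.get(o) in ("aerobic", "facultative")]
    anaerobes = [v for o, v in rates.items() if oxy.get(o) == "anaerobic"]
    comparison = compare_groups(aerobes, anaerobes)
    return results, comparison, rates


def run_phylo(study: LoadedStudy, rates: Mapping[str, float], epsilon: float = 1e-6):
    """Brunch contrasts of the increase rate on the aerobe/anaerobe state."""
    oxy = {r.organism_id: r.oxygen_requirement for r in study.metadata}
    usable = [o for o in rates if o in oxy and math.isfinite(rates[o])]
    tree = prune_to(usable, study.tree)
    tree = resolve_polytomies(tree, epsilon)
    tips = set(tip_labels(tree))
    predictor = {o: (1.0 if oxy[o] in ("aerobic", "facultative") else 0.0) for o in tips}
    response = {o: float(rates[o]) for o in tips}
    return brunch_contrasts(tree, predictor, response, epsilon=epsilon)


def run_diversity(study: LoadedStudy, descriptors=None):
    groups = select_species(study.metadata, "nonredundant_groups")
    return build_diversity_report(
        study.networks, groups, study.classification, study.properties, descriptors
    )


def run_unknown(study: LoadedStudy):
    oxy = {r.organism_id: r.oxygen_requirement for r in study.metadata}
    records = [
        unknown_fraction(anns, organism_id=org)
        for org, anns in sorted(study.annotations.items())
        if org in oxy
    ]
    by_class: dict[str, list[float]] = {"aerobic": [], "facultative": [], "anaerobic": []}
    for rec in records:
        by_class[oxy[rec.organism_id]].append(rec.fraction)
    groups = [v for v in by_class.values() if len(v) >= 2]
    if len(groups) >= 2:
        h, df, p = kruskal_wallis(groups)
        test = {"H": h, "df": df, "p": p, "n_per_class": {k: len(v) for k, v in by_class.items()}}
    else:
        logger.warning("fewer than 2 oxygen classes with >= 2 genomes; test skipped")
        test = None
    return records, test


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def _resolve_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    resolved = {**DEFAULT_CONFIG, **config}
    return resolved


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return None if math.isnan(obj) else obj
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def _write_json(data, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        json.dump(_jsonable(data), fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_all(config) -> dict:
    """Run every stage; returns the manifest (also written to the out dir)."""
    cfg = _resolve_config(config)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    counter = _WarningCounter()
    logger.addHandler(counter)
    try:
        out_dir = Path(cfg["out_dir"])
        out_dir.mkdir(parents=True, exist_ok=True)
        study_dir = Path(cfg["study_dir"])

        if cfg["simulate"] is not None:
            overrides = dict(cfg["simulate"]) if isinstance(cfg["simulate"], dict) else {}
            overrides.setdefault("seed", cfg["seed"])
            try:
                simulate_study(StudyConfig.from_dict(overrides), study_dir)
            except OxymetError as exc:
                raise StageError("simulate", exc) from exc

        try:
            study = load_study(study_dir, policy=cfg["policy"])
        except (OSError, OxymetError) as exc:
            raise StageError("load", exc) from exc

        outputs: dict[str, Path] = {}

        # expansion (rates reused by the phylo stage)
        rates_by_basis: dict[str, dict[str, float]] = {}
        expansion_summary = {}
        try:
            on_tree = set(tip_labels(study.tree))
            orgs = sorted(o for o in study.networks if o in on_tree)
            for basis in ("enzyme", "metabolite"):
                results, comparison, rates = run_expansion(
                    study, basis, cfg["unclassified"], organisms=orgs
                )
                rates_by_basis[basis] = rates
                path = out_dir / f"expansion_{basis}.tsv"
                with path.open("w", encoding="utf-8") as fh:
                    fh.write("organism_id\tbasis\tn_total\tn_anoxic\tincrease_rate\tundefined\n")
                    for r in results:
                        rate = "" if r.undefined else f"{r.increase_rate:.10g}"
                        fh.write(
                            f"{r.organism_id}\t{r.basis}\t{r.n_total}\t{r.n_anoxic}"
                            f"\t{rate}\t{str(r.undefined).lower()}\n"
                        )
                outputs[f"expansion_{basis}"] = path
                expansion_summary[basis] = comparison
        except OxymetError as exc:
            raise StageError("expansion", exc) from exc

        # phylogenetically controlled test
        try:
            phylo_summary = {
                basis: run_phylo(study, rates_by_basis[basis], cfg["epsilon"])
                for basis in ("enzyme", "metabolite")
            }
        except (OSError, OxymetError) as exc:
            raise StageError("phylo", exc) from exc
        models = {
            basis: {
                "without_phylogeny": expansion_summary[basis],
                "with_phylogeny": {
                    "k": phylo_summary[basis].k,
                    "estimate": phylo_summary[basis].estimate,
                    "se": phylo_summary[basis].se,
                    "t_value": phylo_summary[basis].t_value,
                    "p_value": phylo_summary[basis].p_value,
                    "tested": phylo_summary[basis].tested,
                },
            }
            for basis in ("enzyme", "metabolite")
        }
        outputs["models"] = out_dir / "models.json"
        _write_json(models, outputs["models"])

        # chemical diversity
        try:
            reports, es_records = run_diversity(study, cfg["descriptors"])
        except OxymetError as exc:
            raise StageError("diversity", exc) from exc
        path = out_dir / "diversity.tsv"
        with path.open("w", encoding="utf-8") as fh:
            fh.write(
                "descriptor\tgroup\tes_int\tp_int\tm_es\tm_p\tq_low\tq_high\tev"
                "\tverdict\tn_species\tsignificant_fraction\n"
            )
            for r in reports:
                fh.write(
                    f"{r.descriptor}\t{r.group}\t{r.es_int:.6g}\t{r.p_int:.6g}"
                    f"\t{r.m_es:.6g}\t{r.m_p:.6g}\t{r.q_low:.6g}\t{r.q_high:.6g}"
                    f"\t{r.ev:.6g}\t{r.verdict}\t{r.n_species}"
                    f"\t{r.significant_fraction:.6g}\n"
                )
        outputs["diversity"] = path
        outputs["effect_sizes"] = out_dir / "effect_sizes.json"
        _write_json(es_records, outputs["effect_sizes"])

        # unknown-protein fractions
        try:
            unk_records, unk_test = run_unknown(study)
        except OxymetError as exc:
            raise StageError("unknown", exc) from exc
        path = out_dir / "unknown_fraction.tsv"
        with path.open("w", encoding="utf-8") as fh:
            fh.write("organism_id\tn_proteins\tn_unknown\tfraction\n")
            for r in unk_records:
                fh.write(f"{r.organism_id}\t{r.n_proteins}\t{r.n_unknown}\t{r.fraction:.10g}\n")
        outputs["unknown_fraction"] = path
        outputs["unknown_test"] = out_dir / "unknown_test.json"
        _write_json(unk_test, outputs["unknown_test"])

        manifest = {
            "package_version": __version__,
            "seed": cfg["seed"],
            "config": {k: v for k, v in cfg.items() if k != "log_level"},
            "config_hash": hashlib.sha256(
                json.dumps(_jsonable(cfg), sort_keys=True).encode()
            ).hexdigest(),
            "input_digests": {
                name: _digest(p) for name, p in sorted(study.input_paths.items())
            },
            "outputs": {name: str(p) for name, p in outputs.items()},
            "warnings": counter.count,
        }
        _write_json(manifest, out_dir / "manifest.json")
        return manifest
    finally:
        logger.removeHandler(counter)
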