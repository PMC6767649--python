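"""End-to-end orchestration with a config file and a run manifest.

The pipeline runs whichever stages its config provides inputs for, in
dependency order: architecture curation (always; requires the domtblout
table), census, feature annotation, co-expression, and phylostratigraphy.
Stage outputs are pure functions of (inputs, config): re-running with
identical inputs reproduces byte-identical reports, which the manifest
records as checksums alongside row counts and the config snapshot.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import census as census_mod
from . import coexpression as coexpr_mod
from . import features as features_mod
from . import hit_processing as hp
from . import phylostrat as ps

log = logging.getLogger(__name__)

REQUIRED_KEYS = ("inputs",)
THRESHOLD_KEYS = ("protein_evalue_max", "domain_ievalue_max", "overlap_frac_max")


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping[str, Any]) -> None:
    for key in REQUIRED_KEYS:
        if key not in cfg:
            raise ConfigError(f"config missing required key: {key!r}")
    if "domtblout" not in cfg.get("inputs", {}):
        raise ConfigError("config missing required key: 'inputs.domtblout'")
    thresholds = cfg.get("thresholds", {})
    unknown = set(thresholds) - set(THRESHOLD_KEYS)
    if unknown:
        raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")


def pipeline_config_from(cfg: Mapping[str, Any]) -> hp.PipelineConfig:
    thresholds = dict(cfg.get("thresholds", {}))
    exclusion: frozenset[str] = frozenset(cfg.get("exclusion_list", ()))
    exclusion_file = cfg.get("inputs", {}).get("exclusion_list")
    if exclusion_file:
        exclusion |= hp.read_exclusion_list(exclusion_file)
    return hp.PipelineConfig(
        trypsin_families=frozenset(
            cfg.get("trypsin_families", hp.DEFAULT_TRYPSIN_FAMILIES)
        ),
        exclusion_list=exclusion,
        **thresholds,
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> dict:
    """Run every configured stage; write stage reports and the run manifest.

    All configured input files are checked for existence before any stage
    runs; a missing file raises a named error up front.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    else:
        validate_config(config)
    inputs: dict[str, str] = dict(config["inputs"])
    missing = {k: v for k, v in inputs.items() if v and not Path(v).exists()}
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = pipeline_config_from(config)
    manifest: dict[str, Any] = {
        "config": json.loads(json.dumps(dict(config), default=str)),
        "input_checksums": {k: _sha256(v) for k, v in inputs.items() if v},
        "tool_versions": dict(config.get("tool_versions", {})),
        "stages": {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }

    # --- architectures -----------------------------------------------------
    hits = hp.parse_domtblout(inputs["domtblout"])
    archs = hp.build_architectures(hits, cfg)
    arch_path = out / "architectures.tsv"
    hp.write_architecture_report(archs, arch_path)
    manifest["stages"]["architect"] = {"n_hits": len(hits), "n_proteins": len(archs)}

    # --- census ------------------------------------------------------------
    n_only, n_multi = census_mod.classify_tryptome(archs, cfg.trypsin_families)
    manifest["stages"]["census"] = {"n_trypsin_only": n_only, "n_multidomain": n_multi}
    if inputs.get("background_domains"):
        table = census_mod.read_proteome_domain_table(inputs["background_domains"])
        rows, n_fam = census_mod.domain_abundance(archs, table, cfg.trypsin_families)
        census_mod.write_abundance_report(rows, out / "abundance.tsv")
        manifest["stages"]["census"]["n_associated_families"] = n_fam

    # --- features ----------------------------------------------------------
    triad = pred = None
    if inputs.get("msa") and config.get("triad_reference"):
        spec = features_mod.TriadSpec(reference_id=config["triad_reference"])
        triad = features_mod.triad_scan(inputs["msa"], spec)
    if inputs.get("signalp") and inputs.get("tmhmm"):
        pred = features_mod.read_predictor_tables(
            inputs["signalp"], inputs["tmhmm"], [a.protein_id for a in archs]
        )
    if triad or pred or inputs.get("gff"):
        records = features_mod.build_feature_records(
            archs,
            triad=triad,
            predictor_flags=pred,
            gff=inputs.get("gff"),
            protein_to_transcript=config.get("protein_to_transcript"),
            overhang_nt=int(config.get("overhang_nt", 10)),
        )
        features_mod.write_feature_report(records, out / "features.tsv")
        manifest["stages"]["features"] = {"n_records": len(records)}

    # --- co-expression -----------------------------------------------------
    if inputs.get("cell_matrix") and inputs.get("trypsin_genes"):
        gene_set = [
            line.strip()
            for line in Path(inputs["trypsin_genes"]).read_text().splitlines()
            if line.strip()
        ]
        cc = coexpr_mod.CellCounts.from_tsv(inputs["cell_matrix"], trypsin_set=gene_set)
        summary = coexpr_mod.coexpression_summary(cc, int(config.get("min_reads", 1)))
        coexpr_mod.write_summary(summary, out / "coexpression")
        manifest["stages"]["coexpress"] = {
            "n_expressing_cells": summary.n_expressing_cells
        }

    # --- phylostratigraphy -------------------------------------------------
    if inputs.get("species_tree") and inputs.get("presence_matrix"):
        tree = ps.load_tree(inputs["species_tree"])
        pm = ps.read_presence_matrix(inputs["presence_matrix"])
        assignments = ps.assign_origin(pm, tree)
        ps.write_origin_report(assignments, out / "origins.tsv")
        manifest["stages"]["phylostrat"] = {"n_features": len(assignments)}

    manifest["output_checksums"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
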