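"""End-to-end pipeline: (simulate | ingest) -> preprocess -> neutral fit ->
alpha diversity -> beta diversity -> indicator taxa, driven by one config.

Each stage writes its tabular outputs under the output directory and
contributes to a machine-readable ``report.json`` with full provenance
(parameters, seeds, dropped samples).  A stage failure is recorded in the
report; independent later stages still run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .beta import anosim, bray_curtis, nmds, permanova
from .diversity import alpha_diversity, compare_groups, summarize_by_group
from .indicators import indicator_analysis
from .neutral import fit_all_groups
from .simulate import SyntheticConfig, generate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    # either paths ...
    table_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    # ... or a simulation
    simulation: dict | None = None
    # preprocessing
    min_count: int = 10
    drop_single_sample: bool = True
    ecm_only: bool = True
    rarefaction_depth: int | str | None = "min"
    seed: int = 0
    # analysis
    grouping: tuple = ("host_type", "stage")
    n_permutations: int = 999
    nmds_starts: int = 20
    rf_trees: int = 1000
    indicator_top_n: int = 30
    n_boot: int = 1000
    out_dir: str = "ecmassembly_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.grouping, list):
            cfg.grouping = tuple(cfg.grouping)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "artifacts": {},
    }

    # -- stage: inputs ------------------------------------------------------
    try:
        if config.simulation is not None:
            sim_cfg = SyntheticConfig.from_dict(dict(config.simulation))
            table, metadata, taxonomy, truth = generate_study(sim_cfg)
            eio.write_asv_table(table, out / "asv_table.tsv")
            eio.write_metadata(metadata, out / "metadata.tsv")
            eio.write_taxonomy(taxonomy, out / "taxonomy.tsv")
            (out / "truth.json").write_text(
                json.dumps(truth.to_dict(), indent=2, default=str)
            )
            report["stages"]["input"] = {
                "status": "ok", "mode": "simulated",
                "simulation": sim_cfg.to_dict(),
            }
        else:
            table = eio.read_asv_table(config.table_path)
            metadata = eio.read_metadata(config.metadata_path)
            taxonomy = (
                eio.read_taxonomy(config.taxonomy_path)
                if config.taxonomy_path
                else None
            )
            report["stages"]["input"] = {"status": "ok", "mode": "files"}
    except Exception as exc:
        report["stages"]["input"] = {"status": "failed", "error": str(exc)}
        _write_report(report, out)
        return report

    # -- stage: preprocess --------------------------------------------------
    try:
        table, prov = eio.preprocess(
            table,
            taxonomy,
            min_count=config.min_count,
            drop_single_sample=config.drop_single_sample,
            ecm_only=config.ecm_only,
            depth=config.rarefaction_depth,
            seed=config.seed,
        )
        eio.write_asv_table(table, out / "asv_table.filtered.tsv")
        eio.write_provenance(prov, out / "provenance.json")
        metadata = metadata.loc[[s for s in table.sample_ids]]
        report["stages"]["preprocess"] = {"status": "ok", **prov}
    except Exception as exc:
        report["stages"]["preprocess"] = {"status": "failed", "error": str(exc)}
        _write_report(report, out)
        return report

    # -- stage: neutral fits ------------------------------------------------
    try:
        fits = fit_all_groups(table, metadata, grouping=config.grouping)
        entry: dict = {"status": "ok", "groups": {}}
        per_asv_frames = []
        for label, res in fits.items():
            if isinstance(res, Exception):
                entry["groups"][label] = {"status": "failed", "error": str(res)}
                continue
            entry["groups"][label] = {
                "status": "ok",
                "pseudo_r2": res.pseudo_r2,
                "m": res.m,
                "n_asvs": res.n_asvs,
                "smoother_spec": res.smoother_spec,
            }
            df = res.to_dataframe()
            df.insert(0, "group", label)
            per_asv_frames.append(df)
        if per_asv_frames:
            pd.concat(per_asv_frames).to_csv(out / "neutral_fit_per_asv.csv", index=False)
        report["stages"]["neutral"] = entry
    except Exception as exc:
        report["stages"]["neutral"] = {"status": "failed", "error": str(exc)}

    # -- stage: alpha diversity --------------------------------------------
    try:
        adiv = alpha_diversity(table)
        adiv.to_csv(out / "alpha_diversity.csv", index=False)
        summary = summarize_by_group(
            adiv.drop(columns="sample_id"), metadata, grouping=list(config.grouping)
        )
        summary.to_csv(out / "alpha_summary.csv", index=False)
        tests = {}
        for factor in config.grouping:
            labels = metadata.loc[adiv.index, factor].to_numpy()
            for metric in ("shannon", "simpson", "pielou", "sobs"):
                try:
                    res = compare_groups(
                        adiv[metric].to_numpy(float), labels,
                        comparison=f"{metric}~{factor}",
                    )
                    tests[f"{metric}~{factor}"] = res.to_dict()
                except ValueError as exc:
                    tests[f"{metric}~{factor}"] = {"status": "failed", "error": str(exc)}
        (out / "alpha_tests.json").write_text(json.dumps(tests, indent=2))
        report["stages"]["alpha_diversity"] = {
            "status": "ok",
            "summary": summary.to_dict(orient="records"),
            "tests": tests,
        }
    except Exception as exc:
        report["stages"]["alpha_diversity"] = {"status": "failed", "error": str(exc)}

    # -- stage: beta diversity ---------------------------------------------
    try:
        rel = eio.relative_abundance(table)
        hel = eio.hellinger_transform(rel)
        dm = bray_curtis(hel, table.sample_ids)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out / "bray_curtis.tsv", sep="\t"
        )
        stage_groups = metadata["stage"].to_dict() if "stage" in metadata else None
        ord_res = nmds(
            dm, seed=config.seed, n_starts=config.nmds_starts, groups=stage_groups
        )
        coords = ord_res.coordinates.copy()
        coords.insert(0, "sample_id", coords.index)
        coords["stress"] = ord_res.stress
        coords.to_csv(out / "nmds_coordinates.csv", index=False)
        entry = {"status": "ok", "stress": ord_res.stress, "tests": {}}
        for factor in config.grouping:
            labels = metadata.loc[list(dm.ids), factor]
            perm = permanova(
                dm, labels, n_permutations=config.n_permutations,
                seed=config.seed, factor_name=factor,
            )
            ano = anosim(
                dm, labels, n_permutations=config.n_permutations,
                seed=config.seed, factor_name=factor,
            )
            entry["tests"][factor] = {
                "permanova": perm.to_dict(), "anosim": ano.to_dict()
            }
        (out / "beta_tests.json").write_text(json.dumps(entry["tests"], indent=2))
        report["stages"]["beta_diversity"] = entry
    except Exception as exc:
        report["stages"]["beta_diversity"] = {"status": "failed", "error": str(exc)}

    # -- stage: indicator taxa ---------------------------------------------
    try:
        entry = {"status": "ok", "contrasts": {}}
        for contrast in ("stage", "host_type"):
            if contrast not in metadata.columns:
                continue
            result, rf = indicator_analysis(
                table, metadata, contrast,
                taxonomy=taxonomy if config.simulation is None else None,
                top_n=config.indicator_top_n,
                n_trees=config.rf_trees,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            result.to_csv(out / f"indicators_{contrast}.csv", index=False)
            entry["contrasts"][contrast] = {
                "oob_accuracy": rf.oob_accuracy,
                "n_trees": rf.n_trees,
                "n_short_listed": len(result),
                "lnrr_orientation": (
                    f"{result['group_a'].iloc[0]}/{result['group_b'].iloc[0]}"
                    if len(result) else None
                ),
            }
        report["stages"]["indicators"] = entry
    except Exception as exc:
        report["stages"]["indicators"] = {"status": "failed", "error": str(exc)}

    # checksums of written artifacts
    for p in sorted(out.glob("*")):
        if p.name != "report.json" and p.is_file():
            report["artifacts"][p.name] = _sha256(p)
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=_json_default)
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
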