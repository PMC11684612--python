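"""End-to-end study pipeline.

Runs the full workflow of a two-phase design comparison: normalize the
ASV and OTU tables to relative frequencies, run every requested selection
method at every requested subsample size on both tables, compare the
paired selections (ASV vs OTU agreement), and screen each selection for
features differentially represented between the selected and unselected
samples.  All outputs are plain text (sample-ID lists, JSON sidecars and
reports, TSV effect tables) under out/{method}/{size}/, with a manifest
recording configuration, seed, and per-stage status.  Reruns with an
identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .comparison import (kruskal_wallis_screen, lda_effect_size, pairwise_overlap,
                         write_effect_report)
from .feature_table import (FeatureTable, PhenotypeMetadata, impute_phenotype,
                            load_metadata, load_table, to_relative_frequency)
from .selection import METHODS, SelectionResult, select

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("micropick.pipeline")


@dataclass
class PipelineConfig:
    asv_table: str
    otu_table: str | None = None
    metadata: str | None = None
    methods: tuple[str, ...] = METHODS
    sizes: tuple[int, ...] = (20, 50, 100)
    output_dir: str = "out"
    seed: int = 0
    table_format: str = "tsv"
    orientation: str = "features-as-rows"
    linkage: str = "average"
    keep_count: int | None = None
    n_boot: int = 30
    alpha: float = 0.05
    threshold: float = 2.0
    reference_class: str = "control"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for key in ("methods", "sizes"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _validate(config: PipelineConfig, tables: dict[str, FeatureTable]) -> None:
    unknown = set(config.methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}; choose from {METHODS}")
    for label, table in tables.items():
        too_big = [k for k in config.sizes if k > table.n_samples]
        if too_big:
            raise ValueError(
                f"sizes {too_big} exceed the {table.n_samples} samples of the "
                f"{label} table"
            )
    needs_pheno = {"discriminant", "distinct"} & set(config.methods)
    if needs_pheno and config.metadata is None:
        raise ValueError(f"methods {sorted(needs_pheno)} require metadata")


def _write_selection(result: SelectionResult, stem: Path) -> list[str]:
    ids_path = stem.with_suffix(".ids.txt")
    ids_path.write_text("".join(s + "\n" for s in result.selected))
    sidecar = {
        "method": result.method,
        "k": result.k,
        "selected": list(result.selected),
        "params": result.params,
        "scores": result.scores,
    }
    json_path = stem.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return [str(ids_path), str(json_path)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "outputs": [],
    }

    def stage(name: str, fn):
        t0 = time.perf_counter()
        entry = {"stage": name, "status": "ok", "wall_s": None}
        try:
            result = fn()
            return result
        except Exception as exc:  # noqa: BLE001 - recorded, then re-raised
            entry["status"] = f"failed: {exc}"
            raise
        finally:
            entry["wall_s"] = round(time.perf_counter() - t0, 4)
            manifest["stages"].append(entry)
            logger.info("stage=%s status=%s wall_s=%s", name, entry["status"], entry["wall_s"])
            _write_manifest(out, manifest)

    tables: dict[str, FeatureTable] = {}

    def load_inputs():
        tables["asv"] = load_table(config.asv_table, format=config.table_format,
                                   orientation=config.orientation)
        if config.otu_table:
            tables["otu"] = load_table(config.otu_table, format=config.table_format,
                                       orientation=config.orientation)
        _validate(config, tables)
        return tables

    stage("load", load_inputs)

    phenotype: PhenotypeMetadata | None = None
    if config.metadata:
        def load_pheno():
            raw = load_metadata(config.metadata)
            for table in tables.values():
                for s in table.sample_ids:
                    raw.setdefault(s, None)
            return impute_phenotype(raw, reference_class=config.reference_class)

        phenotype = stage("phenotype", load_pheno)

    rel = {label: to_relative_frequency(t) for label, t in
           stage("normalize", lambda: tables).items()}

    selections: dict[tuple[str, int, str], SelectionResult] = {}
    for method in config.methods:
        for k in config.sizes:
            for label, table in rel.items():
                def run_sel(method=method, k=k, label=label, table=table):
                    kwargs = {}
                    if method == "extreme":
                        kwargs["linkage"] = config.linkage
                    if method == "spca":
                        kwargs["keep_count"] = config.keep_count
                    result = select(method, table, k, phenotype=phenotype, **kwargs)
                    stem = out / method / str(k) / f"selection_{label}"
                    stem.parent.mkdir(parents=True, exist_ok=True)
                    manifest["outputs"] += _write_selection(result, stem)
                    return result

                selections[(method, k, label)] = stage(
                    f"select/{method}/k={k}/{label}", run_sel)

    if "otu" in rel:
        for method in config.methods:
            for k in config.sizes:
                def run_cmp(method=method, k=k):
                    report = pairwise_overlap(
                        selections[(method, k, "asv")], selections[(method, k, "otu")],
                        label_a="asv", label_b="otu")
                    path = out / method / str(k) / "agreement_asv_otu.json"
                    path.write_text(json.dumps(report.to_json_dict(), indent=2,
                                               sort_keys=True) + "\n")
                    manifest["outputs"].append(str(path))
                    return report

                stage(f"compare/{method}/k={k}", run_cmp)

    for (method, k, label), result in selections.items():
        def run_screen(method=method, k=k, label=label, result=result):
            table = rel[label]
            groups = {s: ("selected" if s in result.as_set() else "unselected")
                      for s in table.sample_ids}
            records = kruskal_wallis_screen(table, groups, alpha=config.alpha,
                                            group_of_interest="selected")
            survivors = [r.feature_id for r in records if r.significant]
            if survivors:
                lda = {r.feature_id: r for r in lda_effect_size(
                    table, groups, survivors, n_boot=config.n_boot,
                    seed=config.seed, threshold=config.threshold,
                    group_of_interest="selected")}
                merged = []
                for r in records:
                    if r.feature_id in lda:
                        lr = lda[r.feature_id]
                        merged.append(type(r)(r.feature_id, r.kw_p, lr.direction,
                                              lr.lda_effect, lr.significant))
                    else:
                        merged.append(type(r)(r.feature_id, r.kw_p, r.direction,
                                              None, False))
                records = merged
            path = out / method / str(k) / f"effects_{label}.tsv"
            write_effect_report(records, path)
            manifest["outputs"].append(str(path))
            return len([r for r in records if r.significant])

        stage(f"screen/{method}/k={k}/{label}", run_screen)

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def _setup_logging(out: Path) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    file_handler = logging.FileHandler(out / "pipeline.log")
    file_handler.setFormatter(handler.formatter)
    logger.setLevel(logging.INFO)
    logger.addHandler(handler)
    logger.addHandler(file_handler)
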