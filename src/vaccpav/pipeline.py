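"""End-to-end orchestration: simulate → classify → model → features → enrich.

The pipeline is linear and desk-scale, so plain files plus a JSON manifest
stand in for a workflow engine. Every stage reads the formats written by the
previous one; a fixed seed makes the whole run byte-reproducible (the
manifest deliberately records no wall-clock state). Stage progress and
timings go to stderr only.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
import time
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .classify import (
    DEFAULT_WINDOW,
    PavLabels,
    classify,
    filter_ortholog_calls,
    genes_frame,
    summarize,
)
from .enrichment import term_enrichment
from .features import compare_all, compute_features
from .io import (
    read_anchors,
    read_expression,
    read_gff3,
    read_orthogroups,
    read_terms,
    write_table,
)
from .modeling import model_curve, occupancy_histogram
from .simulate import SimulationParams, generate_truth, write_outputs

__all__ = ["RunConfig", "run_pipeline", "render_report", "DEFAULT_DEMO_CONFIG"]

DEFAULT_DEMO_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "classify": True,
        "model": True,
        "features": True,
        "enrich": True,
    },
    "simulate": {
        "n_accessions": 11,
        "n_orthogroups": 800,
        "core_fraction": 0.53,
        "og_error_rate": 0.0,
        "anchor_dropout": 0.0,
    },
    "classify": {"window": DEFAULT_WINDOW, "mode": "dual", "precision": 2},
    "enrich": {"direction": "auxiliary", "min_count": 3},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: str
    seed: int = 0
    stages: dict = field(default_factory=lambda: dict(DEFAULT_DEMO_CONFIG["stages"]))
    simulate: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: dict, outdir: str | None = None) -> "RunConfig":
        m = dict(mapping)
        out = outdir or m.pop("outdir", None)
        if out is None:
            raise ValueError("config must set an output directory")
        allowed = {"seed", "stages", "simulate", "classify", "features", "enrich"}
        unknown = set(m) - allowed - {"outdir"}
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        return cls(
            outdir=os.fspath(out),
            seed=int(m.get("seed", 0)),
            stages={**DEFAULT_DEMO_CONFIG["stages"], **m.get("stages", {})},
            simulate=dict(m.get("simulate", {})),
            classify=dict(m.get("classify", {})),
            features=dict(m.get("features", {})),
            enrich=dict(m.get("enrich", {})),
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(msg: str) -> None:
    print(f"[vaccpav] {msg}", file=sys.stderr)


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        _log(f"stage {self.name}: start")
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is not None:
            _log(f"stage {self.name}: FAILED after {dt:.1f}s")
            raise RuntimeError(f"pipeline stage {self.name!r} failed") from exc
        _log(f"stage {self.name}: done in {dt:.1f}s")
        return False


def run_pipeline(config: RunConfig | dict, outdir: str | None = None) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Outputs land in ``config.outdir``; the manifest (config echo, package
    version, input/output checksums) is written to ``manifest.json`` there.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_mapping(config, outdir=outdir)
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "package": "vaccpav",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "stages": config.stages,
            "simulate": config.simulate,
            "classify": config.classify,
            "features": config.features,
            "enrich": config.enrich,
        },
        "inputs": {},
        "outputs": {},
        "results": {},
    }
    paths: dict = {}

    if config.stages.get("simulate"):
        with _Stage("simulate"):
            params = SimulationParams(seed=config.seed, **config.simulate)
            truth = generate_truth(params)
            sim_dir = os.path.join(config.outdir, "sim")
            paths.update(write_outputs(truth, sim_dir))
            manifest["results"]["simulate"] = {
                "n_orthogroups": int(params.n_orthogroups),
                "n_genes": int(len(truth.genes)),
                "true_core_fraction": truth.n_core / params.n_orthogroups,
            }
    else:
        for key in ("gff3", "orthogroups", "unassigned", "anchors", "expression", "terms"):
            if key in config.classify:
                paths[key] = config.classify[key]
            elif key in config.features:
                paths[key] = config.features[key]
            elif key in config.enrich:
                paths[key] = config.enrich[key]

    labels: PavLabels | None = None
    annotations = None
    table = None
    if config.stages.get("classify"):
        with _Stage("classify"):
            mode = config.classify.get("mode", "dual")
            for key in ("orthogroups", "gff3"):
                if key not in paths:
                    raise FileNotFoundError(f"classify stage needs {key!r} input")
            if mode == "dual" and "anchors" not in paths:
                raise FileNotFoundError("classify stage (dual mode) needs 'anchors' input")
            gff_paths = paths["gff3"]
            if isinstance(gff_paths, dict):
                annotations = {
                    acc: read_gff3(p, accession_id=acc) for acc, p in sorted(gff_paths.items())
                }
            else:
                annotations = {}
                for p in gff_paths:
                    ann = read_gff3(p)
                    annotations[ann.accession_id] = ann
            accessions = sorted(annotations)
            table = read_orthogroups(paths["orthogroups"], paths.get("unassigned"), accessions)
            window = float(config.classify.get("window", DEFAULT_WINDOW))
            if mode == "orthogroup":
                window = float("inf")
            anchors = (
                read_anchors(paths["anchors"], accessions) if "anchors" in paths else None
            )
            filtered = filter_ortholog_calls(table, annotations, anchors, W=window)
            labels = classify(table, filtered)
            precision = int(config.classify.get("precision", 2))
            summary = summarize(labels, precision=precision)
            for name, df in (
                ("labels", labels.to_frame("gene")),
                ("og_labels", labels.to_frame("orthogroup")),
                ("summary", summary),
            ):
                paths[name] = os.path.join(config.outdir, f"{name}.tsv")
                write_table(df, paths[name])
            manifest["results"]["classify"] = {
                "n_core_orthogroups": labels.n_core_groups,
                "n_orthogroups": int(len(labels.og_labels)),
                "core_fraction": labels.core_fraction,
                "window": window if window != float("inf") else "inf",
            }
            for key in ("orthogroups", "unassigned", "anchors"):
                if paths.get(key):
                    manifest["inputs"][key] = _sha256(paths[key])

    if config.stages.get("model"):
        with _Stage("model"):
            if labels is None:
                raise FileNotFoundError("model stage needs classification labels")
            curve = model_curve(occupancy_histogram(labels))
            paths["curve"] = os.path.join(config.outdir, "curve.tsv")
            write_table(curve.as_frame(), paths["curve"])
            manifest["results"]["model"] = {
                "open_pangenome": curve.open_pangenome,
                "pan_at_N": float(curve.points["pan_avg"].iloc[-1]),
                "core_at_N": float(curve.points["core_avg"].iloc[-1]),
            }

    feature_rows = None
    if config.stages.get("features"):
        with _Stage("features"):
            if labels is None or annotations is None:
                raise FileNotFoundError("features stage needs classification labels")
            expr = read_expression(paths["expression"]) if paths.get("expression") else None
            feature_rows = compute_features(annotations, labels, expr)
            comparison = compare_all(feature_rows)
            paths["features"] = os.path.join(config.outdir, "features.tsv")
            paths["feature_contrasts"] = os.path.join(config.outdir, "feature_contrasts.tsv")
            write_table(feature_rows, paths["features"])
            write_table(comparison, paths["feature_contrasts"])
            manifest["results"]["features"] = {
                "n_genes": int(len(feature_rows)),
                "features_compared": comparison["feature"].tolist(),
            }

    if config.stages.get("enrich"):
        with _Stage("enrich"):
            if labels is None or table is None:
                raise FileNotFoundError("enrich stage needs classification labels")
            if not paths.get("terms"):
                raise FileNotFoundError("enrich stage needs a 'terms' input")
            term_map = read_terms(paths["terms"])
            long = table.to_long_frame()
            og_terms: dict[str, set[str]] = {}
            for og, uid in zip(long["orthogroup"], long["uid"]):
                ts = term_map.terms_for(uid)
                if ts:
                    og_terms.setdefault(og, set()).update(ts)
            direction = config.enrich.get("direction", "auxiliary")
            fg = set(labels.og_labels.index[labels.og_labels == direction])
            universe = set(labels.og_labels.index)
            enr = term_enrichment(
                og_terms,
                fg,
                universe,
                min_count=int(config.enrich.get("min_count", 3)),
            )
            enr["term_name"] = enr["term_id"].map(term_map.term_names).fillna("")
            paths["enrichment"] = os.path.join(config.outdir, "enrichment.tsv")
            write_table(enr, paths["enrichment"])
            manifest["results"]["enrich"] = {
                "direction": direction,
                "n_terms_tested": int(len(enr)),
                "top_term": enr["term_id"].iloc[0] if len(enr) else None,
            }

    # flat listing of produced files with checksums
    def _walk(val):
        if isinstance(val, dict):
            return {k: _walk(v) for k, v in sorted(val.items())}
        return _sha256(val) if isinstance(val, str) and os.path.exists(val) else None

    manifest["outputs"] = {k: _walk(v) for k, v in sorted(paths.items())}
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    report_path = os.path.join(config.outdir, "report.md")
    with open(report_path, "wt", encoding="utf-8") as fh:
        fh.write(render_report(config.outdir))
    return manifest


def render_report(outdir: str) -> str:
    """Markdown digest of a finished run directory."""
    lines = ["# Pangenome run report", ""]
    man_path = os.path.join(outdir, "manifest.json")
    if os.path.exists(man_path):
        with open(man_path, "rt", encoding="utf-8") as fh:
            man = json.load(fh)
        lines.append(f"Package vaccpav {man['version']}, seed {man['seed']}.")
        lines.append("")

    def _table(df: pd.DataFrame) -> list[str]:
        header = "| " + " | ".join(df.columns) + " |"
        sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
        body = [
            "| " + " | ".join(str(v) for v in row) + " |" for row in df.itertuples(index=False)
        ]
        return [header, sep, *body]

    summary_path = os.path.join(outdir, "summary.tsv")
    if os.path.exists(summary_path):
        lines += ["## Core / auxiliary classification", ""]
        lines += _table(pd.read_csv(summary_path, sep="\t"))
        lines.append("")
    curve_path = os.path.join(outdir, "curve.tsv")
    if os.path.exists(curve_path):
        lines += ["## Accumulation curve", ""]
        lines += _table(pd.read_csv(curve_path, sep="\t"))
        lines.append("")
    fc_path = os.path.join(outdir, "feature_contrasts.tsv")
    if os.path.exists(fc_path):
        fc = pd.read_csv(fc_path, sep="\t")
        cols = ["feature", "n_core", "n_aux", "median_core", "median_aux", "p_value"]
        lines += ["## Core vs auxiliary gene features", ""]
        lines += _table(fc[cols])
        lines.append("")
    enr_path = os.path.join(outdir, "enrichment.tsv")
    if os.path.exists(enr_path):
        enr = pd.read_csv(enr_path, sep="\t")
        lines += ["## Term enrichment (top 10)", ""]
        if len(enr):
            cols = ["term_id", "term_name", "fg_with", "bg_with", "odds_ratio", "p", "fdr_q"]
            lines += _table(enr[cols].head(10))
        else:
            lines.append("no terms pass min_count")
        lines.append("")
    return "\n".join(lines) + "\n"
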