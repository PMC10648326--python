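"""End-to-end orchestration of the analysis stages.

Stages communicate only through files in the documented formats, so each
one is independently testable and replaceable. ``run_all`` executes the
requested stages in dependency order (simulate -> her2 -> risk -> survival
-> profile), halts on the first failing stage with a stage-named error, and
writes a manifest recording the configuration snapshot, seed, package
version, SHA-256 of every file read or written, and every threshold or
convention choice actually applied — enough to re-run the deterministic
stages bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import expression_profile as ep
from . import her2_calling as hc
from . import risk_model as rm
from . import synthetic as syn
from .io_formats import (
    SchemaError,
    assemble_features,
    read_clinical,
    read_expression,
    read_feature_table,
    read_mutation_flags,
    read_seg,
    read_signature_contributions,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "her2", "risk", "survival", "profile")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: dict) -> list[str]:
    """Pre-flight schema check; returns the stage list. Raises before any
    stage runs if a requested stage cannot resolve its inputs."""
    stages = config.get("stages", list(ALL_STAGES))
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise SchemaError(f"unknown stages {unknown}; valid: {ALL_STAGES}")
    simulating = "simulate" in stages
    inputs = config.get("inputs", {})
    needs = {
        "her2": ["expression", "annotation", "features"],
        "risk": ["clinical", "features", "mutations", "signatures"],
        "survival": ["clinical"],
        "profile": ["expression", "annotation", "clinical", "features"],
    }
    for stage in stages:
        for key in needs.get(stage, []):
            if not simulating and key not in inputs:
                raise SchemaError(
                    f"stage {stage!r} requires input {key!r}, which is neither "
                    "configured nor produced by a simulate stage"
                )
    return list(stages)


def run_all(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Run the configured stages and return the manifest (also written to
    ``<outdir>/manifest.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = validate_config(config)
    seed = int(config.get("seed", 0) if seed is None else seed)

    files: dict[str, str] = {}
    choices: dict[str, object] = {
        "roc_criterion": config.get("roc_criterion", "youden"),
        "linkage": config.get("linkage", "average"),
        "k_clusters": int(config.get("k", 4)),
        "risk_cutoff": rm.RISK_CUTOFF,
        "amp_peak6_region": list(rm.AMP_PEAK6_REGION),
        "amp_peak6_cn_threshold": rm.AMP_PEAK6_CN_THRESHOLD,
        "cn_call_boundary": "strictly_above_threshold",
        "kw_selection_p": ep.KW_SELECTION_P,
        "excluded_chromosome": ep.EXCLUDED_CHROMOSOME,
    }

    def record(label: str, path: Path) -> Path:
        files[label] = _sha256(Path(path))
        return Path(path)

    inputs = {k: Path(v) for k, v in config.get("inputs", {}).items()}

    if "simulate" in stages:
        try:
            sim_cfg = dict(config.get("simulate", {}))
            sim_cfg["seed"] = seed
            params = syn.SimulationParams(**sim_cfg)
            bundle = syn.simulate_cohort(params)
            paths = syn.write_cohort(bundle, outdir / "cohort")
        except Exception as exc:
            raise StageError("simulate", exc) from exc
        for label, path in paths.items():
            record(f"simulate:{label}", path)
        inputs = {
            "clinical": paths["clinical"], "features": paths["features"],
            "mutations": paths["mutations"], "signatures": paths["signatures"],
            "expression": paths["expression"], "annotation": paths["annotation"],
            "segments": paths["segments"],
        }

    for label, path in inputs.items():
        record(f"input:{label}", path)

    clinical = features = expr = None
    if {"her2", "risk", "survival", "profile"} & set(stages):
        clinical = read_clinical(inputs["clinical"]) if "clinical" in inputs else None
        if "features" in inputs:
            features = assemble_features(
                read_feature_table(inputs["features"]),
                read_mutation_flags(inputs["mutations"]) if "mutations" in inputs else None,
                read_signature_contributions(inputs["signatures"])
                if "signatures" in inputs else None,
            )
        if "expression" in inputs:
            expr = read_expression(inputs["expression"], inputs["annotation"])

    her2_result = None
    if "her2" in stages:
        try:
            her2_result = hc.assign_cohort_her2(
                expr, features, criterion=str(choices["roc_criterion"]))
            calls = pd.DataFrame(
                [{"sample_id": s, "erbb2_cn": c.erbb2_cn, "call": c.call,
                  "provenance": c.provenance} for s, c in her2_result.calls.items()]
            ).set_index("sample_id")
            path = outdir / "her2_calls.tsv"
            calls.to_csv(path, sep="\t")
            record("her2:calls", path)
            roc = her2_result.roc
            roc_path = outdir / "her2_roc.tsv"
            pd.DataFrame({"threshold": roc.thresholds,
                          "sensitivity": roc.sensitivity,
                          "specificity": roc.specificity}).to_csv(
                roc_path, sep="\t", index=False)
            record("her2:roc", roc_path)
            choices["cn_threshold"] = her2_result.threshold
        except Exception as exc:
            raise StageError("her2", exc) from exc

    scores = None
    if "risk" in stages:
        try:
            scores = rm.score_cohort(features, clinical)
            path = outdir / "risk_scores.tsv"
            scores.to_csv(path, sep="\t")
            record("risk:scores", path)
        except Exception as exc:
            raise StageError("risk", exc) from exc

    if "survival" in stages:
        try:
            if scores is None:
                raise ValueError("survival stage requires the risk stage output")
            clin = {c.sample_id: c for c in clinical}
            ids = [s for s in scores.index if clin[s].pfs_time is not None]
            km = rm.km_logrank(
                scores.loc[ids, "label"],
                pd.Series({s: clin[s].pfs_time for s in ids}),
                pd.Series({s: clin[s].pfs_event for s in ids}),
            )
            path = outdir / "km.tsv"
            tables = [t.assign(group=g) for g, t in km.curves.items()]
            pd.concat(tables).to_csv(path, sep="\t")
            record("survival:km", path)
            choices["logrank_p"] = km.p
        except Exception as exc:
            raise StageError("survival", exc) from exc

    if "profile" in stages:
        try:
            if her2_result is None:
                raise ValueError("profile stage requires the her2 stage output")
            prior = {c.sample_id: c.prior_anti_her2 for c in clinical}
            groups = ep.make_four_groups(
                {s: c.call for s, c in her2_result.calls.items()}, prior)
            selection = ep.select_her2_genes(expr, groups)
            sel_path = outdir / "selected_genes.tsv"
            selection.frame.to_csv(sel_path, sep="\t")
            record("profile:selected_genes", sel_path)
            clust = ep.cluster_on_profile(
                expr, selection.selected_genes,
                k=int(choices["k_clusters"]), linkage=str(choices["linkage"]))
            lab_path = outdir / "cluster_labels.tsv"
            clust.labels.rename_axis("sample_id").to_csv(lab_path, sep="\t")
            record("profile:labels", lab_path)
            her2_ann = pd.Series(
                {s: c.call == "positive" for s, c in her2_result.calls.items()})
            enrich = ep.cluster_enrichment(clust.labels, her2_ann)
            enr_path = outdir / "cluster_enrichment.tsv"
            enrich.to_csv(enr_path, sep="\t")
            record("profile:enrichment", enr_path)
        except Exception as exc:
            raise StageError("profile", exc) from exc

    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "config": _jsonable(config),
        "choices": choices,
        "files": dict(sorted(files.items())),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
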