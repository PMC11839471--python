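"""End-to-end orchestration: preprocess -> select -> enrich -> drugs -> validate.

:func:`run_study` drives the full analysis on in-memory objects;
:func:`run_all` wraps it with config-file parsing, input checksumming,
output writing and a run manifest.  A single global seed is expanded into
per-stage substreams (one per cancer type and omics layer for the
enrichment bootstrap, one for the randomization test) so every stage is
individually replayable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, PathwayDB, RPKM
from . import io as opio
from .preprocess import cap_outliers, log2_transform
from .markers import select_proteins, select_transcripts
from .enrichment import add_bootstrap, characteristic_pathways, fisher_enrich
from .drugs import collect_multi_pathway_targets, flag_approved, link_drugs
from .validation import compare_mnauc, randomization_hit_test

log = logging.getLogger("oncopath")

__all__ = ["PipelineParams", "StudyResult", "run_study", "run_all", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for malformed or incomplete run configurations."""


@dataclass
class PipelineParams:
    pseudocount: float = 1.0
    anova_alpha: float = 0.05
    protein_alpha: float = 0.05
    significance_alpha: float = 0.05
    bootstrap_reps: int = 1000
    min_pathways: int = 2
    k_clusters: int = 2
    purity_scheme: str = "binary"
    hitrate_n_pairs: int = 1000
    hitrate_n_reps: int = 100
    seed: int = 17


@dataclass
class StudyResult:
    capping_report: object
    marker_sets: dict  # (cancer_type, layer) -> SignificantFeatureSet
    enrichment: dict  # (cancer_type, layer) -> DataFrame
    characteristic: dict  # cancer_type -> DataFrame
    candidates: pd.DataFrame
    mnauc_comparison: object | None
    hitrate: object | None
    counts: dict = field(default_factory=dict)


def run_study(
    transcript: ExpressionMatrix,
    protein: ExpressionMatrix,
    labels: dict[str, str],
    pathways: PathwayDB,
    drug_targets: dict[str, frozenset[str]],
    approved_pairs: set[tuple[str, str]] | None = None,
    mnauc: dict[str, float] | None = None,
    params: PipelineParams | None = None,
) -> StudyResult:
    """Run the full analysis on in-memory inputs."""
    params = params or PipelineParams()
    seed_seq = np.random.SeedSequence(params.seed)
    classes = sorted({labels[s] for s in transcript.sample_ids if s in labels})
    if len(classes) < 2:
        raise ValueError("need at least 2 cancer types")

    t0 = time.time()
    if transcript.scale == RPKM:
        capped, report = cap_outliers(transcript)
        log2m = log2_transform(capped, pseudocount=params.pseudocount)
    else:  # already log2 (pre-transformed input)
        report = None
        log2m = transcript
    log.info("preprocess: %d features x %d samples (%.1fs)", log2m.n_features, log2m.n_samples, time.time() - t0)

    t_universe = log2m.symbol_universe()
    p_universe = protein.symbol_universe()

    # per-(class, layer) bootstrap substreams, then one for the hit-rate test
    children = seed_seq.spawn(2 * len(classes) + 1)
    stream = {
        (cls, layer): np.random.default_rng(children[2 * i + j])
        for i, cls in enumerate(classes)
        for j, layer in enumerate(("transcript", "protein"))
    }
    hit_rng = np.random.default_rng(children[-1])

    marker_sets: dict = {}
    enrichment: dict = {}
    characteristic: dict = {}
    all_candidates = []
    for cls in classes:
        t0 = time.time()
        sel_t = select_transcripts(
            log2m,
            labels,
            cls,
            anova_alpha=params.anova_alpha,
            k_clusters=params.k_clusters,
            purity_scheme=params.purity_scheme,
        )
        sel_p = select_proteins(
            protein, labels, cls, alpha=params.protein_alpha, anova_alpha=params.anova_alpha
        )
        marker_sets[(cls, "transcript")] = sel_t
        marker_sets[(cls, "protein")] = sel_p

        enr = {}
        for layer, sel, universe, matrix in (
            ("transcript", sel_t, t_universe, log2m),
            ("protein", sel_p, p_universe, protein),
        ):
            sig = sel.gene_symbols(matrix) & universe
            records = fisher_enrich(sig, universe, pathways)
            records = add_bootstrap(
                records,
                n_reps=params.bootstrap_reps,
                rng=stream[(cls, layer)],
                alpha=params.significance_alpha,
            )
            enr[layer] = records
            enrichment[(cls, layer)] = records
        char = characteristic_pathways(
            enr["transcript"], enr["protein"], alpha=params.significance_alpha
        )
        characteristic[cls] = char

        genes = collect_multi_pathway_targets(
            char["pathway_id"], pathways, min_pathways=params.min_pathways
        )
        cands = link_drugs(
            genes, drug_targets, char["pathway_id"], pathways, min_pathways=params.min_pathways
        )
        cands = flag_approved(
            cands, cls, approved_pairs or set(), known_types=set(classes)
        )
        all_candidates.append(cands)
        log.info(
            "%s: %d transcripts, %d proteins, %d characteristic pathways, %d drug candidates (%.1fs)",
            cls, len(sel_t.feature_ids), len(sel_p.feature_ids), len(char), len(cands), time.time() - t0,
        )

    candidates = (
        pd.concat(all_candidates, ignore_index=True)
        if all_candidates
        else pd.DataFrame(
            columns=["drug_id", "cancer_type", "pathway_count", "approved", "linked_pathways", "target_genes_hit"]
        )
    )

    mn_cmp = None
    if mnauc:
        cand_drugs = set(candidates["drug_id"])
        cand_vals = [v for d, v in mnauc.items() if d in cand_drugs]
        ref_vals = [v for d, v in mnauc.items() if d not in cand_drugs]
        if cand_vals and ref_vals:
            mn_cmp = compare_mnauc(cand_vals, ref_vals)

    hit = None
    if approved_pairs is not None and len(candidates):
        predicted = set(zip(candidates["drug_id"], candidates["cancer_type"]))
        all_pairs = {(d, c) for d in drug_targets for c in classes}
        n_pairs = min(params.hitrate_n_pairs, len(all_pairs))
        hit = randomization_hit_test(
            predicted,
            all_pairs,
            approved_pairs,
            n_pairs=n_pairs,
            n_reps=params.hitrate_n_reps,
            rng=hit_rng,
        )

    counts = {
        "classes": len(classes),
        "transcripts_selected": {c: len(marker_sets[(c, "transcript")].feature_ids) for c in classes},
        "proteins_selected": {c: len(marker_sets[(c, "protein")].feature_ids) for c in classes},
        "characteristic_pathways": {c: int(len(characteristic[c])) for c in classes},
        "drug_candidates": int(len(candidates)),
    }
    return StudyResult(
        capping_report=report,
        marker_sets=marker_sets,
        enrichment=enrichment,
        characteristic=characteristic,
        candidates=candidates,
        mnauc_comparison=mn_cmp,
        hitrate=hit,
        counts=counts,
    )


_REQUIRED_INPUTS = ("gct", "protein", "labels", "gmt", "drug_targets")
_OPTIONAL_INPUTS = ("features", "approved", "mnauc")
_PARAM_KEYS = set(PipelineParams.__dataclass_fields__)


def load_config(path: str | Path) -> tuple[dict[str, Path], PipelineParams]:
    """Parse and validate a YAML run configuration.

    Layout: top-level ``inputs`` (file paths) and ``params`` mappings.
    Unknown keys anywhere are rejected by name.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"inputs", "params"}
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys: {sorted(unknown)}")
    inputs_raw = raw.get("inputs") or {}
    unknown = set(inputs_raw) - set(_REQUIRED_INPUTS) - set(_OPTIONAL_INPUTS)
    if unknown:
        raise ConfigError(f"{path}: unknown input keys: {sorted(unknown)}")
    missing = [k for k in _REQUIRED_INPUTS if k not in inputs_raw]
    if missing:
        raise ConfigError(f"{path}: missing required inputs: {missing}")
    base = path.parent
    inputs = {k: (base / v if not Path(v).is_absolute() else Path(v)) for k, v in inputs_raw.items()}
    params_raw = raw.get("params") or {}
    unknown = set(params_raw) - _PARAM_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown param keys: {sorted(unknown)}")
    return inputs, PipelineParams(**params_raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config_path: str | Path, out_dir: str | Path) -> dict:
    """Run the whole pipeline from a config file; write outputs + manifest."""
    inputs, params = load_config(config_path)
    for key, p in inputs.items():
        if not p.exists():
            raise FileNotFoundError(f"input {key!r} not found: {p}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    transcript = opio.read_gct(inputs["gct"])
    if "features" in inputs:
        transcript = opio.attach_feature_metadata(
            transcript, opio.read_feature_metadata(inputs["features"])
        )
    protein = opio.read_protein_matrix(inputs["protein"])
    labels = opio.read_labels(inputs["labels"])
    pathways = opio.read_gmt(inputs["gmt"])
    drug_targets = opio.read_drug_targets(inputs["drug_targets"])
    approved = opio.read_approved_pairs(inputs["approved"]) if "approved" in inputs else None
    mnauc = opio.read_mnauc(inputs["mnauc"]) if "mnauc" in inputs else None

    result = run_study(
        transcript, protein, labels, pathways, drug_targets, approved, mnauc, params
    )

    if result.capping_report is not None:
        rep = result.capping_report
        cap_df = rep.per_sample_max.rename("max_rpkm").to_frame()
        cap_df.insert(0, "cell_line", cap_df.index)
        cap_df.to_csv(out_dir / "capping.tsv", sep="\t", index=False, float_format="%.6g")
    for (cls, layer), sel in result.marker_sets.items():
        sel.to_frame(transcript if layer == "transcript" else protein).to_csv(
            out_dir / f"markers_{cls}_{layer}.tsv", sep="\t", float_format="%.6g",
            index_label="feature_id",
        )
        if sel.evaluations:
            pd.DataFrame([asdict(e) for e in sel.evaluations]).to_csv(
                out_dir / f"evals_{cls}.tsv", sep="\t", index=False, float_format="%.6g"
            )
    for (cls, layer), records in result.enrichment.items():
        records.to_csv(
            out_dir / f"enrich_{cls}_{layer}.tsv", sep="\t", float_format="%.6g",
            index_label="pathway_id",
        )
    for cls, char in result.characteristic.items():
        char.to_csv(out_dir / f"pathways_{cls}.tsv", sep="\t", index=False, float_format="%.6g")
    result.candidates.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)

    validation: dict = {}
    if result.mnauc_comparison is not None:
        validation["mnauc"] = asdict(result.mnauc_comparison)
    if result.hitrate is not None:
        hit = asdict(result.hitrate)
        hit.pop("replicate_hit_rates", None)
        hit.pop("per_replicate_fisher_p", None)
        validation["hitrate"] = hit
    with open(out_dir / "validation.json", "w") as fh:
        json.dump(validation, fh, indent=1, sort_keys=True)

    manifest = {
        "version": __version__,
        "seed": params.seed,
        "params": asdict(params),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "counts": result.counts,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
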