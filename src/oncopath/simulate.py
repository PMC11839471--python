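"""Seeded synthetic multi-omics study bundles with planted ground truth.

The generator emulates the seven inputs of a cell-line multi-omics drug
repurposing study: a multi-class labelled RPKM transcript matrix with
per-class marker blocks planted in log2 space, a partially overlapping
log2 protein matrix carrying the same planted shifts, a pathway database in
which planted pathways are enriched for each class's markers, drug-target
annotations where planted effective drugs target genes shared by the
planted pathways, an approved (drug, cancer type) truth set, and an mnAUC
table shifted lower for the planted effective drugs.  Everything is driven
by a single seed and the planted truth is recorded alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import LOG2, RPKM, ExpressionMatrix, PathwayDB
from . import io as opio

__all__ = ["SimConfig", "SyntheticStudyBundle", "generate_study", "write_bundle", "read_bundle"]

_BIOTYPES_NONCODING = ("pseudogene", "lincRNA", "antisense", "miRNA", "misc_RNA")


@dataclass
class SimConfig:
    """Study-generator configuration.

    Defaults describe a compact panel: 4 cancer types x 15 cell lines,
    2000 transcripts (20% non-coding, symbol-less), 50 planted markers per
    type shifted by +2 log2 units over noise sd 0.5, 60% proteome coverage,
    50 pathways of 20 genes with 3 planted pathways per type (60% of
    members drawn from that type's markers, sharing a marker core), 40
    drugs with one planted effective drug per type targeting the core, and
    mnAUC centred at 0.87 for effective drugs versus 0.96 otherwise.
    """

    n_classes: int = 4
    n_samples_per_class: int = 15
    n_features: int = 2000
    n_markers_per_class: int = 50
    effect_size_log2: float = 2.0
    noise_sd: float = 0.5
    noncoding_fraction: float = 0.2
    baseline_log2_range: tuple[float, float] = (1.0, 8.0)
    pseudocount: float = 1.0
    protein_coverage_fraction: float = 0.6
    n_pathways: int = 50
    pathway_size: int = 20
    planted_pathways_per_class: int = 3
    planted_pathway_marker_fraction: float = 0.6
    n_drugs: int = 40
    drug_targets_per_drug: int = 4
    mnauc_effective_mean: float = 0.87
    mnauc_effective_sd: float = 0.15
    mnauc_null_mean: float = 0.96
    mnauc_null_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_classes": self.n_classes,
            "n_samples_per_class": self.n_samples_per_class,
            "n_features": self.n_features,
            "n_markers_per_class": self.n_markers_per_class,
            "n_pathways": self.n_pathways,
            "pathway_size": self.pathway_size,
            "planted_pathways_per_class": self.planted_pathways_per_class,
            "n_drugs": self.n_drugs,
            "drug_targets_per_drug": self.drug_targets_per_drug,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1 (got {v})")
        for name in ("protein_coverage_fraction", "planted_pathway_marker_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1] (got {v})")
        if not 0 <= self.noncoding_fraction < 1:
            raise ValueError("noncoding_fraction must lie in [0, 1)")
        if self.effect_size_log2 < 0:
            raise ValueError("effect_size_log2 must be >= 0")
        n_coding = self.n_features - int(round(self.n_features * self.noncoding_fraction))
        if self.n_markers_per_class * self.n_classes > n_coding:
            raise ValueError(
                "n_markers_per_class x n_classes exceeds the number of protein-coding features"
            )
        if self.n_classes * self.planted_pathways_per_class > self.n_pathways:
            raise ValueError("more planted pathways than pathways")
        if self.n_classes > self.n_drugs:
            raise ValueError("need at least one drug per class")


@dataclass
class SyntheticStudyBundle:
    """A complete generated study plus its planted ground truth."""

    transcript_matrix: ExpressionMatrix  # RPKM scale
    protein_matrix: ExpressionMatrix  # log2 scale
    labels: dict[str, str]
    pathways: PathwayDB
    drug_targets: dict[str, frozenset[str]]
    approved_pairs: set[tuple[str, str]]
    mnauc: dict[str, float]
    truth: dict = field(default_factory=dict)


def generate_study(cfg: SimConfig) -> SyntheticStudyBundle:
    """Generate a synthetic study bundle from a seeded configuration."""
    rng = np.random.default_rng(cfg.seed)
    classes = [f"type_{i + 1}" for i in range(cfg.n_classes)]
    sample_ids = [
        f"CL{c * cfg.n_samples_per_class + s + 1:04d}"
        for c in range(cfg.n_classes)
        for s in range(cfg.n_samples_per_class)
    ]
    labels = {
        sid: classes[i // cfg.n_samples_per_class] for i, sid in enumerate(sample_ids)
    }
    y = np.array([labels[s] for s in sample_ids])

    n_noncoding = int(round(cfg.n_features * cfg.noncoding_fraction))
    n_coding = cfg.n_features - n_noncoding
    feature_ids = [f"T{i + 1:06d}" for i in range(cfg.n_features)]
    coding_mask = np.zeros(cfg.n_features, dtype=bool)
    coding_idx = rng.choice(cfg.n_features, size=n_coding, replace=False)
    coding_mask[coding_idx] = True
    symbols = np.full(cfg.n_features, None, dtype=object)
    symbols[coding_mask] = [f"G{i + 1:05d}" for i in range(n_coding)]
    biotypes = np.where(
        coding_mask, "protein_coding", rng.choice(_BIOTYPES_NONCODING, size=cfg.n_features)
    )

    # plant per-class marker blocks among the coding features (disjoint)
    marker_pool = rng.permutation(np.flatnonzero(coding_mask))
    markers_per_class: dict[str, np.ndarray] = {}
    for i, cls in enumerate(classes):
        start = i * cfg.n_markers_per_class
        markers_per_class[cls] = np.sort(
            marker_pool[start : start + cfg.n_markers_per_class]
        )

    baseline = rng.uniform(*cfg.baseline_log2_range, size=cfg.n_features)
    log2_values = baseline[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_features, len(sample_ids))
    )
    for cls in classes:
        cols = y == cls
        log2_values[np.ix_(markers_per_class[cls], cols)] += cfg.effect_size_log2
    rpkm = np.maximum(2.0 ** log2_values - cfg.pseudocount, 0.0)

    index = pd.Index(feature_ids, name="feature_id")
    transcript = ExpressionMatrix(
        values=pd.DataFrame(rpkm, index=index, columns=sample_ids),
        scale=RPKM,
        gene_symbols=pd.Series(symbols, index=index),
        biotypes=pd.Series(biotypes, index=index),
    )

    # protein layer: a random subset of coding genes, independent log2 noise,
    # same planted shifts (missing channels are not simulated)
    coding_features = np.flatnonzero(coding_mask)
    n_prot = max(1, int(round(n_coding * cfg.protein_coverage_fraction)))
    prot_features = np.sort(rng.choice(coding_features, size=n_prot, replace=False))
    prot_symbols = symbols[prot_features].astype(str)
    prot_baseline = rng.uniform(*cfg.baseline_log2_range, size=n_prot)
    prot_values = prot_baseline[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(n_prot, len(sample_ids))
    )
    prot_pos = {f: i for i, f in enumerate(prot_features)}
    for cls in classes:
        cols = y == cls
        rows = [prot_pos[f] for f in markers_per_class[cls] if f in prot_pos]
        prot_values[np.ix_(rows, cols)] += cfg.effect_size_log2
    prot_index = pd.Index(prot_symbols, name="feature_id")
    protein = ExpressionMatrix(
        values=pd.DataFrame(prot_values, index=prot_index, columns=sample_ids),
        scale=LOG2,
        gene_symbols=pd.Series(prot_index, index=prot_index),
    )

    # pathways: planted ones draw a marker fraction (sharing a per-class core
    # so one drug can hit them all); the rest are random coding gene sets
    sym_of = lambda idx: [str(symbols[i]) for i in idx]  # noqa: E731
    all_coding_symbols = np.array(sym_of(coding_features))
    marker_symbols = {cls: sym_of(markers_per_class[cls]) for cls in classes}
    nonmarker_symbols = np.array(
        sorted(set(all_coding_symbols) - {s for ms in marker_symbols.values() for s in ms})
    )
    n_marker_slots = max(1, int(round(cfg.pathway_size * cfg.planted_pathway_marker_fraction)))

    gene_sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    planted_pathways: dict[str, list[str]] = {cls: [] for cls in classes}
    core_genes: dict[str, list[str]] = {}
    pw_counter = 0
    for cls in classes:
        ms = marker_symbols[cls]
        n_marker_members = min(n_marker_slots, len(ms))  # clamp for tiny marker sets
        core_size = min(cfg.drug_targets_per_drug, n_marker_members)
        core = list(rng.choice(ms, size=core_size, replace=False))
        core_genes[cls] = core
        rest_markers = np.array(sorted(set(ms) - set(core)))
        for _ in range(cfg.planted_pathways_per_class):
            pw_counter += 1
            pid = f"PW{pw_counter:04d}"
            extra_m = list(
                rng.choice(rest_markers, size=n_marker_members - core_size, replace=False)
            )
            filler = list(
                rng.choice(
                    nonmarker_symbols, size=cfg.pathway_size - n_marker_members, replace=False
                )
            )
            gene_sets[pid] = frozenset(core + extra_m + filler)
            descriptions[pid] = f"synthetic pathway ({cls})"
            planted_pathways[cls].append(pid)
    while pw_counter < cfg.n_pathways:
        pw_counter += 1
        pid = f"PW{pw_counter:04d}"
        gene_sets[pid] = frozenset(
            rng.choice(all_coding_symbols, size=cfg.pathway_size, replace=False)
        )
        descriptions[pid] = "synthetic pathway (background)"
    pathways = PathwayDB(gene_sets=gene_sets, descriptions=descriptions)

    # drugs: one planted effective drug per class targets that class's core
    drug_ids = [f"D{i + 1:03d}" for i in range(cfg.n_drugs)]
    planted_drugs = {cls: drug_ids[i] for i, cls in enumerate(classes)}
    drug_targets: dict[str, frozenset[str]] = {}
    for i, drug in enumerate(drug_ids):
        if i < len(classes):
            drug_targets[drug] = frozenset(core_genes[classes[i]])
        else:
            drug_targets[drug] = frozenset(
                rng.choice(nonmarker_symbols, size=cfg.drug_targets_per_drug, replace=False)
            )

    approved_pairs = {(planted_drugs[cls], cls) for cls in classes}

    effective = set(planted_drugs.values())
    mnauc: dict[str, float] = {}
    for drug in drug_ids:
        if drug in effective:
            v = rng.normal(cfg.mnauc_effective_mean, cfg.mnauc_effective_sd)
        else:
            v = rng.normal(cfg.mnauc_null_mean, cfg.mnauc_null_sd)
        mnauc[drug] = float(np.clip(v, 0.05, 2.0))

    truth = {
        "classes": classes,
        "markers": {cls: [feature_ids[i] for i in markers_per_class[cls]] for cls in classes},
        "marker_symbols": {cls: marker_symbols[cls] for cls in classes},
        "pathways": planted_pathways,
        "drugs": {cls: planted_drugs[cls] for cls in classes},
        "core_genes": core_genes,
        "protein_genes": prot_symbols.tolist(),
        "config": _config_to_jsonable(cfg),
    }
    return SyntheticStudyBundle(
        transcript_matrix=transcript,
        protein_matrix=protein,
        labels=labels,
        pathways=pathways,
        drug_targets=drug_targets,
        approved_pairs=approved_pairs,
        mnauc=mnauc,
        truth=truth,
    )


def _config_to_jsonable(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["baseline_log2_range"] = list(d["baseline_log2_range"])
    return d


def write_bundle(bundle: SyntheticStudyBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle as plain-text files readable by :mod:`oncopath.io`.

    Emits expr.gct, features.tsv, prot.tsv, labels.tsv, pathways.gmt,
    drug_targets.tsv, approved.tsv, mnauc.tsv and truth.json.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": directory / "expr.gct",
        "features": directory / "features.tsv",
        "prot": directory / "prot.tsv",
        "labels": directory / "labels.tsv",
        "pathways": directory / "pathways.gmt",
        "drug_targets": directory / "drug_targets.tsv",
        "approved": directory / "approved.tsv",
        "mnauc": directory / "mnauc.tsv",
        "truth": directory / "truth.json",
    }
    opio.write_gct(bundle.transcript_matrix, paths["expr"])
    opio.write_feature_metadata(bundle.transcript_matrix, paths["features"])
    opio.write_protein_matrix(bundle.protein_matrix, paths["prot"])
    opio.write_labels(bundle.labels, paths["labels"])
    opio.write_gmt(bundle.pathways, paths["pathways"])
    opio.write_drug_targets(bundle.drug_targets, paths["drug_targets"])
    opio.write_approved_pairs(bundle.approved_pairs, paths["approved"])
    opio.write_mnauc(bundle.mnauc, paths["mnauc"])
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
    return paths


def read_bundle(directory: str | Path) -> SyntheticStudyBundle:
    """Read back a bundle written by :func:`write_bundle`."""
    directory = Path(directory)
    transcript = opio.read_gct(directory / "expr.gct")
    meta = opio.read_feature_metadata(directory / "features.tsv")
    transcript = opio.attach_feature_metadata(transcript, meta)
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return SyntheticStudyBundle(
        transcript_matrix=transcript,
        protein_matrix=opio.read_protein_matrix(directory / "prot.tsv"),
        labels=opio.read_labels(directory / "labels.tsv"),
        pathways=opio.read_gmt(directory / "pathways.gmt"),
        drug_targets=opio.read_drug_targets(directory / "drug_targets.tsv"),
        approved_pairs=opio.read_approved_pairs(directory / "approved.tsv"),
        mnauc=opio.read_mnauc(directory / "mnauc.tsv"),
        truth=truth,
    )
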