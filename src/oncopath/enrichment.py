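"""Pathway enrichment: Fisher exact test, BH-FDR, permutation bootstrap and
the cross-omics combined significance score.

For one cancer type and one omics layer, the significant gene set is tested
against every pathway with a one-sided (enrichment) Fisher exact test —
equivalently, the hypergeometric upper tail P(X >= k) — over the platform
universe (all gene symbols measurable on that layer).  P values are BH-FDR
corrected across pathways; pathways reaching FDR P < 0.05 are confirmed by a
permutation bootstrap: 1000 random same-size gene sets are drawn from the
universe and the bootstrap P value is the fraction of replicates whose
Fisher P beats the observed one.  Transcript- and protein-layer FDR P values
for a pathway are finally combined into a significance score, the average of
their log10 values; pathways significant on both layers are the cancer
type's characteristic pathways, ranked ascending by score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import PathwayDB
from .markers import bh_adjust

__all__ = [
    "fisher_pvalue",
    "fisher_enrich",
    "bootstrap_p_from_replicates",
    "bootstrap_pathway",
    "add_bootstrap",
    "combine_scores",
    "characteristic_pathways",
]

SIGNIFICANCE_ALPHA = 0.05


def fisher_pvalue(k: int, K: int, n: int, N: int) -> float:
    """One-sided Fisher exact (enrichment) P value: P(X >= k) for
    X ~ Hypergeom(N, K, n).

    k: significant genes in the pathway; K: pathway size within the
    universe; n: significant genes; N: universe size.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent 2x2 counts: k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrich(
    sig_genes: set[str],
    universe: set[str],
    db: PathwayDB,
) -> pd.DataFrame:
    """Fisher enrichment of ``sig_genes`` against every pathway in ``db``.

    Pathways are intersected with the universe before counting; pathways
    with no gene in the universe are skipped.  Returns a DataFrame indexed
    by pathway id with columns ``k, K, n, N, p_fisher, p_fdr``.
    """
    sig_genes = set(sig_genes)
    universe = set(universe)
    stray = sig_genes - universe
    if stray:
        raise ValueError(
            f"{len(stray)} significant genes outside the universe: {sorted(stray)[:5]}"
        )
    N = len(universe)
    n = len(sig_genes)
    rows = []
    for pid, genes in db.items():
        members = genes & universe
        K = len(members)
        if K == 0:
            continue
        k = len(sig_genes & members)
        rows.append((pid, k, K, n, N, fisher_pvalue(k, K, n, N)))
    out = pd.DataFrame(
        rows, columns=["pathway_id", "k", "K", "n", "N", "p_fisher"]
    ).set_index("pathway_id")
    out["p_fdr"] = bh_adjust(out["p_fisher"].to_numpy()) if len(out) else np.nan
    return out


def bootstrap_p_from_replicates(observed_p: float, replicate_p) -> float:
    """The bootstrap counting estimator: the fraction of replicate P values
    strictly smaller than the observed one.

    Five of 1000 replicates below the observed P gives 0.005.  A count of
    zero is reported as 0.0 (not smoothed), matching the counting formula.
    """
    replicate_p = np.asarray(replicate_p, dtype=float)
    if replicate_p.size < 1:
        raise ValueError("need at least one bootstrap replicate")
    return float(np.count_nonzero(replicate_p < observed_p)) / replicate_p.size


def bootstrap_pathway(
    k: int,
    K: int,
    n: int,
    N: int,
    n_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation bootstrap P value for one pathway's enrichment.

    Each replicate draws a uniform random gene set of size ``n`` from the
    universe and computes its Fisher P for the pathway.  Because that P
    depends on the random set only through its overlap with the pathway, the
    overlap is sampled directly from Hypergeom(N, K, n) — an exactly
    equivalent, allocation-free realization of the same draw.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng)
    observed = fisher_pvalue(k, K, n, N)
    rep_k = rng.hypergeometric(K, N - K, n, size=n_reps)
    rep_p = hypergeom.sf(rep_k - 1, N, K, n)
    return bootstrap_p_from_replicates(observed, rep_p)


def add_bootstrap(
    records: pd.DataFrame,
    n_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    alpha: float = SIGNIFICANCE_ALPHA,
) -> pd.DataFrame:
    """Run the bootstrap for every record with ``p_fdr < alpha``.

    Adds a ``p_bootstrap`` column (NaN where the bootstrap was not run).
    Pathways are processed in index order so a seeded generator reproduces
    results bit for bit.
    """
    rng = np.random.default_rng(rng)
    out = records.copy()
    out["p_bootstrap"] = np.nan
    for pid in out.index[out["p_fdr"] < alpha]:
        row = out.loc[pid]
        out.loc[pid, "p_bootstrap"] = bootstrap_pathway(
            int(row["k"]), int(row["K"]), int(row["n"]), int(row["N"]), n_reps=n_reps, rng=rng
        )
    return out


def combine_scores(p_fdr_transcript: float, p_fdr_protein: float) -> float:
    """Cross-omics significance score: mean of the log10 FDR P values.

    Smaller (more negative) = more significant.  Zero P values are floored
    at the smallest positive normal float with a warning.
    """
    ps = []
    for p in (p_fdr_transcript, p_fdr_protein):
        if not (0 <= p <= 1):
            raise ValueError(f"FDR p value {p} outside [0, 1]")
        if p == 0:
            warnings.warn("FDR p of 0 floored at the smallest representable positive value")
            p = float(np.finfo(float).tiny)
        ps.append(p)
    return float((np.log10(ps[0]) + np.log10(ps[1])) / 2)


def characteristic_pathways(
    transcript_records: pd.DataFrame,
    protein_records: pd.DataFrame,
    alpha: float = SIGNIFICANCE_ALPHA,
) -> pd.DataFrame:
    """Pathways significant on both omics layers, ranked by combined score.

    Significance on a layer means FDR P < alpha AND bootstrap P < alpha.
    Returns a DataFrame with columns ``pathway_id, p_fdr_transcript,
    p_fdr_protein, score`` sorted ascending by score, ties broken
    alphabetically by pathway id.
    """

    def _significant(records: pd.DataFrame) -> pd.Index:
        ok = (records["p_fdr"] < alpha) & (records["p_bootstrap"] < alpha)
        return records.index[ok.fillna(False)]

    shared = _significant(transcript_records).intersection(_significant(protein_records))
    rows = [
        {
            "pathway_id": pid,
            "p_fdr_transcript": transcript_records.loc[pid, "p_fdr"],
            "p_fdr_protein": protein_records.loc[pid, "p_fdr"],
            "score": combine_scores(
                transcript_records.loc[pid, "p_fdr"], protein_records.loc[pid, "p_fdr"]
            ),
        }
        for pid in shared
    ]
    out = pd.DataFrame(rows, columns=["pathway_id", "p_fdr_transcript", "p_fdr_protein", "score"])
    return out.sort_values(["score", "pathway_id"], kind="stable").reset_index(drop=True)
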