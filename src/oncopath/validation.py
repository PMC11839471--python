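"""Quantitative validation of predicted drug-cancer-type pairs.

Two checks mirror how pathway-derived drug candidates are evaluated against
external evidence:

* a Wilcoxon rank-sum (Mann-Whitney U) comparison of mnAUC — the mean
  normalized area under the dose-response curve, i.e. the average fraction
  of cells surviving drug exposure (lower = more potent) — between the
  candidate drugs and a reference drug set;

* a randomization hit-rate test: a predicted (drug, cancer type) pair is a
  "hit" when the drug is an approved targeted therapy for that cancer type;
  the predicted hit rate is compared with the mean hit rate of repeated
  uniform samples of pairs, and the difference is tested with a two-sided
  Fisher exact test on the pooled 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MnAUCComparison",
    "HitRateResult",
    "compare_mnauc",
    "randomization_hit_test",
]


@dataclass
class MnAUCComparison:
    mean_candidates: float
    mean_reference: float
    wilcoxon_p: float
    n_candidates: int
    n_reference: int


@dataclass
class HitRateResult:
    predicted_pairs: int
    predicted_hits: int
    n_pairs_per_rep: int
    n_reps: int
    mean_random_hit_rate: float
    predicted_hit_rate: float
    fisher_p: float
    replicate_hit_rates: list[float] = field(default_factory=list)
    per_replicate_fisher_p: list[float] = field(default_factory=list)


def compare_mnauc(candidates, reference, exact_max_n: int = 25) -> MnAUCComparison:
    """Two-sided Wilcoxon rank-sum comparison of two mnAUC samples.

    Uses the exact U distribution when both samples have at most
    ``exact_max_n`` values and no ties straddle the groups; otherwise the
    normal approximation with tie correction.  Means are reported to two
    decimals.
    """
    a = np.asarray(list(candidates), dtype=float)
    b = np.asarray(list(reference), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both mnAUC samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= exact_max_n and not has_ties) else "asymptotic"
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MnAUCComparison(
        mean_candidates=round(float(a.mean()), 2),
        mean_reference=round(float(b.mean()), 2),
        wilcoxon_p=float(min(p, 1.0)),
        n_candidates=int(a.size),
        n_reference=int(b.size),
    )


def randomization_hit_test(
    predicted: set[tuple[str, str]],
    all_pairs: set[tuple[str, str]],
    approved: set[tuple[str, str]],
    n_pairs: int = 1000,
    n_reps: int = 100,
    rng: np.random.Generator | int | None = None,
    mode: str = "pooled",
) -> HitRateResult:
    """Compare the predicted hit rate with random (drug, cancer type) draws.

    Each replicate samples ``n_pairs`` pairs uniformly without replacement
    from ``all_pairs`` and counts how many are approved.  ``mode="pooled"``
    (default) builds one Fisher 2x2 table from the predictions against all
    replicates pooled; ``mode="per_replicate"`` additionally reports a
    Fisher p per replicate (the pooled p is still the headline number).
    """
    predicted = set(predicted)
    all_pairs_list = sorted(all_pairs)
    if not predicted:
        raise ValueError("no predicted pairs to evaluate")
    if not predicted <= set(all_pairs_list):
        stray = sorted(predicted - set(all_pairs_list))[:5]
        raise ValueError(f"predicted pairs outside the sampling universe: {stray}")
    if n_pairs > len(all_pairs_list):
        raise ValueError("n_pairs exceeds the size of the pair universe")
    if mode not in ("pooled", "per_replicate"):
        raise ValueError("mode must be 'pooled' or 'per_replicate'")
    rng = np.random.default_rng(rng)

    approved = set(approved)
    is_hit = np.array([pair in approved for pair in all_pairs_list])
    n_universe = len(all_pairs_list)

    rep_hits = np.empty(n_reps, dtype=int)
    per_rep_p: list[float] = []
    predicted_hits = sum(1 for pair in predicted if pair in approved)
    n_predicted = len(predicted)
    for r in range(n_reps):
        idx = rng.choice(n_universe, size=n_pairs, replace=False)
        rep_hits[r] = int(is_hit[idx].sum())
        if mode == "per_replicate":
            table = [
                [predicted_hits, n_predicted - predicted_hits],
                [int(rep_hits[r]), n_pairs - int(rep_hits[r])],
            ]
            per_rep_p.append(float(stats.fisher_exact(table, alternative="two-sided")[1]))

    pooled_hits = int(rep_hits.sum())
    pooled_total = n_pairs * n_reps
    table = [
        [predicted_hits, n_predicted - predicted_hits],
        [pooled_hits, pooled_total - pooled_hits],
    ]
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return HitRateResult(
        predicted_pairs=n_predicted,
        predicted_hits=predicted_hits,
        n_pairs_per_rep=n_pairs,
        n_reps=n_reps,
        mean_random_hit_rate=float(rep_hits.mean() / n_pairs),
        predicted_hit_rate=predicted_hits / n_predicted,
        fisher_p=fisher_p,
        replicate_hit_rates=(rep_hits / n_pairs).tolist(),
        per_replicate_fisher_p=per_rep_p,
    )
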