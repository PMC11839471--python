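"""Pathway-mediated drug repurposing.

Genes sitting in multiple characteristic pathways of a cancer type are
collected as candidate molecular targets; drugs (DrugBank/KEGG target
annotations) hitting at least one such gene become candidates for that
cancer type.  A candidate's strength is its pathway count — the number of
characteristic pathways containing at least one of the drug's targets
(union over targets).  Candidates are ranked by pathway count and annotated
against the approved targeted-therapy table.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .containers import PathwayDB

__all__ = [
    "collect_multi_pathway_targets",
    "link_drugs",
    "flag_approved",
]


def collect_multi_pathway_targets(
    characteristic_ids,
    db: PathwayDB,
    min_pathways: int = 2,
) -> set[str]:
    """Genes appearing in at least ``min_pathways`` characteristic pathways."""
    if min_pathways < 1:
        raise ValueError("min_pathways must be >= 1")
    counts: dict[str, int] = {}
    for pid in characteristic_ids:
        for gene in db[pid]:
            counts[gene] = counts.get(gene, 0) + 1
    return {g for g, c in counts.items() if c >= min_pathways}


def link_drugs(
    genes: set[str],
    drug_targets: dict[str, frozenset[str]],
    characteristic_ids,
    db: PathwayDB,
    min_pathways: int = 2,
) -> pd.DataFrame:
    """Link drugs to a cancer type through its characteristic pathways.

    A drug qualifies if at least one of its targets is in ``genes`` (the
    multi-pathway target set).  Its linked pathways are all characteristic
    pathways containing any of its targets; drugs whose pathway count falls
    below ``min_pathways`` are dropped.  Sorted by descending pathway count,
    ties alphabetical by drug id.
    """
    characteristic_ids = list(characteristic_ids)
    rows = []
    for drug in sorted(drug_targets):
        targets = set(drug_targets[drug])
        hit_genes = targets & genes
        if not hit_genes:
            continue
        linked = [pid for pid in characteristic_ids if db[pid] & targets]
        if len(linked) < min_pathways:
            continue
        rows.append(
            {
                "drug_id": drug,
                "pathway_count": len(linked),
                "linked_pathways": ";".join(sorted(linked)),
                "target_genes_hit": ";".join(sorted(hit_genes)),
            }
        )
    out = pd.DataFrame(rows, columns=["drug_id", "pathway_count", "linked_pathways", "target_genes_hit"])
    return out.sort_values(
        ["pathway_count", "drug_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def flag_approved(
    candidates: pd.DataFrame,
    cancer_type: str,
    approved_pairs: set[tuple[str, str]],
    known_types: set[str] | None = None,
) -> pd.DataFrame:
    """Annotate candidates with whether (drug, cancer type) is an approved
    targeted therapy.

    When ``known_types`` is given, approved-table cancer-type strings outside
    that vocabulary trigger a warning listing the unmatched labels.
    """
    if known_types is not None:
        unmatched = sorted({t for _, t in approved_pairs} - set(known_types))
        if unmatched:
            warnings.warn(
                f"approved table lists cancer types outside the annotation vocabulary: {unmatched}"
            )
    out = candidates.copy()
    out["cancer_type"] = cancer_type
    out["approved"] = [
        (drug, cancer_type) in approved_pairs for drug in out["drug_id"]
    ]
    cols = ["drug_id", "cancer_type", "pathway_count", "approved", "linked_pathways", "target_genes_hit"]
    return out[cols]
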