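"""Screen quality control: score concordance and reference-set separation.

Two checks mirror how dropout screens are validated in practice: (i) the
Pearson correlation of gene med.CS between independent analysis units
(half-libraries A vs B, or two cell lines), and (ii) how cleanly the
score separates known common-essential genes from known nonessential
genes, summarized per set (median med.CS) and globally as an AUROC where
more-negative scores rank higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection


@dataclass(frozen=True)
class CorrelationReport:
    pairing: tuple[str, str]
    n_genes_common: int
    pearson_r: float
    p_value: float


@dataclass(frozen=True)
class SetSeparation:
    name: str
    role: str
    n_genes_found: int
    median_med_cs: float


@dataclass(frozen=True)
class SeparationReport:
    per_set: list[SetSeparation]
    auroc: float
    n_essential: int
    n_nonessential: int


def _scored(gene_scores: pd.DataFrame) -> pd.DataFrame:
    return gene_scores[gene_scores["status"] == "scored"]


def correlate_gene_scores(
    a: pd.DataFrame,
    b: pd.DataFrame,
    labels: tuple[str, str] = ("unit1", "unit2"),
) -> CorrelationReport:
    """Pearson r (with two-sided p) of med.CS over commonly scored genes.

    Symmetric in its arguments; requires at least 3 common genes.
    """
    merged = _scored(a).merge(_scored(b), on="gene", suffixes=("_1", "_2"))
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} genes scored in both units; need >= 3"
        )
    r, p = stats.pearsonr(merged["med_cs_1"], merged["med_cs_2"])
    return CorrelationReport(labels, len(merged), float(r), float(p))


def ranking_auroc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUROC for "positives score more negative", via the rank-sum identity.

    Midranks handle ties, so this equals the normalized Mann-Whitney U
    statistic and is invariant to strictly monotone transforms.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([-pos, -neg]))  # negate: depleted first
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def reference_separation(
    gene_scores: pd.DataFrame, refs: GeneSetCollection
) -> SeparationReport:
    """Separation of essential vs nonessential reference sets by med.CS.

    Reports each reference set's coverage and median med.CS, and a global
    AUROC with the union of essential_reference sets as positives and the
    union of nonessential_reference sets as negatives (genes in both
    unions are excluded from the negatives). Genes absent from the scored
    table count toward n_genes_found bookkeeping only.
    """
    ess_sets = refs.by_role("essential_reference")
    non_sets = refs.by_role("nonessential_reference")
    if not ess_sets or not non_sets:
        raise ValueError(
            "need at least one essential_reference and one nonessential_reference set"
        )
    scored = _scored(gene_scores).set_index("gene")["med_cs"]
    per_set = []
    for name, members in {**ess_sets, **non_sets}.items():
        found = scored.index.intersection(members)
        per_set.append(
            SetSeparation(
                name=name,
                role=refs.roles[name],
                n_genes_found=len(found),
                median_med_cs=float(scored.loc[found].median()) if len(found) else np.nan,
            )
        )
    ess = refs.union_of_role("essential_reference")
    non = refs.union_of_role("nonessential_reference") - ess
    pos = scored.loc[scored.index.intersection(ess)]
    neg = scored.loc[scored.index.intersection(non)]
    auroc = ranking_auroc(pos.to_numpy(), neg.to_numpy())
    return SeparationReport(per_set, auroc, len(pos), len(neg))


def separation_table(report: SeparationReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": s.name,
                "role": s.role,
                "n_genes_found": s.n_genes_found,
                "median_med_cs": s.median_med_cs,
            }
            for s in report.per_set
        ]
    )
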