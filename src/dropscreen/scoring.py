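"""CRISPR score (CS) and gene-level med.CS computation.

Per analysis unit (cell line, half-library, replicate): guides with fewer
than 50 reads in the PD0 baseline sample are removed; normalized abundance
is the per-sample proportion after adding a pseudocount of 1 to every raw
count; the guide log2 fold-change L_i = log2(p_PD14 / p_PD0); and the
CRISPR score CS_i subtracts the median L over surviving nontargeting
controls, so the nontargeting median CS is exactly zero in every unit.
Replicates are averaged at guide level, the A/B half-libraries are merged
by concatenation, and the gene score med.CS is the median CS over a
gene's surviving guides (genes with fewer than ``min_guides`` survivors
are reported but carry no score).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountTable, LibraryManifest

logger = logging.getLogger(__name__)

DEFAULT_PD0_THRESHOLD = 50
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_MIN_GUIDES = 3


def iter_units(counts: CountTable):
    """Yield ((cell_line, library, replicate), pd0_sample_id, pd14_sample_id).

    Each replicate unit must have exactly one PD0 and one PD14 sample.
    """
    for key, grp in counts.samples.groupby(["cell_line", "library", "replicate"]):
        pd0 = grp.loc[grp["timepoint"] == "PD0", "sample_id"]
        pd14 = grp.loc[grp["timepoint"] == "PD14", "sample_id"]
        if len(pd0) != 1 or len(pd14) != 1:
            raise ValueError(
                f"analysis unit {key} needs exactly one PD0 and one PD14 sample "
                f"(got {len(pd0)} and {len(pd14)})"
            )
        yield key, pd0.iloc[0], pd14.iloc[0]


def _single_unit(counts: CountTable) -> tuple[tuple, str, str]:
    units = list(iter_units(counts))
    if len(units) != 1:
        raise ValueError(
            f"expected a single analysis unit, found {len(units)}; "
            "use score_screen / CrisprScreen for multi-unit tables"
        )
    return units[0]


def filter_low_pd0(
    counts: CountTable,
    manifest: LibraryManifest | None = None,
    threshold: int = DEFAULT_PD0_THRESHOLD,
) -> CountTable:
    """Remove guides with PD0 count below ``threshold`` from one unit.

    Operates on a count table restricted to a single analysis unit (one
    cell line / library / replicate). Removals are logged per category
    when a manifest is supplied. A guide with exactly ``threshold`` reads
    is retained (the filter is strictly "less than").
    """
    _, pd0_id, _ = _single_unit(counts)
    keep = counts.counts[pd0_id] >= threshold
    removed = counts.counts.index[~keep]
    if manifest is not None and len(removed):
        nt = manifest.nontargeting_ids
        n_nt = sum(1 for g in removed if g in nt)
        logger.info(
            "PD0 filter (<%d): removed %d guides (%d targeting, %d nontargeting)",
            threshold,
            len(removed),
            len(removed) - n_nt,
            n_nt,
        )
    elif len(removed):
        logger.info("PD0 filter (<%d): removed %d guides", threshold, len(removed))
    return CountTable(counts.counts[keep.to_numpy()], counts.samples)


def compute_cs(
    counts: CountTable,
    manifest: LibraryManifest,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-guide CRISPR scores for one (already PD0-filtered) unit.

    Returns a table with columns sgrna_id, gene, log2fc, cs, cell_line,
    library, replicate. Raises if no surviving nontargeting guide exists
    (the normalization is undefined without the null distribution).
    """
    (cell_line, library, replicate), pd0_id, pd14_id = _single_unit(counts)
    c0 = counts.counts[pd0_id].to_numpy(dtype=float) + pseudocount
    c14 = counts.counts[pd14_id].to_numpy(dtype=float) + pseudocount
    p0 = c0 / c0.sum()
    p14 = c14 / c14.sum()
    lfc = np.log2(p14 / p0)
    ids = counts.counts.index
    nt_mask = np.asarray(ids.isin(manifest.nontargeting_ids), dtype=bool)
    if not nt_mask.any():
        raise ValueError(
            f"no surviving nontargeting guides in unit "
            f"({cell_line}, {library}, {replicate}); CS undefined"
        )
    # Subtract the NT median so that the median CS over nontargeting
    # guides is exactly zero. For an even NT count the two central order
    # statistics must land at exactly +/-h, which plain subtraction of the
    # rounded midpoint does not guarantee; anchoring at the lower central
    # value makes the cancellation exact in floating point.
    nt_sorted = np.sort(lfc[nt_mask])
    k = len(nt_sorted)
    if k % 2 == 1:
        cs = lfc - nt_sorted[k // 2]
    else:
        lo, hi = nt_sorted[k // 2 - 1], nt_sorted[k // 2]
        cs = (lfc - lo) - (hi - lo) / 2.0
    gene_of = manifest.gene_of()
    return pd.DataFrame(
        {
            "sgrna_id": ids,
            "gene": gene_of.reindex(ids).to_numpy(),
            "log2fc": lfc,
            "cs": cs,
            "cell_line": cell_line,
            "library": library,
            "replicate": replicate,
        }
    ).reset_index(drop=True)


def aggregate_replicates(scores: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean guide-level CS across replicates where the guide survived.

    A guide filtered out in some replicates keeps the mean over the
    replicates in which it survived, with ``n_reps`` recording how many
    contributed; guides surviving in no replicate are absent.
    """
    if len(scores) == 0:
        raise ValueError("no replicate score tables given")
    pooled = pd.concat(scores, ignore_index=True)
    units = pooled[["cell_line", "library"]].drop_duplicates()
    if len(units) != 1:
        raise ValueError("replicate tables span multiple (cell_line, library) units")
    agg = (
        pooled.groupby("sgrna_id", sort=False)
        .agg(
            gene=("gene", "first"),
            log2fc=("log2fc", "mean"),
            cs=("cs", "mean"),
            n_reps=("cs", "size"),
        )
        .reset_index()
    )
    agg["cell_line"] = units.iloc[0]["cell_line"]
    agg["library"] = units.iloc[0]["library"]
    return agg


def merge_libraries(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> pd.DataFrame:
    """Concatenate guide-level scores of the two half-libraries.

    The A/B guide universes must be disjoint; after merging, the gene
    collapse operates on up to the full per-gene multiplicity (6 guides).
    An empty half is allowed (merge is identity on the other).
    """
    if len(scores_a) == 0:
        return scores_b.copy()
    if len(scores_b) == 0:
        return scores_a.copy()
    overlap = set(scores_a["sgrna_id"]) & set(scores_b["sgrna_id"])
    if overlap:
        raise ValueError(
            f"half-libraries share guide ids (not an A/B partition): "
            f"{sorted(overlap)[:5]}"
        )
    cl = set(scores_a["cell_line"]) | set(scores_b["cell_line"])
    if len(cl) > 1:
        raise ValueError(f"cannot merge libraries across cell lines: {sorted(cl)}")
    merged = pd.concat([scores_a, scores_b], ignore_index=True)
    merged["library"] = "both"
    return merged


def gene_med_cs(
    scores: pd.DataFrame,
    manifest: LibraryManifest,
    min_guides: int = DEFAULT_MIN_GUIDES,
) -> pd.DataFrame:
    """Collapse guide CS to gene med.CS (sample median of surviving guides).

    Even guide counts take the mean of the two central order statistics.
    Genes with fewer than ``min_guides`` surviving guides get
    status='insufficient_guides' and no med_cs; nontargeting guides never
    contribute. Returns one row per manifest gene.
    """
    targ = manifest.targeting
    totals = targ.groupby("gene")["sgrna_id"].size()
    surv = scores[scores["gene"].notna()]
    med = surv.groupby("gene")["cs"].median()
    used = surv.groupby("gene")["cs"].size()
    genes = sorted(manifest.genes)
    n_used = used.reindex(genes).fillna(0).astype(int)
    scored = n_used >= min_guides
    out = pd.DataFrame(
        {
            "gene": genes,
            "med_cs": np.where(scored.to_numpy(), med.reindex(genes).to_numpy(), np.nan),
            "n_guides_used": n_used.to_numpy(),
            "n_guides_total": totals.reindex(genes).fillna(0).astype(int).to_numpy(),
            "status": np.where(scored, "scored", "insufficient_guides"),
        }
    )
    n_insuff = int((~scored).sum())
    if n_insuff:
        logger.info(
            "gene_med_cs: %d genes with < %d surviving guides (unscored)",
            n_insuff,
            min_guides,
        )
    return out


def score_screen(
    counts: CountTable,
    manifest: LibraryManifest,
    pd0_threshold: int = DEFAULT_PD0_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_guides: int = DEFAULT_MIN_GUIDES,
) -> dict:
    """Run the full scoring pipeline on a multi-unit count table.

    Per replicate unit: PD0 filter then CS; replicates averaged at guide
    level per (cell_line, library); half-libraries merged per cell line;
    med.CS per gene on the merged guide set. Returns a dict with
    'sgrna_scores' (per cell line, merged), 'library_sgrna_scores'
    (per cell line and library), 'gene_scores' and 'library_gene_scores'
    (same keying, gene level).
    """
    per_unit: dict[tuple, list[pd.DataFrame]] = {}
    for (cl, lib, rep), pd0_id, pd14_id in iter_units(counts):
        sub = counts.select_samples([pd0_id, pd14_id])
        filtered = filter_low_pd0(sub, manifest, pd0_threshold)
        per_unit.setdefault((cl, lib), []).append(
            compute_cs(filtered, manifest, pseudocount)
        )
    library_sgrna = {key: aggregate_replicates(reps) for key, reps in per_unit.items()}
    cell_lines = sorted({cl for cl, _ in library_sgrna})
    sgrna_scores: dict[str, pd.DataFrame] = {}
    for cl in cell_lines:
        libs = [t for (c, _), t in sorted(library_sgrna.items()) if c == cl]
        merged = libs[0]
        for t in libs[1:]:
            merged = merge_libraries(merged, t)
        sgrna_scores[cl] = merged
    return {
        "sgrna_scores": sgrna_scores,
        "library_sgrna_scores": library_sgrna,
        "gene_scores": {
            cl: gene_med_cs(t, manifest, min_guides) for cl, t in sgrna_scores.items()
        },
        "library_gene_scores": {
            key: gene_med_cs(t, manifest, min_guides)
            for key, t in library_sgrna.items()
        },
    }
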