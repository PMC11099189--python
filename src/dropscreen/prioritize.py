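"""The hit funnel: rank, top-N dropout, common-essential removal,
druggable-genome annotation, cross-indication selectivity, overlaps and
Fisher enrichment.

A ranked list orders genes by med.CS from most negative (rank 1, the
strongest dropout) to most positive. Candidate prioritization removes
genes already known to be essential in most cell lines, keeps genes that
are targets of existing drugs ("drugged") or in families predicted
tractable ("druggable"), and calls a gene a selective dependency when it
is strongly depleted in every screen of the indication of interest while
staying neutral in every comparator screen.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_TAU_DEP = -1.0
DEFAULT_TAU_NEUTRAL = -0.3


def rank_genes(gene_scores: pd.DataFrame) -> pd.DataFrame:
    """Rank scored genes by med.CS ascending (rank 1 = most negative).

    Ties break lexicographically by gene symbol; genes with
    status='insufficient_guides' are excluded and logged.
    """
    scored = gene_scores[gene_scores["status"] == "scored"]
    if len(scored) == 0:
        raise ValueError("no scored genes to rank")
    dropped = len(gene_scores) - len(scored)
    if dropped:
        logger.info("rank_genes: excluded %d unscored genes", dropped)
    ranked = scored.sort_values(["med_cs", "gene"], kind="mergesort").reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked


def top_dropout(ranked: pd.DataFrame, n: int) -> set[str]:
    """First n genes of a ranked list (the top-N dropout set)."""
    if n > len(ranked):
        raise ValueError(f"requested top {n} of a {len(ranked)}-gene ranking")
    return set(ranked["gene"].iloc[:n])


def drop_common_essentials(
    candidates: set[str] | pd.DataFrame, essential_refs: GeneSetCollection
) -> set[str] | pd.DataFrame:
    """Remove genes in the union of essential_reference sets.

    Accepts a gene set or a ranked table; returns the same type. The
    removal count is logged; removing everything leaves an empty result
    with a warning.
    """
    essentials = essential_refs.union_of_role("essential_reference")
    if isinstance(candidates, pd.DataFrame):
        keep = ~candidates["gene"].isin(essentials)
        logger.info("drop_common_essentials: removed %d genes", int((~keep).sum()))
        out = candidates[keep].reset_index(drop=True)
        if len(out) == 0:
            logger.warning("drop_common_essentials: all candidates were essential")
        return out
    out_set = set(candidates) - essentials
    logger.info("drop_common_essentials: removed %d genes", len(candidates) - len(out_set))
    if not out_set and candidates:
        logger.warning("drop_common_essentials: all candidates were essential")
    return out_set


def annotate_druggable(
    candidates: Iterable[str], drug_refs: GeneSetCollection
) -> pd.DataFrame:
    """Flag each candidate as drugged and/or druggable from reference sets."""
    drugged = drug_refs.union_of_role("drugged")
    druggable = drug_refs.union_of_role("druggable")
    genes = sorted(set(candidates))
    return pd.DataFrame(
        {
            "gene": genes,
            "drugged": [g in drugged for g in genes],
            "druggable": [g in druggable for g in genes],
        }
    )


def cross_screen_selectivity(
    own: Mapping[str, pd.DataFrame],
    comparators: Mapping[str, pd.DataFrame],
    tau_dep: float = DEFAULT_TAU_DEP,
    tau_neutral: float = DEFAULT_TAU_NEUTRAL,
) -> pd.DataFrame:
    """Selective dependencies: depleted in every own screen, neutral in
    every comparator.

    A gene is selective iff med.CS <= tau_dep in every own screen AND it
    is scored with med.CS >= tau_neutral in every comparator screen; a
    gene unscored in some comparator is flagged (comparator_unscored) and
    never selected. Returns one row per gene scored in all own screens,
    with per-screen med.CS columns.
    """
    if tau_dep >= tau_neutral:
        raise ValueError(f"tau_dep ({tau_dep}) must be < tau_neutral ({tau_neutral})")
    if not own or not comparators:
        raise ValueError("need at least one own and one comparator screen")

    def scored_map(t: pd.DataFrame) -> pd.Series:
        return t[t["status"] == "scored"].set_index("gene")["med_cs"]

    own_s = {name: scored_map(t) for name, t in own.items()}
    comp_s = {name: scored_map(t) for name, t in comparators.items()}
    genes = sorted(set.intersection(*(set(s.index) for s in own_s.values())))
    out = pd.DataFrame({"gene": genes})
    for name, s in {**own_s, **comp_s}.items():
        out[f"med_cs_{name}"] = s.reindex(genes).to_numpy()
    dep = np.all([own_s[n].reindex(genes) <= tau_dep for n in own_s], axis=0)
    comp_vals = np.array([comp_s[n].reindex(genes).to_numpy() for n in comp_s])
    unscored = np.isnan(comp_vals).any(axis=0)
    neutral = np.all(np.nan_to_num(comp_vals, nan=-np.inf) >= tau_neutral, axis=0)
    out["depleted_own"] = dep
    out["comparator_unscored"] = unscored
    out["selective"] = dep & neutral & ~unscored
    return out


def set_overlap(sets: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], int]:
    """Exact cardinality of every Venn region of 2-3 named sets.

    Keys are tuples of the set names a region belongs to (exclusively);
    e.g. for sets X, Y the key ('X', 'Y') counts elements in both.
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("set_overlap handles 2 or 3 sets")
    frozen = {n: set(sets[n]) for n in names}
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            region = set.intersection(*(frozen[n] for n in inside))
            for n in names:
                if n not in inside:
                    region -= frozen[n]
            out[inside] = len(region)
    return out


def enrich_fisher(
    selection: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of a selection against gene sets.

    For each set: the 2x2 table is (k, n-k, K-k, N-n-K+k) with N the
    universe size, n the selection size, K the set size within the
    universe and k the overlap; p = P(X >= k) under the hypergeometric
    null, with Benjamini-Hochberg FDR across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selection = set(selection)
    if not selection <= universe:
        raise ValueError("selection must be a subset of the universe")
    N, n = len(universe), len(selection)
    rows = []
    for name, members in sets.sets.items():
        K = len(members & universe)
        k = len(members & selection)
        a, b, c, d = k, n - k, K - k, N - n - K + k
        if b * c == 0:
            odds = np.inf if a * d > 0 else np.nan
        else:
            odds = (a * d) / (b * c)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set": name,
                "k": k,
                "set_size": K,
                "selection_size": n,
                "universe_size": N,
                "odds_ratio": odds,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def prioritization_funnel(
    own: Mapping[str, pd.DataFrame],
    comparators: Mapping[str, pd.DataFrame],
    essential_refs: GeneSetCollection | None = None,
    drug_refs: GeneSetCollection | None = None,
    tau_dep: float = DEFAULT_TAU_DEP,
    tau_neutral: float = DEFAULT_TAU_NEUTRAL,
) -> pd.DataFrame:
    """Full candidate funnel: selectivity calls, then common-essential
    removal, then druggable-genome annotation.

    Returns the CandidateTable with per-screen med.CS, selectivity,
    is_common_essential and drugged/druggable flags; rows for common
    essentials are retained but can never be selective.
    """
    table = cross_screen_selectivity(own, comparators, tau_dep, tau_neutral)
    if essential_refs is not None:
        essentials = essential_refs.union_of_role("essential_reference")
        table["is_common_essential"] = table["gene"].isin(essentials)
        n_removed = int((table["is_common_essential"] & table["selective"]).sum())
        if n_removed:
            logger.info(
                "funnel: %d selective calls removed as common-essential", n_removed
            )
        table["selective"] = table["selective"] & ~table["is_common_essential"]
    else:
        table["is_common_essential"] = False
    if drug_refs is not None:
        flags = annotate_druggable(table["gene"], drug_refs)
        table = table.merge(flags, on="gene", how="left")
    else:
        table["drugged"] = False
        table["druggable"] = False
    return table
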