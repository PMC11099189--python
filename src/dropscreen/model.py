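"""Model/results interface over the screen-scoring pipeline.

``CrisprScreen`` holds a count table, a library manifest and the scoring
parameters; ``fit()`` runs the full pipeline (PD0 filter, CS, replicate
averaging, A/B merge, gene med.CS) and returns a ``ScreenResults`` that
carries the score tables and exposes QC, ranking and prioritization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import qc as _qc
from . import prioritize as _prio
from .io import CountTable, GeneSetCollection, LibraryManifest, write_results
from .scoring import (
    DEFAULT_MIN_GUIDES,
    DEFAULT_PD0_THRESHOLD,
    DEFAULT_PSEUDOCOUNT,
    score_screen,
)


class CrisprScreen:
    """A pooled dropout screen ready for scoring.

    Parameters
    ----------
    counts : CountTable
        sgRNA x sample read counts (PD0 and PD14 per replicate unit).
    manifest : LibraryManifest
        Guide-to-gene map with nontargeting controls.
    pd0_threshold : int
        Guides with fewer PD0 reads than this are removed per unit.
    pseudocount : float
        Added to every raw count before the proportion normalization.
    min_guides : int
        Minimum surviving guides for a gene to receive a med.CS.
    """

    def __init__(
        self,
        counts: CountTable,
        manifest: LibraryManifest,
        pd0_threshold: int = DEFAULT_PD0_THRESHOLD,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        min_guides: int = DEFAULT_MIN_GUIDES,
    ):
        self.counts = counts
        self.manifest = manifest
        self.pd0_threshold = pd0_threshold
        self.pseudocount = pseudocount
        self.min_guides = min_guides

    @classmethod
    def from_files(
        cls,
        counts_path: str | Path,
        samples_path: str | Path,
        manifest_path: str | Path,
        **kwargs,
    ) -> "CrisprScreen":
        from .io import read_counts, read_manifest, read_sample_table

        manifest = read_manifest(manifest_path)
        counts = read_counts(counts_path, manifest, read_sample_table(samples_path))
        return cls(counts, manifest, **kwargs)

    def fit(self) -> "ScreenResults":
        tables = score_screen(
            self.counts,
            self.manifest,
            pd0_threshold=self.pd0_threshold,
            pseudocount=self.pseudocount,
            min_guides=self.min_guides,
        )
        return ScreenResults(model=self, **tables)


@dataclass
class ScreenResults:
    """Fitted screen scores: guide CS and gene med.CS per cell line.

    ``gene_scores``/``sgrna_scores`` key on cell line (A/B merged);
    ``library_gene_scores``/``library_sgrna_scores`` key on
    (cell_line, library) before the merge, for concordance QC.
    """

    model: CrisprScreen
    sgrna_scores: Mapping[str, pd.DataFrame]
    library_sgrna_scores: Mapping[tuple, pd.DataFrame]
    gene_scores: Mapping[str, pd.DataFrame]
    library_gene_scores: Mapping[tuple, pd.DataFrame] = field(default_factory=dict)

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.gene_scores)

    # -- QC ---------------------------------------------------------------
    def library_concordance(self, cell_line: str) -> _qc.CorrelationReport:
        """Pearson r of gene med.CS between half-libraries A and B."""
        a = self.library_gene_scores.get((cell_line, "A"))
        b = self.library_gene_scores.get((cell_line, "B"))
        if a is None or b is None:
            raise ValueError(f"cell line {cell_line!r} lacks both half-libraries")
        return _qc.correlate_gene_scores(
            a, b, labels=(f"{cell_line}:A", f"{cell_line}:B")
        )

    def cell_line_concordance(self, cl1: str, cl2: str) -> _qc.CorrelationReport:
        return _qc.correlate_gene_scores(
            self.gene_scores[cl1], self.gene_scores[cl2], labels=(cl1, cl2)
        )

    def reference_separation(
        self, refs: GeneSetCollection, cell_line: str | None = None
    ) -> _qc.SeparationReport:
        cl = cell_line or self.cell_lines[0]
        return _qc.reference_separation(self.gene_scores[cl], refs)

    # -- Prioritization ----------------------------------------------------
    def rank_genes(self, cell_line: str | None = None) -> pd.DataFrame:
        cl = cell_line or self.cell_lines[0]
        return _prio.rank_genes(self.gene_scores[cl])

    def top_dropout(self, n: int, cell_line: str | None = None) -> set[str]:
        return _prio.top_dropout(self.rank_genes(cell_line), n)

    def prioritize(
        self,
        comparators: Mapping[str, pd.DataFrame],
        essential_refs: GeneSetCollection | None = None,
        drug_refs: GeneSetCollection | None = None,
        tau_dep: float = _prio.DEFAULT_TAU_DEP,
        tau_neutral: float = _prio.DEFAULT_TAU_NEUTRAL,
    ) -> pd.DataFrame:
        """Run the candidate funnel with this screen's cell lines as 'own'."""
        return _prio.prioritization_funnel(
            self.gene_scores,
            comparators,
            essential_refs=essential_refs,
            drug_refs=drug_refs,
            tau_dep=tau_dep,
            tau_neutral=tau_neutral,
        )

    # -- Reporting ---------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Dropout screen scoring (CRISPR score / med.CS)",
            "=" * 54,
            f"{'guides in manifest':<28}{len(m.manifest.entries):>10d}",
            f"{'nontargeting controls':<28}{len(m.manifest.nontargeting_ids):>10d}",
            f"{'PD0 filter threshold':<28}{m.pd0_threshold:>10d}",
            f"{'pseudocount':<28}{m.pseudocount:>10.3g}",
            f"{'min guides per gene':<28}{m.min_guides:>10d}",
            "-" * 54,
        ]
        for cl in self.cell_lines:
            g = self.gene_scores[cl]
            scored = g[g["status"] == "scored"]
            lines.append(
                f"{cl:<14}{len(scored):>7d} genes scored   "
                f"median med.CS {scored['med_cs'].median():>8.3f}"
            )
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cl in self.cell_lines:
            write_results(self.sgrna_scores[cl], outdir / f"sgrna_scores_{cl}.tsv")
            write_results(self.gene_scores[cl], outdir / f"gene_scores_{cl}.tsv")

    def plot_rank(self, cell_line: str | None = None, highlight=(), ax=None):
        """Rank-ordered med.CS curve (waterfall), optional gene highlights."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ranked = self.rank_genes(cell_line)
        ax.plot(ranked["rank"], ranked["med_cs"], lw=1)
        for gene in highlight:
            row = ranked[ranked["gene"] == gene]
            if len(row):
                ax.scatter(row["rank"], row["med_cs"], color="red", zorder=3)
                ax.annotate(gene, (row["rank"].iloc[0], row["med_cs"].iloc[0]))
        ax.set_xlabel("gene rank (most depleted first)")
        ax.set_ylabel("med.CS")
        return ax
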