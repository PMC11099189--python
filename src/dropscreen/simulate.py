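"""Synthetic GeCKOv2-like dropout screens with known ground truth.

The generator emulates a genome-scale knockout library (6 guides per gene
split 3+3 across half-libraries A and B, plus nontargeting controls) taken
through a negative-selection screen: a baseline sample after selection
(PD0) and a sample after 14 population doublings (PD14), sequenced at a
fixed fold-coverage.

Growth model
------------
Each guide i starts at abundance a_i ~ LogNormal(0, baseline_spread). A
targeting guide against gene g with per-doubling fitness effect s_g <= 0
and cutting efficacy e_i in [0, 1] grows to expected relative abundance

    w_i = a_i * 2**(D * (1 + s_g * e_i)),

normalized over the guides in its half-library; nontargeting guides and
guides against neutral genes have s = 0, so neutral guides are exactly
invariant in proportion and the expected guide-level log2 fold-change of
an essential guide relative to neutral guides is D * s_g * e_i in closed
form. Read counts are negative binomial around the expected proportions
(variance mu + phi * mu**2; phi = 0 is Poisson), drawn independently per
replicate and timepoint.

MOI is recorded for bookkeeping only; multiple-integration, copy-number
and off-target effects are not modeled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CountTable, LibraryManifest

FULL_SCALE_GUIDES = 123_411  # printed guide total of the GeCKOv2 library


def cells_for_coverage(n_guides: int, coverage: float) -> float:
    """Cells needed to hold ``coverage``-fold representation of the library."""
    return float(coverage) * float(n_guides)


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; the defaults are the study conditions.

    ``n_genes`` defaults to the desk-scale configuration (2000 genes);
    library geometry (6 guides/gene, 1000 nontargeting controls), the
    screen protocol (14 doublings, 300x coverage, MOI ~0.3) and the noise
    family follow the screening protocol being emulated.
    """

    seed: int
    n_genes: int = 2000
    sgrnas_per_gene: int = 6
    n_nontargeting: int = 1000
    doublings: int = 14
    coverage: float = 300.0
    moi: float = 0.3  # bookkeeping only; infection is not modeled
    frac_essential: float = 0.05
    effect_low: float = -0.35   # s_g ~ Uniform(effect_low, effect_high)
    effect_high: float = -0.15
    efficacy_a: float = 5.0     # e_i ~ Beta(efficacy_a, efficacy_b)
    efficacy_b: float = 1.5
    baseline_spread: float = 0.5  # log-normal sigma of initial abundances
    nb_dispersion: float = 0.05   # phi in var = mu + phi mu^2; 0 = Poisson
    reads_per_sample: int | None = None  # default: coverage * n_guides

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required for any stochastic call")
        for name in ("n_genes", "sgrnas_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_nontargeting < 0 or self.doublings < 0:
            raise ValueError("n_nontargeting and doublings must be >= 0")
        if not 0.0 <= self.frac_essential <= 1.0:
            raise ValueError("frac_essential must be in [0, 1]")
        if self.effect_low > self.effect_high:
            raise ValueError("effect_low must be <= effect_high")
        if self.effect_high > 0:
            raise ValueError(
                "fitness effects must satisfy s_g <= 0 (dropout-only model)"
            )
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.sgrnas_per_gene + self.n_nontargeting

    def resolved_reads(self) -> int:
        """Reads per sample; defaults to coverage x library size."""
        if self.reads_per_sample is not None:
            return int(self.reads_per_sample)
        return int(round(cells_for_coverage(self.n_guides, self.coverage)))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated screen, keyed like the manifest.

    Covers every targeting gene and guide; nontargeting guides are absent.
    """

    gene_effects: dict[str, float]
    guide_efficacies: dict[str, float]
    essential_labels: dict[str, bool] = field(default_factory=dict)

    def expected_gene_lfc(self, doublings: int) -> pd.Series:
        """Closed-form expected guide-average log2 fold-change per gene,
        D * s_g * mean(e_i), the quantity med.CS estimates."""
        eff = pd.Series(self.guide_efficacies)
        gene = eff.index.str.rsplit("_sg", n=1).str[0]
        mean_eff = eff.groupby(gene).mean()
        s = pd.Series(self.gene_effects)
        return doublings * s * mean_eff.reindex(s.index)


def make_manifest(params: SimParams) -> LibraryManifest:
    """Deterministic library manifest: ``GENE####_sgK`` guides alternating
    A/B within each gene (3+3 at the default multiplicity of 6) and
    ``NT_K`` nontargeting controls split evenly between half-libraries."""
    genes = [f"GENE{i + 1:05d}" for i in range(params.n_genes)]
    rows: list[tuple[str, str | None, str, str]] = []
    for gi, g in enumerate(genes):
        # alternate A/B within each gene, with a per-gene phase so that odd
        # multiplicities still balance across the whole library
        offset = gi * params.sgrnas_per_gene
        for k in range(params.sgrnas_per_gene):
            sub = "A" if (offset + k) % 2 == 0 else "B"
            rows.append((f"{g}_sg{k + 1}", g, "targeting", sub))
    for k in range(params.n_nontargeting):
        sub = "A" if k % 2 == 0 else "B"
        rows.append((f"NT_{k + 1}", None, "nontargeting", sub))
    entries = pd.DataFrame(rows, columns=["sgrna_id", "gene", "category", "sublibrary"])
    return LibraryManifest(entries)


def _rng_for(params: SimParams, cell_line: str) -> np.random.Generator:
    # independent, reproducible stream per cell line; crc32 < 2**32
    return np.random.default_rng([params.seed, zlib.crc32(cell_line.encode())])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.clip(mean, 1e-12, None)
    if phi == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return rng.poisson(lam)


def simulate_screen(
    manifest: LibraryManifest,
    params: SimParams,
    cell_line: str = "SIM1",
    n_replicates: int = 2,
    essential_genes: Iterable[str] | None = None,
) -> tuple[CountTable, SimTruth]:
    """Simulate PD0/PD14 counts for one cell line across both half-libraries.

    Each half-library is an independently transduced population: a sample
    only carries reads for its own guides (off-library rows are zero).
    Essential genes are either supplied explicitly or drawn as a fraction
    ``frac_essential`` of the manifest's genes; their per-doubling fitness
    effects come from the configured uniform distribution and per-guide
    efficacies from the configured beta. Returns the count table (one
    sample per library x replicate x timepoint) and the ground truth.
    """
    if len(manifest.entries) == 0:
        raise ValueError("manifest is empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = _rng_for(params, cell_line)

    genes = sorted(manifest.genes)
    targ = manifest.targeting
    if essential_genes is None:
        n_ess = int(round(params.frac_essential * len(genes)))
        essential = set(rng.choice(genes, size=n_ess, replace=False)) if n_ess else set()
    else:
        essential = set(essential_genes)
        unknown = essential - set(genes)
        if unknown:
            raise ValueError(f"essential_genes not in manifest: {sorted(unknown)[:5]}")

    s_g = {g: 0.0 for g in genes}
    for g in sorted(essential):
        s_g[g] = float(rng.uniform(params.effect_low, params.effect_high))
    eff = {
        sg: float(e)
        for sg, e in zip(
            targ["sgrna_id"], rng.beta(params.efficacy_a, params.efficacy_b, len(targ))
        )
    }
    truth = SimTruth(
        gene_effects=s_g,
        guide_efficacies=eff,
        essential_labels={g: g in essential for g in genes},
    )

    all_ids = manifest.sgrna_ids
    gene_of = manifest.gene_of()
    a = rng.lognormal(mean=0.0, sigma=params.baseline_spread, size=len(all_ids))
    a = pd.Series(a, index=all_ids)
    # per-guide growth exponent D*(1 + s_g*e_i); s=0 for NT and neutral genes
    s_per_guide = gene_of.reindex(all_ids).map(s_g).fillna(0.0).to_numpy(dtype=float)
    e_per_guide = pd.Series(eff).reindex(all_ids).fillna(0.0).to_numpy(dtype=float)
    se = s_per_guide * e_per_guide
    growth = np.exp2(params.doublings * (1.0 + se))

    reads = params.resolved_reads()
    phi = params.nb_dispersion
    cols: dict[str, np.ndarray] = {}
    meta: list[tuple[str, str, str, int, str]] = []
    for lib in ("A", "B"):
        in_lib = manifest.entries["sublibrary"].isin([lib, "both"]).to_numpy()
        if not in_lib.any():
            continue
        a_lib = a.to_numpy() * in_lib
        p0 = a_lib / a_lib.sum()
        w = a_lib * growth
        p14 = w / w.sum()
        for rep in range(1, n_replicates + 1):
            for tp, p in (("PD0", p0), ("PD14", p14)):
                sid = f"{cell_line}_{lib}_R{rep}_{tp}"
                cols[sid] = _nb_draw(rng, reads * p, phi)
                meta.append((sid, tp, cell_line, rep, lib))
    counts = pd.DataFrame(cols, index=all_ids).astype(np.int64)
    samples = pd.DataFrame(
        meta, columns=["sample_id", "timepoint", "cell_line", "replicate", "library"]
    )
    return CountTable(counts, samples), truth


def truth_table(truth: SimTruth) -> pd.DataFrame:
    """Flatten a SimTruth into a per-gene TSV-ready table."""
    rows = [
        {
            "gene": g,
            "fitness_effect": truth.gene_effects[g],
            "essential": truth.essential_labels.get(g, False),
        }
        for g in sorted(truth.gene_effects)
    ]
    return pd.DataFrame(rows)
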