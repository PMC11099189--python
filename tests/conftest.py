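import numpy as np
import pandas as pd
import pytest

import dropscreen as ds
from dropscreen.io import CountTable, LibraryManifest


@pytest.fixture
def toy_manifest() -> LibraryManifest:
    """Three guides: two targeting (GENEA, GENEB) and one nontargeting."""
    return LibraryManifest(
        pd.DataFrame(
            {
                "sgrna_id": ["GENEA_sg1", "GENEB_sg1", "NT_1"],
                "gene": ["GENEA", "GENEB", None],
                "category": ["targeting", "targeting", "nontargeting"],
                "sublibrary": ["A", "B", "both"],
            }
        )
    )


def make_unit_counts(
    counts: dict[str, tuple[int, int]],
    cell_line: str = "CL",
    library: str = "both",
    replicate: int = 1,
) -> CountTable:
    """Single analysis-unit count table from {sgrna_id: (pd0, pd14)}."""
    ids = list(counts)
    pd0 = [counts[i][0] for i in ids]
    pd14 = [counts[i][1] for i in ids]
    s0 = f"{cell_line}_{library}_R{replicate}_PD0"
    s14 = f"{cell_line}_{library}_R{replicate}_PD14"
    frame = pd.DataFrame({s0: pd0, s14: pd14}, index=pd.Index(ids, name="sgrna_id"))
    samples = pd.DataFrame(
        {
            "sample_id": [s0, s14],
            "timepoint": ["PD0", "PD14"],
            "cell_line": cell_line,
            "replicate": replicate,
            "library": library,
        }
    )
    return CountTable(frame, samples)


def gene_score_frame(med_cs: dict[str, float]) -> pd.DataFrame:
    """Minimal scored gene table from {gene: med_cs}."""
    genes = sorted(med_cs)
    return pd.DataFrame(
        {
            "gene": genes,
            "med_cs": [med_cs[g] for g in genes],
            "n_guides_used": 6,
            "n_guides_total": 6,
            "status": "scored",
        }
    )


@pytest.fixture(scope="session")
def default_sim():
    """Default scaled-down screen simulation, scored end to end.

    Returns (params, manifest, counts, truth, ScreenResults); shared
    session-wide because the full pipeline is the expensive part.
    """
    params = ds.SimParams(seed=7)
    manifest = ds.make_manifest(params)
    counts, truth = ds.simulate_screen(
        manifest, params, cell_line="PDX1", n_replicates=2
    )
    results = ds.CrisprScreen(counts, manifest).fit()
    return params, manifest, counts, truth, results
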