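"""Plain-text I/O for pooled-screen artifacts.

Library manifests, count tables and ranked result tables travel as
tab-separated text with a header row; gene set collections use the GMT
dialect (set name, description, then tab-separated members). Sample
metadata for a count table is supplied separately (a TSV sidecar or a
DataFrame), never inferred from sample names.

Nothing here is ever silently dropped: every zero-filled or discarded
record is counted and logged with a reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("targeting", "nontargeting")
SUBLIBRARIES = ("A", "B", "both")
TIMEPOINTS = ("PD0", "PD14")
GENE_SET_ROLES = (
    "essential_reference",
    "nonessential_reference",
    "drugged",
    "druggable",
    "pathway",
)


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase.

    No alias resolution is attempted.
    """
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# LibraryManifest


@dataclass(frozen=True)
class LibraryManifest:
    """sgRNA -> gene map with nontargeting controls and A/B sublibrary labels.

    ``entries`` has columns ``sgrna_id``, ``gene`` (None for nontargeting
    guides), ``category`` (targeting/nontargeting) and ``sublibrary``
    (A/B/both). This is the guide universe for every gene-level collapse.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries
        required = ["sgrna_id", "gene", "category", "sublibrary"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        dup = df["sgrna_id"][df["sgrna_id"].duplicated()]
        if len(dup):
            raise ValueError(
                f"duplicate sgrna_id in manifest: {sorted(set(dup))[:10]}"
            )
        bad_cat = set(df["category"]) - set(CATEGORIES)
        if bad_cat:
            raise ValueError(f"unknown category values: {sorted(bad_cat)}")
        bad_sub = set(df["sublibrary"]) - set(SUBLIBRARIES)
        if bad_sub:
            raise ValueError(f"unknown sublibrary values: {sorted(bad_sub)}")
        nt = df["category"] == "nontargeting"
        if df.loc[nt, "gene"].notna().any():
            offenders = df.loc[nt & df["gene"].notna(), "sgrna_id"]
            raise ValueError(
                f"nontargeting guides with a gene symbol: {list(offenders)[:10]}"
            )
        targeting_empty = ~nt & (df["gene"].isna() | (df["gene"].astype(str).str.strip() == ""))
        if targeting_empty.any():
            offenders = df.loc[targeting_empty, "sgrna_id"]
            raise ValueError(
                f"targeting guides without a gene symbol: {list(offenders)[:10]}"
            )

    @property
    def sgrna_ids(self) -> pd.Index:
        return pd.Index(self.entries["sgrna_id"])

    @property
    def targeting(self) -> pd.DataFrame:
        return self.entries[self.entries["category"] == "targeting"]

    @property
    def nontargeting_ids(self) -> set[str]:
        nt = self.entries["category"] == "nontargeting"
        return set(self.entries.loc[nt, "sgrna_id"])

    @property
    def genes(self) -> set[str]:
        return set(self.targeting["gene"])

    def gene_of(self) -> pd.Series:
        """Series mapping sgrna_id -> gene symbol (NaN for nontargeting)."""
        return self.entries.set_index("sgrna_id")["gene"]

    def subset(self, sgrna_ids: Iterable[str]) -> "LibraryManifest":
        keep = self.entries["sgrna_id"].isin(set(sgrna_ids))
        return LibraryManifest(self.entries[keep].reset_index(drop=True))


def read_manifest(path: str | Path) -> LibraryManifest:
    """Read a library manifest TSV.

    The header must name sgrna, gene, category and sublibrary columns
    (``sgrna`` or ``sgrna_id`` both accepted). Gene symbols are normalized
    (uppercased, trimmed); an empty gene field on a nontargeting row is
    read as null.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.rename(columns={"sgrna": "sgrna_id"})
    if "sgrna_id" not in df.columns:
        raise ValueError(f"{path}: no 'sgrna' or 'sgrna_id' column in header")
    gene = df.get("gene", pd.Series("", index=df.index)).map(
        lambda g: normalize_symbol(g) if str(g).strip() else None
    )
    out = pd.DataFrame(
        {
            "sgrna_id": df["sgrna_id"].str.strip(),
            "gene": gene,
            "category": df["category"].str.strip().str.lower(),
            "sublibrary": df["sublibrary"].str.strip(),
        }
    )
    return LibraryManifest(out)


def write_manifest(manifest: LibraryManifest, path: str | Path) -> None:
    df = manifest.entries.copy()
    df["gene"] = df["gene"].fillna("")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CountTable


@dataclass(frozen=True)
class CountTable:
    """Integer sgRNA x sample read counts plus per-sample metadata.

    ``counts`` is indexed by sgrna_id with one column per sample_id;
    ``samples`` holds (sample_id, timepoint, cell_line, replicate, library).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["sample_id", "timepoint", "cell_line", "replicate", "library"]
        missing = [c for c in req if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        bad_tp = set(self.samples["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
        meta_ids = list(self.samples["sample_id"])
        if sorted(meta_ids) != sorted(self.counts.columns):
            raise ValueError("sample metadata ids do not match count columns")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise ValueError("counts must be integers")
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        # every (cell_line, library) unit needs both timepoints
        for (cl, lib), grp in self.samples.groupby(["cell_line", "library"]):
            tps = set(grp["timepoint"])
            if not {"PD0", "PD14"} <= tps:
                raise ValueError(
                    f"analysis unit ({cl}, {lib}) lacks a PD0 or PD14 sample"
                )

    @property
    def sgrna_ids(self) -> pd.Index:
        return self.counts.index

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = list(sample_ids)
        return CountTable(
            self.counts[ids],
            self.samples[self.samples["sample_id"].isin(ids)].reset_index(drop=True),
        )

    def select_guides(self, sgrna_ids: Iterable[str]) -> "CountTable":
        keep = self.counts.index.isin(set(sgrna_ids))
        return CountTable(self.counts[keep], self.samples)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata sidecar TSV for a count table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_line": str})
    df["replicate"] = df["replicate"].astype(int)
    return df


def read_counts(
    path: str | Path,
    manifest: LibraryManifest,
    samples: pd.DataFrame | str | Path,
) -> CountTable:
    """Read a count TSV (first column sgrna_id, one column per sample).

    Rows are restricted to manifest guides; guides in the manifest but
    absent from the file are zero-filled (absence of a pooled-library
    guide from sequencing is an observed dropout, not missing data) and
    the zero-fill is logged. Unknown sgrna_ids or negative/non-integer
    counts are hard errors naming the offenders.
    """
    if not isinstance(samples, pd.DataFrame):
        samples = read_sample_table(samples)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str).str.strip()
    unknown = raw.index.difference(manifest.sgrna_ids)
    if len(unknown):
        raise ValueError(
            f"{path}: sgrna_ids absent from the manifest: {sorted(unknown)[:10]}"
        )
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (np.mod(vals, 1) != 0)
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: invalid count at row {row!r}, column {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
    counts = raw.reindex(manifest.sgrna_ids)
    n_filled = int(counts.isna().any(axis=1).sum())
    if n_filled:
        logger.warning(
            "%s: %d manifest guides absent from count file; zero-filled "
            "(absence treated as observed dropout)",
            path,
            n_filled,
        )
    counts = counts.fillna(0).astype(np.int64)
    return CountTable(counts, samples.reset_index(drop=True))


def write_counts(table: CountTable, counts_path: str | Path, samples_path: str | Path) -> None:
    table.counts.rename_axis("sgrna_id").to_csv(counts_path, sep="\t")
    table.samples.to_csv(samples_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GeneSetCollection


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with a role per set (essential_reference, drugged, ...)."""

    sets: Mapping[str, frozenset[str]]
    roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, role in self.roles.items():
            if role not in GENE_SET_ROLES:
                raise ValueError(f"unknown role {role!r} for set {name!r}")

    def by_role(self, role: str) -> dict[str, frozenset[str]]:
        return {n: s for n, s in self.sets.items() if self.roles.get(n) == role}

    def union_of_role(self, role: str) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.by_role(role).values():
            out |= s
        return out

    def __len__(self) -> int:
        return len(self.sets)


def read_gene_sets(
    path: str | Path,
    role_map: Mapping[str, str] | None = None,
    default_role: str = "pathway",
) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, tab-separated members.

    Symbols are normalized; duplicate members collapse by set semantics.
    Empty sets are kept with a warning. ``role_map`` assigns a role per set
    name (others get ``default_role``).
    """
    role_map = dict(role_map or {})
    sets: dict[str, frozenset[str]] = {}
    roles: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: unreadable GMT line (need name and description)"
                )
            name = parts[0].strip()
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(
                normalize_symbol(m) for m in parts[2:] if m.strip()
            )
            if not members:
                logger.warning("%s:%d: gene set %r is empty; kept", path, lineno, name)
            sets[name] = members
            roles[name] = role_map.get(name, default_role)
    return GeneSetCollection(sets, roles)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            role = collection.roles.get(name, "pathway")
            fh.write("\t".join([name, role, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Result tables


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a score/candidate table as TSV with 6-significant-digit floats.

    Row order is preserved as given (callers emit deterministic order).
    An empty table is an error, never an empty file.
    """
    if table is None or len(table) == 0:
        raise ValueError(f"refusing to write an empty result table to {path}")
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
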