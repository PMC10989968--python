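"""OTU count tables and sample metadata: reading, validation, rarefaction, filtering.

The substrate of the pipeline is a samples x OTUs matrix of non-negative
integer read counts together with per-sample metadata assigning each sample
to an island with a known area.  This module owns all tabular I/O plus the
three standard pre-network transformations: rarefaction to a common depth,
prevalence filtering, and the log10(x+1) transform applied before
rank-correlation (cosmetic for Spearman, which is invariant to strictly
increasing maps, but fixed here for reproducibility).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

#: Columns that must be present in a metadata table.
REQUIRED_METADATA_COLUMNS = ("sample_id", "island_id", "area_m2")

#: Minimum number of samples an OTU must occur in to survive the default
#: prevalence filter.
DEFAULT_MIN_PREVALENCE = 12


@dataclass
class OtuTable:
    """Integer count matrix of samples x OTUs with identifier lists.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per matrix row.
    otu_ids : list of str
        Unique OTU identifiers, one per matrix column.
    counts : ndarray of shape (n_samples, n_otus)
        Non-negative integer read counts.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU identifiers")
        if counts.size:
            if not np.issubdtype(counts.dtype, np.number):
                raise ValueError("counts must be numeric")
            neg = np.argwhere(counts < 0)
            if neg.size:
                i, j = neg[0]
                raise ValueError(
                    f"negative count at sample {self.sample_ids[i]!r}, "
                    f"OTU {self.otu_ids[j]!r}"
                )
            frac = np.argwhere(counts != np.floor(counts))
            if frac.size:
                i, j = frac[0]
                raise ValueError(
                    f"non-integer count at sample {self.sample_ids[i]!r}, "
                    f"OTU {self.otu_ids[j]!r}"
                )
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def presence(self) -> np.ndarray:
        """Boolean samples x OTUs detection matrix."""
        return self.counts > 0

    def select_samples(self, keep: np.ndarray) -> "OtuTable":
        keep = np.asarray(keep)
        ids = [self.sample_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool \
            else [self.sample_ids[i] for i in keep]
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return OtuTable(ids, list(self.otu_ids), self.counts[idx])

    def select_otus(self, keep: np.ndarray) -> "OtuTable":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        ids = [self.otu_ids[i] for i in idx]
        return OtuTable(list(self.sample_ids), ids, self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by sample, columns OTUs."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


class SampleMetadata:
    """Per-sample island assignment, island area (m2), and soil covariates.

    Wraps a DataFrame with required columns ``sample_id``, ``island_id``,
    ``area_m2``; any further numeric columns (moisture, toc, tn, tp,
    available_ca, ...) ride along as covariates.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in REQUIRED_METADATA_COLUMNS:
            if col not in frame.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["island_id"] = frame["island_id"].astype(str)
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if (frame["area_m2"] <= 0).any():
            raise ValueError("island area must be > 0")
        per_island = frame.groupby("island_id")["area_m2"].nunique()
        bad = per_island[per_island > 1]
        if len(bad):
            raise ValueError(
                f"island {bad.index[0]!r} has inconsistent area values"
            )
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def island_of(self) -> pd.Series:
        """Map sample_id -> island_id."""
        return self.frame.set_index("sample_id")["island_id"]

    def islands(self) -> pd.DataFrame:
        """One row per island: island_id, area_m2, sorted by area."""
        isl = (
            self.frame.groupby("island_id", as_index=False)["area_m2"]
            .first()
            .sort_values("area_m2", kind="mergesort")
            .reset_index(drop=True)
        )
        return isl

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        keep = self.frame["sample_id"].isin(set(sample_ids))
        return SampleMetadata(self.frame[keep])

    def covariate_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("sample_id", "island_id")]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _comment_header(params: dict) -> str:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"## micronar v{__version__} {items}".rstrip()


def read_otu_table(path, format: str = "tsv", orientation: str = "auto") -> OtuTable:
    """Read an OTU table from TSV or dense BIOM-style JSON.

    TSV dialect: lines starting ``##`` are comments; the header row carries
    identifiers.  The dominant convention puts OTUs on rows (header cell
    ``#OTU ID`` or ``otu_id``); a header cell ``sample_id`` marks the
    transposed layout.  ``orientation`` may force ``"otus_as_rows"`` or
    ``"samples_as_rows"``; ``"auto"`` applies the header convention and falls
    back to OTUs-as-rows.
    """
    if format == "biom-dense":
        return _read_biom_dense(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'biom-dense'")

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("##")]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError("no samples: empty OTU table file")
    header = lines[0].split("\t")
    first_cell = header[0].lstrip("#").strip().lower().replace(" ", "_")
    if orientation == "auto":
        orientation = "samples_as_rows" if first_cell == "sample_id" else "otus_as_rows"
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")

    row_ids = []
    data = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        row_ids.append(parts[0])
        data.append(parts[1:])
    col_ids = header[1:]
    if not row_ids or not col_ids:
        raise ValueError("no samples: table has no data rows or columns")
    try:
        mat = np.array(data, dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric count in table: {exc}") from exc
    if orientation == "otus_as_rows":
        table = OtuTable(col_ids, row_ids, mat.T)
    else:
        table = OtuTable(row_ids, col_ids, mat)
    if table.n_samples == 0:
        raise ValueError("no samples")
    return table


def _read_biom_dense(path) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    rows = [r["id"] for r in doc["rows"]]       # observations = OTUs
    cols = [c["id"] for c in doc["columns"]]    # samples
    if not cols:
        raise ValueError("no samples")
    mat = np.array(doc["data"], dtype=float)
    if mat.shape != (len(rows), len(cols)):
        raise ValueError("BIOM data shape inconsistent with row/column lists")
    return OtuTable(cols, rows, mat.T)


def write_otu_table(table: OtuTable, path, format: str = "tsv",
                    orientation: str = "otus_as_rows") -> None:
    """Write a table in a form :func:`read_otu_table` reads back losslessly."""
    if format == "biom-dense":
        doc = {
            "id": None,
            "format": "micronar dense",
            "generated_by": f"micronar v{__version__}",
            "type": "OTU table",
            "matrix_type": "dense",
            "shape": [table.n_otus, table.n_samples],
            "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        fh.write(_comment_header({"orientation": orientation}) + "\n")
        if orientation == "otus_as_rows":
            fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\n")
            for j, otu in enumerate(table.otu_ids):
                fh.write(otu + "\t" + "\t".join(map(str, table.counts[:, j])) + "\n")
        else:
            fh.write("sample_id\t" + "\t".join(table.otu_ids) + "\n")
            for i, sam in enumerate(table.sample_ids):
                fh.write(sam + "\t" + "\t".join(map(str, table.counts[i])) + "\n")


def read_metadata(path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header({}) + "\n")
        meta.frame.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Rarefy every sample to ``depth`` reads without replacement.

    Samples whose total falls below ``depth`` are dropped with a warning.
    Each retained sample is subsampled by a multivariate hypergeometric draw
    (classic rarefaction), with a per-sample random stream derived from the
    master seed and the sample's position, so the result for one sample does
    not depend on which other samples are present.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, ", ".join(dropped),
        )
    if not keep.any():
        raise ValueError("no samples survive rarefaction")
    new_counts = np.zeros((int(keep.sum()), table.n_otus), dtype=np.int64)
    out_row = 0
    for i in range(table.n_samples):
        if not keep[i]:
            continue
        row = table.counts[i]
        if totals[i] == depth:
            new_counts[out_row] = row
        else:
            rng = np.random.default_rng([seed, i])
            new_counts[out_row] = rng.multivariate_hypergeometric(row, depth)
        out_row += 1
    sample_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return OtuTable(sample_ids, list(table.otu_ids), new_counts)


def prevalence_filter(table: OtuTable, min_samples: int = DEFAULT_MIN_PREVALENCE) -> OtuTable:
    """Keep OTUs detected (count > 0) in at least ``min_samples`` samples."""
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    prev = (table.counts > 0).sum(axis=0)
    keep = prev >= min_samples
    if not keep.any():
        logger.warning("prevalence_filter: no OTUs survive (min_samples=%d)", min_samples)
    return table.select_otus(keep)


def log_transform(table: OtuTable) -> np.ndarray:
    """Elementwise log10(count + 1); shape preserved (samples x OTUs)."""
    return np.log10(table.counts.astype(float) + 1.0)


def island_richness(table: OtuTable, meta: SampleMetadata) -> pd.Series:
    """Number of OTUs detected in at least one sample of each island."""
    island_of = meta.island_of()
    unknown = [s for s in table.sample_ids if s not in island_of.index]
    if unknown:
        raise ValueError(f"sample(s) with unknown island: {', '.join(unknown[:5])}")
    pres = table.presence()
    islands = island_of.loc[table.sample_ids].to_numpy()
    out = {}
    for isl in pd.unique(islands):
        rows = pres[islands == isl]
        out[isl] = int(rows.any(axis=0).sum())
    return pd.Series(out, name="richness").sort_index()
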