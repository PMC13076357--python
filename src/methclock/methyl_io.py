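"""Readers and writers for the on-disk formats of the pipeline.

The primary input format is the Bismark-style coverage file: a 6-column
tab-separated table (chromosome, start, end, methylation percentage,
methylated count, unmethylated count) with 1-based coordinates and
``start == end`` for single-cytosine records.  Sample metadata travel in a
TSV with one row per blood sample.  CpG-island intervals arrive as BED3 and
gene models as BED12; both are converted on read to the internal 1-based
inclusive convention that the coverage format dictates.

All readers transparently accept gzip-compressed files.
"""

from __future__ import annotations

import gzip
import io

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CpGSite",
    "SiteCounts",
    "MethylationDataset",
    "read_coverage_file",
    "write_coverage_file",
    "collapse_strands",
    "read_metadata",
    "assemble_dataset",
    "read_intervals",
    "save_dataset",
    "load_dataset",
]

COVERAGE_COLUMNS = ["chrom", "start", "end", "pct", "meth", "unmeth"]
METADATA_REQUIRED = ["sample_id", "individual_id", "sex", "age_years"]

# tolerance on the redundant percentage column of a coverage row
_PCT_TOL = 0.1


@dataclass(frozen=True)
class CpGSite:
    """A CpG dinucleotide, addressed by the plus-strand C (1-based)."""

    chrom: str
    pos: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"CpG position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class SiteCounts:
    """Methylated/total read counts at one CpG in one sample."""

    site: CpGSite
    methylated: int
    total: int

    def __post_init__(self):
        if not (0 <= self.methylated <= self.total):
            raise ValueError(
                f"need 0 <= methylated <= total, got {self.methylated}/{self.total}"
            )

    @property
    def ratio(self) -> float:
        """Methylation ratio, NaN when the site is unobserved (total = 0)."""
        return self.methylated / self.total if self.total > 0 else float("nan")


@dataclass
class MethylationDataset:
    """Sites x samples methylation counts with the sample metadata join.

    ``meth`` and ``total`` are dense integer matrices aligned to ``sites``
    (rows, ordered by chromosome then position) and ``samples`` (columns).
    A (site, sample) cell with ``total == 0`` is *missing*: the site was not
    observed in that sample.
    """

    sites: pd.DataFrame  # columns: chrom, pos
    samples: pd.DataFrame  # columns: sample_id, individual_id, sex, age_years, ...
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self):
        ns, nc = len(self.sites), len(self.samples)
        if self.meth.shape != (ns, nc) or self.total.shape != (ns, nc):
            raise ValueError("count matrices must be sites x samples")
        if np.any(self.meth > self.total) or np.any(self.meth < 0):
            raise ValueError("need 0 <= methylated <= total everywhere")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def ratios(self) -> np.ndarray:
        """Methylation ratios with NaN at missing (zero-total) cells."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.meth / self.total
        return np.where(self.total > 0, r, np.nan)

    @property
    def missing(self) -> np.ndarray:
        return self.total == 0

    def subset_sites(self, mask: np.ndarray) -> "MethylationDataset":
        return MethylationDataset(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=self.samples.copy(),
            meth=self.meth[mask],
            total=self.total[mask],
        )


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_coverage_file(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read one Bismark-style coverage file into a counts table.

    Returns a DataFrame with columns ``chrom, pos, meth, total`` where
    ``total = methylated + unmethylated``.  The redundant percentage column
    is not used for computation; it is checked against the counts and a
    warning is emitted when it disagrees by more than 0.1 percentage points.
    Rows with zero total coverage are retained (they mark missing data).

    Raises ``ValueError`` naming the offending line for malformed rows.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                chrom = parts[0]
                start = int(parts[1])
                end = int(parts[2])
                pct = float(parts[3])
                meth = int(parts[4])
                unmeth = int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if start < 1 or end < start:
                raise ValueError(
                    f"{path}: line {lineno}: bad coordinates {start}-{end}"
                )
            if meth < 0 or unmeth < 0:
                raise ValueError(
                    f"{path}: line {lineno}: negative counts"
                )
            total = meth + unmeth
            if total > 0 and abs(pct - 100.0 * meth / total) > _PCT_TOL:
                warnings.warn(
                    f"{path}: line {lineno}: percentage column {pct} disagrees "
                    f"with counts {meth}/{total}",
                    stacklevel=2,
                )
            rows.append((chrom, start, meth, total))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    df["chrom"] = df["chrom"].astype(str)
    if sample_id is not None:
        df.attrs["sample_id"] = sample_id
    return df


def write_coverage_file(counts: pd.DataFrame, path) -> None:
    """Write a counts table (chrom, pos, meth, total) as Bismark coverage."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for chrom, pos, meth, total in counts[
            ["chrom", "pos", "meth", "total"]
        ].itertuples(index=False):
            unmeth = total - meth
            pct = 100.0 * meth / total if total > 0 else 0.0
            fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:g}\t{meth}\t{unmeth}\n")


def collapse_strands(counts: pd.DataFrame) -> pd.DataFrame:
    """Merge symmetric CpG records reported on both strands.

    A CpG covers positions ``pos`` (plus-strand C) and ``pos + 1``
    (minus-strand C).  When both records exist the minus-strand counts are
    added to the plus-strand row.  Greedy left-to-right pairing; idempotent
    on already-collapsed input; total read counts are conserved.
    """
    out_chrom, out_pos, out_meth, out_total = [], [], [], []
    for chrom, grp in counts.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        meth = grp["meth"].to_numpy().copy()
        total = grp["total"].to_numpy().copy()
        consumed = np.zeros(len(pos), dtype=bool)
        by_pos = {p: i for i, p in enumerate(pos)}
        for i, p in enumerate(pos):
            if consumed[i]:
                continue
            j = by_pos.get(p + 1)
            if j is not None and not consumed[j]:
                meth[i] += meth[j]
                total[i] += total[j]
                consumed[j] = True
        keep = ~consumed
        out_chrom.extend([chrom] * int(keep.sum()))
        out_pos.extend(pos[keep])
        out_meth.extend(meth[keep])
        out_total.extend(total[keep])
    return pd.DataFrame(
        {"chrom": out_chrom, "pos": out_pos, "meth": out_meth, "total": out_total}
    )


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, individual_id, sex, age_years).

    Sex is coded F/M; anything else is kept but treated as unknown by the
    sex-effect analyses.  Ages are non-negative years.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str})
    missing_cols = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing required columns: {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dups}")
    if (meta["age_years"] < 0).any():
        raise ValueError("age_years must be non-negative")
    return meta.reset_index(drop=True)


def assemble_dataset(
    coverage_files: Mapping[str, object],
    metadata,
    collapse: bool = False,
) -> MethylationDataset:
    """Assemble the cross-sample dataset from per-sample coverage files.

    The site universe is the union of sites seen in any sample; a site
    absent from a sample's file is missing (total 0) there.  Site order is
    deterministic: chromosome lexicographic, then position.  The result is
    invariant to the order of ``coverage_files``.

    ``metadata`` may be a path or an already-read DataFrame; every coverage
    sample_id must appear there and vice versa.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    cov_ids = set(coverage_files)
    meta_ids = set(metadata["sample_id"])
    only_cov = sorted(cov_ids - meta_ids)
    only_meta = sorted(meta_ids - cov_ids)
    if only_cov or only_meta:
        raise ValueError(
            "coverage/metadata sample mismatch: "
            f"missing from metadata {only_cov}; missing coverage {only_meta}"
        )

    per_sample: dict[str, pd.DataFrame] = {}
    for sid in metadata["sample_id"]:
        src = coverage_files[sid]
        df = src if isinstance(src, pd.DataFrame) else read_coverage_file(src, sid)
        if collapse:
            df = collapse_strands(df)
        if df.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError(f"sample {sid}: duplicate sites in coverage file")
        per_sample[sid] = df

    universe = (
        pd.concat([df[["chrom", "pos"]] for df in per_sample.values()])
        .drop_duplicates()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    index = pd.MultiIndex.from_frame(universe)
    n_sites, n_samples = len(universe), len(metadata)
    meth = np.zeros((n_sites, n_samples), dtype=np.int64)
    total = np.zeros((n_sites, n_samples), dtype=np.int64)
    for col, sid in enumerate(metadata["sample_id"]):
        df = per_sample[sid]
        loc = index.get_indexer(pd.MultiIndex.from_frame(df[["chrom", "pos"]]))
        meth[loc, col] = df["meth"].to_numpy()
        total[loc, col] = df["total"].to_numpy()
    return MethylationDataset(
        sites=universe, samples=metadata.reset_index(drop=True),
        meth=meth, total=total,
    )


def read_intervals(path, kind: str = "bed") -> pd.DataFrame:
    """Read BED3 intervals or BED12 gene models.

    BED is 0-based half-open on disk; the returned table uses the internal
    1-based inclusive convention.  For BED12 the result carries one row per
    gene with ``strand``, ``tss`` (start of gene on plus strand, end on
    minus) and ``exons``, a list of 1-based inclusive (start, end) pairs
    derived from the block fields.
    """
    if kind not in ("bed", "bed12"):
        raise ValueError(f"kind must be 'bed' or 'bed12', got {kind!r}")
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if kind == "bed":
                if len(parts) < 3:
                    raise ValueError(f"{path}: line {lineno}: BED needs >= 3 fields")
                chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
                rows.append({"chrom": chrom, "start": start0 + 1, "end": end0})
            else:
                if len(parts) < 12:
                    raise ValueError(f"{path}: line {lineno}: BED12 needs 12 fields")
                chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
                name, strand = parts[3], parts[5]
                if strand not in ("+", "-"):
                    raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise ValueError(
                        f"{path}: line {lineno}: blockCount disagrees with "
                        "blockSizes/blockStarts"
                    )
                if starts[0] != 0 or starts[-1] + sizes[-1] != end0 - start0:
                    raise ValueError(
                        f"{path}: line {lineno}: blocks inconsistent with chromEnd"
                    )
                exons = [
                    (start0 + bs + 1, start0 + bs + sz)
                    for bs, sz in zip(starts, sizes)
                ]
                tss = start0 + 1 if strand == "+" else end0
                rows.append(
                    {
                        "chrom": chrom, "start": start0 + 1, "end": end0,
                        "name": name, "strand": strand, "tss": tss, "exons": exons,
                    }
                )
    return pd.DataFrame(rows)


def save_dataset(dataset: MethylationDataset, path) -> None:
    """Serialize a dataset to a single ``.npz`` archive (lossless)."""
    np.savez_compressed(
        path,
        chrom=dataset.sites["chrom"].to_numpy(dtype="U"),
        pos=dataset.sites["pos"].to_numpy(dtype=np.int64),
        meth=dataset.meth,
        total=dataset.total,
        samples_json=np.array(
            dataset.samples.to_json(orient="table", index=False)
        ),
    )


def load_dataset(path) -> MethylationDataset:
    with np.load(path, allow_pickle=False) as z:
        sites = pd.DataFrame({"chrom": z["chrom"].astype(str), "pos": z["pos"]})
        samples = pd.read_json(
            io.StringIO(str(z["samples_json"])), orient="table"
        ).reset_index(drop=True)
        return MethylationDataset(
            sites=sites, samples=samples,
            meth=z["meth"], total=z["total"],
        )
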