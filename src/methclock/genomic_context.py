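"""CpG-density and genic context classification of clock sites.

Density context follows the island/shore convention: a site inside a
(merged) CpG island is ``island``; within 2,000 bp of an island boundary
but not inside any island, ``shore`` (boundary inclusive); anything
further is ``outside``.  Genic context uses strand-aware transcription
start sites: ``promoter`` when within +/-2,000 bp of a TSS (inclusive,
and taking precedence over everything), else ``exon`` when inside an
exon block, else ``intron`` inside the gene span, else ``intergenic``
with the nearest gene and a strand-aware upstream/downstream call.
Age direction per site comes from the sign of its age correlation:
r > 0 hypermethylating, r < 0 hypomethylating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SHORE_BP", "PROMOTER_BP", "GenomicAnnotation", "merge_intervals",
           "classify_density", "classify_genic", "annotate_sites",
           "summarize_by_context"]

SHORE_BP = 2000
PROMOTER_BP = 2000


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent 1-based inclusive intervals per chrom."""
    out = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        for s, e in grp[["start", "end"]].itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


@dataclass
class GenomicAnnotation:
    """Island intervals and gene models used for context classification."""

    islands: pd.DataFrame | None = None  # chrom, start, end (1-based incl.)
    genes: pd.DataFrame | None = None  # chrom, start, end, name, strand, tss, exons

    def __post_init__(self):
        if self.islands is not None:
            self.islands = merge_intervals(self.islands)


def classify_density(
    sites: pd.DataFrame, islands: pd.DataFrame, shore_bp: int = SHORE_BP
) -> np.ndarray:
    """Label each site island / shore / outside (a partition).

    Islands must be non-overlapping after merging (``merge_intervals`` is
    applied).  A site within ``shore_bp`` of two islands is a single
    shore, never double-counted.
    """
    islands = merge_intervals(islands)
    labels = np.full(len(sites), "outside", dtype=object)
    for chrom, grp in islands.groupby("chrom", sort=False):
        mask = (sites["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos = sites.loc[mask, "pos"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # interval index whose start is the rightmost <= pos
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos <= ends[np.clip(j, 0, None)])
        near_prev = (j >= 0) & (pos - ends[np.clip(j, 0, None)] <= shore_bp)
        nxt = np.clip(j + 1, 0, len(starts) - 1)
        near_next = (j + 1 < len(starts)) & (starts[nxt] - pos <= shore_bp)
        sub = np.where(inside, "island",
                       np.where(near_prev | near_next, "shore", "outside"))
        labels[mask] = sub
    return labels


def classify_genic(
    sites: pd.DataFrame, genes: pd.DataFrame, promoter_bp: int = PROMOTER_BP
) -> pd.DataFrame:
    """Genic context per site with nearest gene and TSS distance.

    Precedence: promoter (|pos - TSS| <= promoter_bp, strand-aware TSS) >
    exon > intron > intergenic.  The nearest gene is the one minimizing
    |pos - TSS|; ties break toward the lower gene start, then the
    lexicographically smaller name.  ``position_rel_gene`` is upstream /
    downstream / within relative to gene strand (upstream = 5' side).
    The result is invariant to gene-list order.
    """
    genes = genes.sort_values(["chrom", "start", "name"]).reset_index(drop=True)
    records = []
    for chrom, pos in sites[["chrom", "pos"]].itertuples(index=False):
        cand = genes[genes["chrom"] == chrom]
        if cand.empty:
            records.append(("intergenic", "none", None, np.nan))
            continue
        tss = cand["tss"].to_numpy()
        dist = np.abs(pos - tss)
        j = int(np.argmin(dist))  # argmin is first minimum: start/name tie-break
        nearest = cand.iloc[j]
        d_tss = int(dist[j])

        if d_tss <= promoter_bp:
            rel = _relative_position(pos, nearest)
            records.append(("promoter", rel, nearest["name"], d_tss))
            continue
        inside = cand[(cand["start"] <= pos) & (pos <= cand["end"])]
        if not inside.empty:
            host = inside.iloc[0]
            in_exon = any(s <= pos <= e for s, e in host["exons"])
            d_host = int(abs(pos - host["tss"]))
            records.append(
                ("exon" if in_exon else "intron", "within", host["name"], d_host)
            )
            continue
        rel = _relative_position(pos, nearest)
        records.append(("intergenic", rel, nearest["name"], d_tss))
    return pd.DataFrame(
        records,
        columns=["genic", "position_rel_gene", "nearest_gene", "tss_distance"],
    )


def _relative_position(pos: int, gene: pd.Series) -> str:
    if gene["start"] <= pos <= gene["end"]:
        return "within"
    before = pos < gene["start"]
    if gene["strand"] == "+":
        return "upstream" if before else "downstream"
    return "downstream" if before else "upstream"


def annotate_sites(
    sites: pd.DataFrame,
    annotation: GenomicAnnotation,
    r: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full context labels for a set of (clock) sites.

    ``r`` — the per-site age correlation — sets the direction label:
    hyper (r > 0) or hypo (r < 0).
    """
    out = sites[["chrom", "pos"]].reset_index(drop=True).copy()
    if annotation.islands is not None:
        out["density"] = classify_density(out, annotation.islands)
    if annotation.genes is not None:
        out = pd.concat([out, classify_genic(out, annotation.genes)], axis=1)
    if r is not None:
        out["r"] = np.asarray(r, float)
        out["direction"] = np.where(out["r"] > 0, "hyper", "hypo")
    return out


def summarize_by_context(annotated: pd.DataFrame) -> dict:
    """Contingency and trend tables over density / genic categories.

    Per category: site counts, hyper/hypo counts and mean age correlation;
    plus a one-way ANOVA of per-site r across the populated density
    groups.  Empty categories are reported with count 0 and excluded from
    the ANOVA.
    """
    tables = {}
    for key in ("density", "genic"):
        if key not in annotated.columns:
            continue
        levels = (
            ["island", "shore", "outside"] if key == "density"
            else ["promoter", "exon", "intron", "intergenic"]
        )
        rows = []
        for lev in levels:
            sub = annotated[annotated[key] == lev]
            rows.append(
                {
                    key: lev,
                    "n": len(sub),
                    "n_hyper": int((sub.get("direction") == "hyper").sum()),
                    "n_hypo": int((sub.get("direction") == "hypo").sum()),
                    "mean_r": float(sub["r"].mean()) if len(sub) else np.nan,
                }
            )
        tables[key] = pd.DataFrame(rows)

    result = {"tables": tables}
    if "density" in annotated.columns and "r" in annotated.columns:
        groups = [
            annotated.loc[annotated["density"] == lev, "r"].to_numpy()
            for lev in ("island", "shore", "outside")
        ]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) >= 2:
            F, p = stats.f_oneway(*groups)
            result["anova_F"] = float(F)
            result["anova_p"] = float(p)
    return result
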