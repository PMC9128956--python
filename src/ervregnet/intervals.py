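"""Genomic interval utilities shared across the enrichment and
polymorphism modules.

Intervals are held in pandas DataFrames with 0-based half-open
``chrom``/``start``/``end`` columns (BED convention).  Overlap queries are
answered with sorted arrays and a running maximum of interval ends, which
handles overlapping input intervals without building a tree.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def validate_intervals(df: pd.DataFrame, chrom_lengths: Mapping[str, int] | None = None) -> None:
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError("intervals must satisfy 0 <= start < end")
    if chrom_lengths is not None:
        for chrom, grp in df.groupby("chrom"):
            if chrom not in chrom_lengths:
                raise ValueError(f"unknown chromosome {chrom}")
            if (grp["end"] > chrom_lengths[chrom]).any():
                raise ValueError(f"interval beyond end of {chrom}")


class OverlapIndex:
    """Per-chromosome index answering point/interval overlap queries."""

    def __init__(self, df: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in df.groupby("chrom"):
            order = np.argsort(grp["start"].to_numpy(), kind="stable")
            starts = grp["start"].to_numpy()[order]
            ends = grp["end"].to_numpy()[order]
            self._by_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends))

    def overlaps_any(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean array: does each query interval share >=1 bp with the set?"""
        if chrom not in self._by_chrom:
            return np.zeros(len(starts), dtype=bool)
        t_starts, _, t_cummax = self._by_chrom[chrom]
        idx = np.searchsorted(t_starts, ends, side="left")
        hit = idx > 0
        hit[hit] = t_cummax[idx[hit] - 1] > starts[hit]
        return hit


def count_overlapping(query: pd.DataFrame, targets: pd.DataFrame) -> int:
    """Number of query intervals overlapping (>=1 bp) any target interval."""
    return int(overlap_flags(query, targets).sum())


def overlap_flags(query: pd.DataFrame, targets: pd.DataFrame) -> pd.Series:
    """Per-query boolean: overlaps any target (>=1 bp, strand-agnostic)."""
    index = OverlapIndex(targets)
    out = np.zeros(len(query), dtype=bool)
    pos = np.arange(len(query))
    for chrom, grp in query.groupby("chrom"):
        loc = pos[(query["chrom"] == chrom).to_numpy()]
        out[loc] = index.overlaps_any(
            chrom, grp["start"].to_numpy(), grp["end"].to_numpy()
        )
    return pd.Series(out, index=query.index)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or bookended intervals per chromosome (idempotent)."""
    rows = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby("chrom"):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def total_length(df: pd.DataFrame) -> int:
    """Total bp covered; intervals are merged first."""
    merged = merge_intervals(df)
    return int((merged["end"] - merged["start"]).sum()) if len(merged) else 0


def point_interval_distance(
    points: pd.DataFrame, targets: pd.DataFrame
) -> pd.DataFrame:
    """Distance from each point to the nearest target interval.

    ``points`` needs ``chrom``/``pos`` columns; distance is 0 inside an
    interval, else the gap to the nearer end.  Returns a DataFrame aligned
    to ``points`` with ``distance`` (np.inf when the chromosome holds no
    target) and ``nearest`` (positional index into ``targets``, -1 if none).
    """
    dist = np.full(len(points), np.inf)
    nearest = np.full(len(points), -1, dtype=int)
    tpos = np.arange(len(targets))
    ppos = np.arange(len(points))
    for chrom, tgrp in targets.groupby("chrom"):
        sel = (points["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        order = np.argsort(tgrp["start"].to_numpy(), kind="stable")
        starts = tgrp["start"].to_numpy()[order]
        ends = tgrp["end"].to_numpy()[order]
        orig = tpos[(targets["chrom"] == chrom).to_numpy()][order]
        cummax = np.maximum.accumulate(ends)
        # index of the interval attaining the running max end (for ids)
        argmax = np.arange(len(ends))
        for i in range(1, len(ends)):
            if ends[argmax[i - 1]] >= ends[i]:
                argmax[i] = argmax[i - 1]
        pts = points.loc[sel, "pos"].to_numpy()
        idx = np.searchsorted(starts, pts, side="right")
        d = np.full(len(pts), np.inf)
        near = np.full(len(pts), -1, dtype=int)
        has_prev = idx > 0
        prev_end = np.where(has_prev, cummax[np.maximum(idx - 1, 0)], -1)
        inside = has_prev & (prev_end > pts)
        d[inside] = 0.0
        near[inside] = orig[argmax[np.maximum(idx - 1, 0)][inside]]
        left_gap = np.where(has_prev & ~inside, pts - prev_end + 1, np.inf)
        has_next = idx < len(starts)
        right_gap = np.where(
            has_next & ~inside, starts[np.minimum(idx, len(starts) - 1)] - pts, np.inf
        )
        use_left = ~inside & (left_gap <= right_gap)
        use_right = ~inside & (right_gap < left_gap)
        d[use_left] = left_gap[use_left]
        near[use_left] = orig[argmax[np.maximum(idx - 1, 0)][use_left]]
        d[use_right] = right_gap[use_right]
        near[use_right] = orig[np.minimum(idx, len(starts) - 1)[use_right]]
        dist[ppos[sel]] = d
        nearest[ppos[sel]] = near
    return pd.DataFrame({"distance": dist, "nearest": nearest}, index=points.index)


# ---------------------------------------------------------------------------
# File format adapters


def read_bed(path, filter_min_score: float | None = None) -> pd.DataFrame:
    """Read BED3-6.  ``filter_min_score`` drops rows with score below the
    threshold (used for reliability filtering of repeat annotations)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    if filter_min_score is not None:
        if "score" not in df.columns:
            raise ValueError("score filtering requested but BED has no score column")
        df = df[df["score"] >= filter_min_score].reset_index(drop=True)
    validate_intervals(df)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path) -> pd.DataFrame:
    names = BED_COLUMNS + ["signal", "pvalue", "qvalue", "peak_offset"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    validate_intervals(df)
    return df


def tss_from_gtf(path) -> pd.DataFrame:
    """Extract per-transcript TSSs from a GTF file.

    GTF is 1-based inclusive; after conversion to 0-based half-open, the
    TSS of a + strand transcript is its start and of a - strand transcript
    its end-1.  Returns columns ``gene``, ``chrom``, ``pos``, ``strand``.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "transcript":
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]) - 1, int(f[4]), f[6], f[8]
            gene = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gene = item.split()[1].strip('"')
                    break
            if gene is None:
                continue
            pos = start if strand == "+" else end - 1
            rows.append((gene, chrom, pos, strand))
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "strand"])
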