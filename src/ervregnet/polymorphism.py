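"""Detection of reference TE insertions absent from individual genomes.

When an individual lacks a TE insertion that is present in the reference
genome, reads sequenced from the empty allele map across the insertion
site: the aligner soft-clips them at one element boundary and places the
clipped tail at the other boundary as a supplementary alignment (recorded
in the SA tag of the primary record).  Such "skipping reads" — one mapped
segment ending near the element's left edge and the other starting near
its right edge — evidence an allele without the insertion.  A locus is
called absent in a sample when at least ``min_reads`` distinct skipping
reads support it (the read-count floor guards against index hopping and
similar cross-sample artifacts).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd
import pysam

__all__ = [
    "SplitReadCandidate",
    "extract_candidates",
    "count_skipping_reads",
    "call_absent_alleles",
    "summarize_cohort",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


@dataclass(frozen=True)
class SplitReadCandidate:
    """One primary soft-clipped read whose two segments share a chromosome.

    ``left_end`` is the reference end of the leftmost segment and
    ``right_start`` the reference start of the rightmost segment — the two
    facing breakpoints of the putative deletion junction.
    """

    read_id: str
    chrom: str
    left_end: int
    right_start: int


def _cigar_ref_span(cigar: str) -> int:
    span = 0
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.group(2) in _REF_CONSUMING:
            span += int(m.group(1))
        pos = m.end()
    if pos != len(cigar) or span == 0:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return span


def extract_candidates(
    records: Iterable[pysam.AlignedSegment],
) -> tuple[list[SplitReadCandidate], int]:
    """Select primary soft-clipped records with a supplementary mapping.

    Keeps primary (non-secondary, non-supplementary) records that are
    soft-clipped and carry an SA tag; derives the reference span of the
    clipped portion from the first SA entry.  Pairs whose two segments map
    to different chromosomes are discarded.  Returns the candidates and
    the number of records skipped for malformed CIGARs.
    """
    out: list[SplitReadCandidate] = []
    n_malformed = 0
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.cigartuples is None or not any(
            op == 4 for op, _ in rec.cigartuples  # 4 = soft clip
        ):
            continue
        if not rec.has_tag("SA"):
            continue
        sa = rec.get_tag("SA").split(";")[0]
        fields = sa.split(",")
        if len(fields) < 4:
            n_malformed += 1
            continue
        sa_chrom, sa_pos, _sa_strand, sa_cigar = fields[0], fields[1], fields[2], fields[3]
        if sa_chrom != rec.reference_name:
            continue
        try:
            sa_start = int(sa_pos) - 1  # SA positions are 1-based
            sa_span = _cigar_ref_span(sa_cigar)
            primary_start = rec.reference_start
            primary_end = rec.reference_end
            if primary_end is None:
                raise ValueError("unaligned primary span")
        except (ValueError, TypeError):
            n_malformed += 1
            continue
        sa_end = sa_start + sa_span
        if primary_start <= sa_start:
            left_end, right_start = primary_end, sa_start
        else:
            left_end, right_start = sa_end, primary_start
        out.append(
            SplitReadCandidate(rec.query_name, rec.reference_name, left_end, right_start)
        )
    if n_malformed:
        warnings.warn(f"skipped {n_malformed} records with malformed CIGAR/SA")
    return out, n_malformed


def count_skipping_reads(
    candidates: Iterable[SplitReadCandidate],
    te_loci: pd.DataFrame,
    tolerance: int = 25,
) -> pd.Series:
    """Count distinct skipping reads per TE locus.

    A candidate supports a locus when its left segment's end lies within
    ``tolerance`` nt of the locus start AND its right segment's start lies
    within ``tolerance`` nt of the locus end — the two segments flank the
    element from opposite sides.  Duplicate read ids are collapsed per
    locus, and one read contributes at most one event per locus.

    ``te_loci`` needs ``chrom``/``start``/``end``/``locus_id`` columns.
    Returns counts indexed by locus_id (loci with zero support included).
    """
    support: dict[str, set[str]] = {lid: set() for lid in te_loci["locus_id"]}
    by_chrom = {chrom: grp for chrom, grp in te_loci.groupby("chrom")}
    for cand in candidates:
        grp = by_chrom.get(cand.chrom)
        if grp is None:
            continue
        near_left = (grp["start"] - cand.left_end).abs() <= tolerance
        near_right = (grp["end"] - cand.right_start).abs() <= tolerance
        for lid in grp.loc[near_left & near_right, "locus_id"]:
            support[lid].add(cand.read_id)
    return pd.Series(
        {lid: len(reads) for lid, reads in support.items()}, name="skipping_reads"
    ).rename_axis("locus_id")


def call_absent_alleles(
    counts_by_sample: dict[str, pd.Series], min_reads: int = 2
) -> pd.DataFrame:
    """Per (locus, sample) absent-allele calls from skipping-read counts.

    A sample lacks at least one allele of a locus when ``min_reads`` or
    more skipping reads support it.  Returns a long-format DataFrame with
    columns ``locus_id``, ``sample``, ``skipping_reads``, ``absent_allele``.
    """
    rows = []
    for sample, counts in counts_by_sample.items():
        for lid, n in counts.items():
            rows.append((lid, sample, int(n), n >= min_reads))
    return pd.DataFrame(
        rows, columns=["locus_id", "sample", "skipping_reads", "absent_allele"]
    )


def summarize_cohort(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-locus cohort summary: samples lacking >=1 allele and the fraction."""
    n_samples = calls["sample"].nunique()
    grp = calls.groupby("locus_id")["absent_allele"].sum().astype(int)
    return pd.DataFrame(
        {
            "n_samples_lacking": grp,
            "fraction_lacking": grp / n_samples if n_samples else 0.0,
        }
    )


def read_sam_candidates(path) -> tuple[list[SplitReadCandidate], int]:
    """Extract split-read candidates straight from a SAM/BAM file."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        return extract_candidates(fh)
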