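"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generators emulate the statistical structure of the study inputs:

* :func:`simulate_expression` — negative-binomial single-cell count
  matrices over the germ-cell induction series plus naive/primed ESCs,
  with gene classes planted as shared, PGCLC-only, naive-only or null
  upregulation;
* :func:`simulate_genome` — a toy genome with TE loci per subfamily,
  peak sets placed on TE loci at a controlled rate, and strand-aware
  gene TSSs;
* :func:`simulate_ortholog_history` — loci assigned to primate-tree
  insertion branches, a tree-consistent old-to-young order, and a
  presence/absence table masked with missing values;
* :func:`simulate_alignments` — SAM records containing soft-clipped
  junction-spanning reads at planted absent-allele loci, plus noise
  reads clipped far from any element boundary.

Read bases are arbitrary; the generators aim for the count/interval/
label structure the statistics consume, not sequence realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .expression import ExpressionMatrix, GERMLINE_CELL_TYPES

__all__ = [
    "ExpressionDesign",
    "GenomeDesign",
    "HistoryDesign",
    "ReadSimDesign",
    "ALL_CELL_TYPES",
    "SPECIES_ORDER",
    "BRANCH_SPECIES",
    "simulate_expression",
    "simulate_genome",
    "simulate_ortholog_history",
    "simulate_alignments",
    "write_sam",
]

ALL_CELL_TYPES = GERMLINE_CELL_TYPES + ("naiveESC", "primedESC")

#: Ortholog-table species, ordered by divergence from human (deep to shallow).
SPECIES_ORDER = ("marmoset", "macaque", "gibbon", "orangutan", "gorilla", "chimpanzee")

#: Species carrying an orthologous insertion for each branch label.
BRANCH_SPECIES = {
    "HCGOG": {"chimpanzee", "gorilla", "orangutan", "gibbon"},
    "HCGO": {"chimpanzee", "gorilla", "orangutan"},
    "HCG": {"chimpanzee", "gorilla"},
    "HC": {"chimpanzee"},
    "H": set(),
}


def _check_positive(name: str, value: float) -> None:
    if value <= 0:
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass
class ExpressionDesign:
    """Design of a planted-signal single-cell count matrix.

    ``effect_size`` is a multiplicative mean shift applied in the "up"
    cell types of each gene class; MLC receives half the PGCLC effect,
    mirroring the half weight the specificity model assigns MLC.
    """

    n_cells_per_type: Mapping[str, int] = field(
        default_factory=lambda: {ct: 200 for ct in ALL_CELL_TYPES}
    )
    cell_types: tuple[str, ...] = ALL_CELL_TYPES
    n_genes_per_class: Mapping[str, int] = field(
        default_factory=lambda: {
            "both_up": 100,
            "pgclc_only": 100,
            "naive_only": 100,
            "null": 1700,
        }
    )
    effect_size: float = 4.0
    library_size: float = 5000.0
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for ct in self.cell_types:
            if self.n_cells_per_type.get(ct, 0) < 1:
                raise ValueError(f"cell type {ct!r} requires at least one cell")
        for cls, n in self.n_genes_per_class.items():
            if n < 0:
                raise ValueError(f"negative gene count for class {cls!r}")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        _check_positive("library_size", self.library_size)
        _check_positive("dispersion", self.dispersion)


@dataclass
class GenomeDesign:
    """Design of a toy genome: TE loci, peak sets and gene TSSs."""

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_500_000}
    )
    n_te_loci: Mapping[str, int] = field(
        default_factory=lambda: {"LTR5_Hs": 60, "LTR5B": 40, "AluY": 80}
    )
    te_length_range: tuple[int, int] = (300, 1000)
    n_peaks: Mapping[str, int] = field(default_factory=lambda: {"both": 80, "pgclc": 60})
    planted_overlap_rate: float = 0.5
    target_subfamily: str = "LTR5_Hs"
    n_genes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.planted_overlap_rate <= 1:
            raise ValueError("planted_overlap_rate must lie in [0, 1]")
        lo, hi = self.te_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid te_length_range")
        if hi > max(self.chrom_lengths.values()):
            raise ValueError("TE length exceeds every chromosome")
        if self.target_subfamily not in self.n_te_loci:
            raise ValueError(f"unknown target subfamily {self.target_subfamily!r}")


@dataclass
class HistoryDesign:
    """Design of a planted ortholog history over the primate tree."""

    n_loci: int = 200
    branch_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"HCGOG": 0.3, "HCGO": 0.1, "HCG": 0.2, "HC": 0.15, "H": 0.25}
    )
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        total = sum(self.branch_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"branch_proportions must sum to 1, got {total}")
        unknown = set(self.branch_proportions) - set(BRANCH_SPECIES)
        if unknown:
            raise ValueError(f"unknown branches: {sorted(unknown)}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class ReadSimDesign:
    """Design of a split-read alignment simulation for one sample."""

    n_loci: int = 50
    absent_loci: tuple[str, ...] = ()
    reads_per_junction: int = 4
    read_length: int = 150
    min_clip: int = 30
    noise_reads: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_junction < 0 or self.noise_reads < 0:
            raise ValueError("read counts must be >= 0")
        if self.read_length < 2 * self.min_clip:
            raise ValueError(
                f"read_length {self.read_length} shorter than twice the minimum "
                f"clip {self.min_clip}"
            )


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    design: ExpressionDesign,
    gene_classes: pd.Series | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial counts with planted class structure.

    Gene classes: ``both_up`` genes have their mean multiplied by
    ``effect_size`` in PGCLC and naiveESC (half effect in MLC);
    ``pgclc_only`` genes only in PGCLC/MLC; ``naive_only`` genes only in
    naiveESC; ``null`` genes are flat.  Counts are NB(mean m, dispersion
    r) with variance m + m^2/r; ``dispersion=inf`` gives the Poisson
    limit.  Returns the matrix and a truth table (gene -> class).

    ``gene_classes`` (gene id -> class) overrides the design's class
    layout; it is how a second species sharing gene ids but with a
    different planted truth is generated.
    """
    rng = np.random.default_rng(design.seed)
    if gene_classes is not None:
        unknown = set(gene_classes.unique()) - {"both_up", "pgclc_only", "naive_only", "null"}
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        genes = list(gene_classes.index)
        classes = list(gene_classes.values)
    else:
        genes, classes = [], []
        for cls in ("both_up", "pgclc_only", "naive_only", "null"):
            n = design.n_genes_per_class.get(cls, 0)
            for i in range(n):
                genes.append(f"{cls}_{i:04d}")
                classes.append(cls)
    n_genes = len(genes)
    if n_genes == 0:
        raise ValueError("design contains no genes")

    # baseline per-gene expression rates, lognormal across genes
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base /= base.sum()

    e = design.effect_size
    half = 1.0 + (e - 1.0) / 2.0
    effect = {
        "both_up": {"PGCLC": e, "MLC": half, "naiveESC": e},
        "pgclc_only": {"PGCLC": e, "MLC": half},
        "naive_only": {"naiveESC": e},
        "null": {},
    }

    cols, meta_rows, blocks = [], [], []
    cls_arr = np.array(classes)
    for ct in design.cell_types:
        n_cells = design.n_cells_per_type[ct]
        mult = np.ones(n_genes)
        for cls, by_type in effect.items():
            if ct in by_type:
                mult[cls_arr == cls] = by_type[ct]
        # planted means are exactly base*effect; per-cell totals therefore
        # exceed library_size in cell types with activated programs, as in
        # real cells (depth is removed downstream by CP10k anyway)
        mean = base * mult * design.library_size
        m = np.tile(mean[:, None], (1, n_cells))
        if np.isinf(design.dispersion):
            block = rng.poisson(m)
        else:
            r = design.dispersion
            block = rng.negative_binomial(r, r / (r + m))
        blocks.append(block)
        dataset = "esc" if ct in ("naiveESC", "primedESC") else "germline"
        for i in range(n_cells):
            cols.append(f"{ct}_{i:04d}")
            meta_rows.append((ct, dataset))

    counts = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(genes, name="feature"), columns=cols
    )
    meta = pd.DataFrame(meta_rows, index=pd.Index(cols, name="cell_id"),
                        columns=["cell_type", "dataset"])
    truth = pd.DataFrame({"gene_class": classes}, index=pd.Index(genes, name="gene"))
    return ExpressionMatrix(counts, meta), truth


# ---------------------------------------------------------------------------
# Genome


def _place_interval(
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    length: int,
    accept,
    max_tries: int = 1000,
) -> tuple[str, int, int]:
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    for _ in range(max_tries):
        ci = int(rng.choice(len(chroms), p=probs))
        if lens[ci] < length:
            continue
        start = int(rng.integers(0, int(lens[ci]) - length + 1))
        iv = (chroms[ci], start, start + length)
        if accept(iv):
            return iv
    raise RuntimeError(f"could not place an interval of length {length} in 1000 tries")


def simulate_genome(
    design: GenomeDesign,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Toy genome: TE annotation, peak sets and a TSS table.

    Exactly ``round(planted_overlap_rate * n_peaks)`` peaks of each
    category overlap a TE locus of the target subfamily; the remaining
    peaks are placed off every target locus.  Two runs with the same seed
    give identical output.
    """
    rng = np.random.default_rng(design.seed)
    lo, hi = design.te_length_range

    te_rows = []
    occupied: list[tuple[str, int, int]] = []

    def no_te_overlap(iv):
        return all(
            not (iv[0] == o[0] and iv[1] < o[2] and o[1] < iv[2]) for o in occupied
        )

    for subfam in sorted(design.n_te_loci):
        for i in range(design.n_te_loci[subfam]):
            length = int(rng.integers(lo, hi + 1))
            iv = _place_interval(rng, design.chrom_lengths, length, no_te_overlap)
            occupied.append(iv)
            te_rows.append(
                (
                    iv[0],
                    iv[1],
                    iv[2],
                    f"{subfam}_{i:04d}",
                    subfam,
                    float(rng.integers(2500, 10001)),
                    "+" if rng.random() < 0.5 else "-",
                )
            )
    te = pd.DataFrame(
        te_rows,
        columns=["chrom", "start", "end", "locus_id", "subfamily", "score", "strand"],
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    targets = te[te["subfamily"] == design.target_subfamily]
    target_ivs = list(zip(targets["chrom"], targets["start"], targets["end"]))

    def overlaps_target(iv):
        return any(
            iv[0] == o[0] and iv[1] < o[2] and o[1] < iv[2] for o in target_ivs
        )

    peak_sets: dict[str, pd.DataFrame] = {}
    for cat in sorted(design.n_peaks):
        n = design.n_peaks[cat]
        n_on = int(round(design.planted_overlap_rate * n))
        rows = []
        for i in range(n_on):
            # anchor the peak on a random target locus
            o = target_ivs[int(rng.integers(0, len(target_ivs)))]
            length = int(rng.integers(200, 601))
            offset = int(rng.integers(-length + 1, o[2] - o[1]))
            start = max(0, o[1] + offset)
            end = min(design.chrom_lengths[o[0]], start + length)
            rows.append((o[0], start, end, f"{cat}_peak_{i:04d}", 0, "."))
        for i in range(n_on, n):
            length = int(rng.integers(200, 601))
            iv = _place_interval(
                rng, design.chrom_lengths, length, lambda iv: not overlaps_target(iv)
            )
            rows.append((iv[0], iv[1], iv[2], f"{cat}_peak_{i:04d}", 0, "."))
        peak_sets[cat] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    tss_rows = []
    for i in range(design.n_genes):
        iv = _place_interval(rng, design.chrom_lengths, 1, lambda iv: True)
        strand = "+" if rng.random() < 0.5 else "-"
        tss_rows.append((f"gene_{i:04d}", iv[0], iv[1], strand))
    tss = pd.DataFrame(tss_rows, columns=["gene", "chrom", "pos", "strand"])
    return te, peak_sets, tss


# ---------------------------------------------------------------------------
# Ortholog history


def simulate_ortholog_history(
    design: HistoryDesign,
) -> tuple[list[str], pd.DataFrame, pd.Series]:
    """Planted insertion branches, tree order and masked ortholog table.

    Loci are assigned to branches by the design proportions and ordered
    old to young (every HCGOG locus precedes every HCGO locus, and so
    on).  Species presence follows the planted branch (e.g. an HCG locus
    is present in chimpanzee and gorilla and absent elsewhere), then each
    cell is masked to 'missing' independently at ``missing_rate``.
    """
    rng = np.random.default_rng(design.seed)
    branch_order = ["HCGOG", "HCGO", "HCG", "HC", "H"]
    props = [design.branch_proportions.get(b, 0.0) for b in branch_order]
    counts = np.floor(np.asarray(props) * design.n_loci).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    remainder = design.n_loci - counts.sum()
    frac = np.asarray(props) * design.n_loci - counts
    for i in np.argsort(-frac)[:remainder]:
        counts[i] += 1

    order, truth = [], []
    for b, n in zip(branch_order, counts):
        for i in range(n):
            order.append(f"locus_{len(order):04d}")
            truth.append(b)
    truth = pd.Series(truth, index=pd.Index(order, name="locus_id"), name="branch")

    table = pd.DataFrame(
        "absent", index=pd.Index(order, name="locus_id"), columns=list(SPECIES_ORDER)
    )
    for lid, b in truth.items():
        for sp in BRANCH_SPECIES[b]:
            table.loc[lid, sp] = "present"
    if design.missing_rate > 0:
        mask = rng.random(table.shape) < design.missing_rate
        vals = table.to_numpy(dtype=object)
        vals[mask] = "missing"
        table = pd.DataFrame(vals, index=table.index, columns=table.columns)
    return order, table, truth


# ---------------------------------------------------------------------------
# Split-read alignments


def simulate_alignments(
    design: ReadSimDesign,
    te_annotation: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    sample: str = "sample0",
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """SAM records containing planted skipping reads for absent loci.

    For each planted absent locus, ``reads_per_junction`` primary
    soft-clipped records are generated whose non-clipped portion ends at
    the element's left boundary and whose clipped portion (described in
    the SA tag) starts at the right boundary, i.e. the read spans the
    empty insertion site.  Noise reads are soft-clipped with SA tags but
    their breakpoints lie > 25 nt from any element boundary.
    """
    if te_annotation.empty:
        raise ValueError("empty TE annotation")
    unknown = set(design.absent_loci) - set(te_annotation["locus_id"])
    if unknown:
        raise ValueError(f"absent loci not in annotation: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(design.seed)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c, "LN": int(l)} for c, l in sorted(chrom_lengths.items())
            ],
            "RG": [{"ID": sample, "SM": sample}],
        }
    )
    loci = te_annotation.set_index("locus_id")
    records: list[pysam.AlignedSegment] = []
    read_no = 0

    def make_record(name, chrom, pos, cigar, sa):
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        rec.reference_name = chrom
        rec.reference_start = pos
        rec.cigarstring = cigar
        rec.flag = 0
        rec.mapping_quality = 60
        rec.query_sequence = "A" * design.read_length
        rec.set_tag("SA", sa)
        rec.set_tag("RG", sample)
        return rec

    for lid in design.absent_loci:
        row = loci.loc[lid]
        chrom, start, end = row["chrom"], int(row["start"]), int(row["end"])
        for _ in range(design.reads_per_junction):
            matched = int(rng.integers(design.min_clip, design.read_length - design.min_clip + 1))
            clipped = design.read_length - matched
            # primary maps left of the element, ending exactly at its start
            p_start = start - matched
            if p_start < 0:
                matched = start if start > 0 else design.min_clip
                clipped = design.read_length - matched
                p_start = 0
            cigar = f"{matched}M{clipped}S"
            sa = f"{chrom},{end + 1},+,{matched}H{clipped}M,60,0;"
            records.append(
                make_record(f"{sample}_skip_{lid}_{read_no}", chrom, p_start, cigar, sa)
            )
            read_no += 1

    boundaries = sorted(
        set(te_annotation["start"]).union(te_annotation["end"])
    )
    chroms = sorted(chrom_lengths)
    for i in range(design.noise_reads):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        for _ in range(1000):
            pos = int(rng.integers(100, chrom_lengths[chrom] - 2 * design.read_length))
            bp = pos + design.read_length // 2
            near = te_annotation[te_annotation["chrom"] == chrom]
            dists = np.concatenate(
                [np.abs(near["start"].to_numpy() - bp), np.abs(near["end"].to_numpy() - bp)]
            ) if len(near) else np.array([np.inf])
            if dists.min() > 25 + design.read_length:
                break
        half = design.read_length // 2
        cigar = f"{half}M{design.read_length - half}S"
        sa = f"{chrom},{bp + 200},+,{half}H{design.read_length - half}M,60,0;"
        records.append(make_record(f"{sample}_noise_{i}", chrom, pos, cigar, sa))
    return header, records


def write_sam(header: pysam.AlignmentHeader, records, path) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(rec)
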