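"""Dating ERV insertions from primate ortholog presence/absence.

Each human TE locus either has an orthologous insertion at the syntenic
position of another primate genome (it predates the divergence from that
species) or lacks one.  Ortholog detection is noisy and leaves many
missing values, so instead of dating loci one at a time the procedure
orders the loci by their position in a phylogeny of the subfamily (old to
young) and slides a window along that order: for each species, the
youngest window in which at least ``min_present`` of ``window`` loci have
an orthologous insertion marks the end of the era predating the
human/species divergence.  Loci older than that boundary are assigned to
branches of the primate tree (HCGOG > HCGO > HCG > HC > H, from the
hominoid common ancestor down to human-specific).

The module also carries the alignment/tree hygiene filters applied before
tree building: low-coverage alignment columns, gappy sequences, and
leaves with outlying external branch lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MSAFilterParams",
    "SPECIES_BY_DEPTH",
    "BRANCH_LABELS",
    "filter_msa",
    "detect_branch_outliers",
    "date_insertions",
    "assign_branches",
    "stratify_genes_by_date",
    "read_msa_fasta",
    "write_msa_fasta",
    "read_tree",
    "read_ortholog_table",
    "write_branch_table",
]

#: Species whose pre-divergence flags produce branch labels, ordered from
#: deepest divergence to shallowest.  Macaque and marmoset flags are
#: computed (they calibrate contamination by older subfamilies) but do
#: not yield labels beyond HCGOG.
SPECIES_BY_DEPTH = (
    ("gibbon", "HCGOG"),
    ("orangutan", "HCGO"),
    ("gorilla", "HCG"),
    ("chimpanzee", "HC"),
)

BRANCH_LABELS = ("HCGOG", "HCGO", "HCG", "HC", "H", "ND")


@dataclass(frozen=True)
class MSAFilterParams:
    min_site_coverage: float = 0.85
    max_seq_gap_fraction: float = 0.15
    outlier_z: float = 3.0

    def __post_init__(self) -> None:
        for f in (self.min_site_coverage, self.max_seq_gap_fraction):
            if not 0 < f <= 1:
                raise ValueError("filter fractions must lie in (0, 1]")


def filter_msa(
    msa: Mapping[str, str], params: MSAFilterParams = MSAFilterParams()
) -> dict[str, str]:
    """Two-step alignment cleanup: columns first, then sequences.

    First, alignment columns whose non-gap coverage is below
    ``min_site_coverage`` are removed.  Second, sequences with a gap
    fraction above ``max_seq_gap_fraction`` over the REMAINING columns are
    removed.  The step order is fixed: a sequence is judged only on the
    well-covered columns.
    """
    ids = list(msa)
    if not ids:
        raise ValueError("empty alignment")
    lengths = {len(msa[i]) for i in ids}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal aligned lengths")
    arr = np.array([list(msa[i]) for i in ids])
    gap = (arr == "-") | (arr == ".")
    coverage = 1.0 - gap.mean(axis=0)
    keep_cols = coverage >= params.min_site_coverage
    arr, gap = arr[:, keep_cols], gap[:, keep_cols]
    if arr.shape[1] == 0:
        raise ValueError("no alignment columns pass the coverage filter")
    seq_gap_frac = gap.mean(axis=1)
    keep_rows = seq_gap_frac <= params.max_seq_gap_fraction
    if not keep_rows.any():
        raise ValueError("no sequences pass the gap filter")
    return {
        ids[i]: "".join(arr[i]) for i in range(len(ids)) if keep_rows[i]
    }


def detect_branch_outliers(tree, z_threshold: float = 3.0) -> set[str]:
    """Leaves with standardized external branch length above the threshold.

    ``tree`` is a dendropy Tree with branch lengths.  External branch
    lengths are Z-standardized (sample SD); leaves with z > threshold are
    returned.  When all external branches are equal the SD is zero and no
    leaf is an outlier.  Removing outliers and re-running may reveal more;
    the filter is applied once.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("tree must have at least 3 leaves")
    lengths = np.array(
        [lf.edge.length if lf.edge.length is not None else 0.0 for lf in leaves]
    )
    sd = lengths.std(ddof=1)
    if sd == 0:
        return set()
    z = (lengths - lengths.mean()) / sd
    return {
        leaves[i].taxon.label for i in range(len(leaves)) if z[i] > z_threshold
    }


def date_insertions(
    order: Sequence[str],
    table: pd.DataFrame,
    window: int = 10,
    min_present: int = 4,
) -> tuple[dict[str, str | None], pd.DataFrame]:
    """Sliding-window pre-divergence flags per species.

    ``order`` lists locus ids from oldest to youngest; ``table`` is
    indexed by locus id with one column per species holding ``present`` /
    ``absent`` / ``missing``.  For each species, windows of ``window``
    consecutive loci are slid from old to young; a window qualifies when
    at least ``min_present`` of its loci are present (missing counts as
    not-present).  The boundary — the species' "final copy" — is the
    youngest locus actually PRESENT within the youngest qualifying
    window; loci strictly older than the boundary are flagged
    pre-divergence (the boundary locus itself is not).  Anchoring the
    boundary on a present locus rather than the window edge keeps the
    call exact on complete data: the window exists to ride over missing
    values, not to extend the pre-divergence era past the last observed
    ortholog.  With fewer loci than the window, the whole order is
    evaluated as one window.

    Returns ``(boundary per species, flags DataFrame loci x species)``.
    """
    order = list(order)
    missing = [l for l in order if l not in table.index]
    if missing:
        raise ValueError(f"ordered loci absent from table: {missing[:5]}")
    flags = pd.DataFrame(False, index=pd.Index(order, name="locus_id"), columns=table.columns)
    boundaries: dict[str, str | None] = {}
    n = len(order)
    w = min(window, n)
    for sp in table.columns:
        present = (table.loc[order, sp] == "present").to_numpy()
        cum = np.concatenate([[0], np.cumsum(present)])
        counts = cum[w:] - cum[:-w]  # counts[i] = presents in order[i:i+w]
        qualifying = np.nonzero(counts >= min_present)[0]
        if len(qualifying) == 0:
            boundaries[sp] = None
            continue
        win_start = qualifying[-1]
        in_window = np.nonzero(present[win_start : win_start + w])[0]
        boundary_idx = win_start + in_window[-1]  # youngest present locus
        boundaries[sp] = order[boundary_idx]
        flags.iloc[:boundary_idx, flags.columns.get_loc(sp)] = True
    return boundaries, flags


def assign_branches(flags: pd.DataFrame) -> pd.Series:
    """Map per-species pre-divergence flags to tree branch labels.

    The deepest species for which a locus predates the divergence wins:
    pre-gibbon -> HCGOG, else pre-orangutan -> HCGO, else pre-gorilla ->
    HCG, else pre-chimpanzee -> HC, else H.  A locus flagged for a deep
    species but not a shallower one is internally inconsistent; the
    deepest-true rule still applies and a warning is emitted.
    """
    labels = pd.Series("H", index=flags.index, dtype=object, name="branch")
    n_conflicts = 0
    species = [sp for sp, _ in SPECIES_BY_DEPTH if sp in flags.columns]
    for locus in flags.index:
        row = flags.loc[locus]
        assigned = None
        for sp, lab in SPECIES_BY_DEPTH:
            if sp in flags.columns and row[sp]:
                assigned = lab
                deeper_rank = [s for s, _ in SPECIES_BY_DEPTH].index(sp)
                shallower = [
                    s
                    for s, _ in SPECIES_BY_DEPTH[deeper_rank + 1 :]
                    if s in flags.columns and not row[s]
                ]
                if shallower:
                    n_conflicts += 1
                break
        if assigned:
            labels[locus] = assigned
    if n_conflicts:
        warnings.warn(
            f"{n_conflicts} loci had inconsistent species flags; "
            "resolved by the deepest pre-divergence species"
        )
    return labels


def stratify_genes_by_date(
    gene_to_loci: Mapping[str, Sequence[str]],
    locus_branches: Mapping[str, str] | pd.Series,
) -> pd.Series:
    """Propagate locus branch labels to their associated genes.

    A gene inherits the branch of its associated loci when they all agree;
    if any associated locus lacks a label (it was dropped from the tree)
    or the labels conflict, the gene is 'ND' (not determined).
    """
    branches = dict(locus_branches)
    out = {}
    for gene, loci in gene_to_loci.items():
        labs = {branches.get(l) for l in loci}
        if None in labs or len(labs) != 1:
            out[gene] = "ND"
        else:
            out[gene] = labs.pop()
    return pd.Series(out, dtype=object, name="branch").rename_axis("gene")


# ---------------------------------------------------------------------------
# IO


def read_msa_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA into an id -> aligned-sequence mapping."""
    from Bio import SeqIO

    msa = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not msa:
        raise ValueError(f"no sequences in {path}")
    return msa


def write_msa_fasta(msa: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in msa:
            fh.write(f">{name}\n{msa[name]}\n")


def read_tree(path):
    """Read a Newick tree (dendropy Tree, branch lengths preserved)."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


def read_ortholog_table(path) -> pd.DataFrame:
    """Read a locus x species TSV with values 1/0/NA into present/absent/missing."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    mapping = {"1": "present", "0": "absent", "NA": "missing", "": "missing"}
    return raw.apply(lambda col: col.map(lambda v: mapping.get(v, v)))


def write_branch_table(branches: pd.Series, path) -> None:
    branches.rename("branch").to_csv(path, sep="\t", index_label="locus_id")
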