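"""Expression-level analyses: normalization, TE subfamily aggregation,
cell-type-specificity scoring, upregulation classification and the
cross-species "likely regulated" gene call.

The central statistic is a cell-type-specificity score for each feature
(gene or TE subfamily).  A model profile ``m`` assigns each cell type a
weight in [0, 1]; a feature's observed profile ``d`` is built by
normalizing expression (log2[CP10k+1]), Z-scoring each feature across all
cells, averaging the Z scores per cell type, and min-max rescaling those
means to [0, 1].  The score is ``-log10(SSR)`` where SSR is the sum of
squared residuals between ``d`` and ``m``: features whose expression
tracks the model profile closely obtain high scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "SpecificityModel",
    "GERMLINE_CELL_TYPES",
    "PGCLC_MODEL",
    "SSR_FLOOR",
    "normalize_cp10k",
    "aggregate_te_subfamilies",
    "specificity_score",
    "differential_upregulation",
    "wald_differential_upregulation",
    "de_from_table",
    "classify_features",
    "compare_species",
]

#: Germ-cell induction series, in differentiation order.
GERMLINE_CELL_TYPES = ("iPSC", "iMeLC", "PGCLC", "MLC", "TC", "T1LC")

#: Floor applied to the SSR before the -log10 transform, so that a feature
#: matching the model profile exactly scores 12.0 instead of +inf.
SSR_FLOOR = 1e-12


@dataclass
class ExpressionMatrix:
    """Raw counts of features per cell, with per-cell metadata.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integers, features x cells.
    cell_meta
        DataFrame indexed by cell id with at least a ``cell_type`` column;
        an optional ``dataset`` column records the originating experiment.
    """

    counts: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids in counts matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate cell ids in counts matrix")
        if "cell_type" not in self.cell_meta.columns:
            raise ValueError("cell_meta must contain a 'cell_type' column")
        missing = self.counts.columns.difference(self.cell_meta.index)
        if len(missing):
            raise ValueError(f"cells missing from cell_meta: {list(missing)[:5]}")
        if "dataset" not in self.cell_meta.columns:
            self.cell_meta = self.cell_meta.assign(dataset="default")
        # align metadata to column order
        self.cell_meta = self.cell_meta.loc[self.counts.columns]

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns

    def cell_types(self) -> pd.Series:
        return self.cell_meta["cell_type"]

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        cells = list(cells)
        return ExpressionMatrix(self.counts[cells], self.cell_meta.loc[cells].copy())

    def write_tsv(self, counts_path, cells_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature")
        self.cell_meta.to_csv(cells_path, sep="\t", index_label="cell_id")

    @classmethod
    def read_tsv(cls, counts_path, cells_path) -> "ExpressionMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(cells_path, sep="\t", index_col=0)
        return cls(counts, meta)


@dataclass(frozen=True)
class SpecificityModel:
    """Model profile: one weight in [0, 1] per cell type.

    At least one weight must equal 1 so that the rescaled data profile and
    the model live on the same [0, 1] scale.
    """

    cell_types: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cell_types) != len(self.weights):
            raise ValueError("cell_types and weights must have equal length")
        w = np.asarray(self.weights, dtype=float)
        if np.any((w < 0) | (w > 1)):
            raise ValueError("model weights must lie in [0, 1]")
        if not np.any(w == 1.0):
            raise ValueError("at least one model weight must equal 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.cell_types), dtype=float)


#: PGCLC-specificity model over the germ-cell induction series:
#: iPSC:iMeLC:PGCLC:MLC:TC:T1LC = 0:0:1:0.5:0:0.  MLC retains half weight
#: because key germ-cell TFs stay weakly expressed in multiplying
#: prospermatogonia-like cells.
PGCLC_MODEL = SpecificityModel(GERMLINE_CELL_TYPES, (0.0, 0.0, 1.0, 0.5, 0.0, 0.0))


def normalize_cp10k(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts-per-10,000 normalization and its log2(x+1) transform.

    Cells with zero total counts are dropped with a warning.  Returns
    ``(cp10k, log_cp10k)``; each column of ``cp10k`` sums to 10,000.
    """
    if matrix.counts.size == 0:
        raise ValueError("empty expression matrix")
    totals = matrix.counts.sum(axis=0)
    zero = totals[totals == 0].index
    counts = matrix.counts
    if len(zero):
        warnings.warn(f"dropping {len(zero)} cells with zero total counts")
        counts = counts.drop(columns=zero)
        totals = totals.drop(zero)
        if counts.shape[1] == 0:
            raise ValueError("all cells have zero total counts")
    cp10k = counts.div(totals, axis=1) * 1e4
    log_cp10k = np.log2(cp10k + 1.0)
    return cp10k, log_cp10k


def aggregate_te_subfamilies(
    locus_matrix: ExpressionMatrix, locus_to_subfamily: Mapping[str, str] | pd.Series
) -> ExpressionMatrix:
    """Sum TE locus counts into subfamily-level counts per cell.

    Every locus in the matrix must map to exactly one subfamily; grand
    total counts are conserved.
    """
    mapping = pd.Series(dict(locus_to_subfamily)) if not isinstance(
        locus_to_subfamily, pd.Series
    ) else locus_to_subfamily
    missing = locus_matrix.features.difference(mapping.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} loci missing from annotation: {sorted(missing)[:10]}"
        )
    groups = mapping.loc[locus_matrix.features]
    agg = locus_matrix.counts.groupby(groups.values).sum()
    agg.index.name = "subfamily"
    return ExpressionMatrix(agg, locus_matrix.cell_meta.copy())


def specificity_score(
    matrix: ExpressionMatrix,
    model: SpecificityModel = PGCLC_MODEL,
    ssr_floor: float = SSR_FLOOR,
) -> pd.DataFrame:
    """Score each feature against a cell-type model profile.

    Pipeline: log2[CP10k+1] per cell -> per-feature Z score across all
    cells of the dataset being scored (population SD, ddof=0) -> mean Z
    per cell type -> min-max rescale of the means to [0, 1] -> SSR
    against the model weights -> score = -log10(max(SSR, ssr_floor)).

    Scoring is confined to the cells whose cell type appears in the
    model: when the matrix mixes datasets (e.g. a germline series plus
    an ESC comparison), cells outside the modelled series do not affect
    the Z standardization.

    Features with zero variance across cells, or whose per-cell-type means
    are all equal (rescaling undefined), are flagged rather than scored.

    Returns a DataFrame indexed by feature with columns ``ssr``,
    ``score`` and ``flag`` ('' | 'zero_variance' | 'degenerate_rescale').
    """
    types = matrix.cell_types()
    present = set(types.unique())
    absent = [t for t in model.cell_types if t not in present]
    if absent:
        raise ValueError(f"model cell types absent from matrix: {absent}")
    in_model = types.isin(model.cell_types)
    matrix = matrix.subset_cells(list(types.index[in_model]))
    types = matrix.cell_types()

    _, logx = normalize_cp10k(matrix)
    vals = logx.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    zero_var = sd[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mu) / sd

    cols = pd.Index(logx.columns)
    type_of = types.loc[cols]
    means = np.column_stack(
        [z[:, (type_of == ct).to_numpy()].mean(axis=1) for ct in model.cell_types]
    )
    lo = np.nanmin(means, axis=1)
    hi = np.nanmax(means, axis=1)
    degenerate = (hi == lo) & ~zero_var
    with np.errstate(invalid="ignore", divide="ignore"):
        rescaled = (means - lo[:, None]) / (hi - lo)[:, None]

    m = np.asarray(model.weights, dtype=float)
    ssr = np.nansum((rescaled - m) ** 2, axis=1)
    score = -np.log10(np.maximum(ssr, ssr_floor))

    flag = np.where(zero_var, "zero_variance", np.where(degenerate, "degenerate_rescale", ""))
    bad = flag != ""
    ssr = np.where(bad, np.nan, ssr)
    score = np.where(bad, np.nan, score)
    return pd.DataFrame(
        {"ssr": ssr, "score": score, "flag": flag}, index=logx.index
    ).rename_axis("feature")


def differential_upregulation(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_rpm_q90: float = 0.2,
) -> pd.DataFrame:
    """Differential upregulation of group A over group B (rank test).

    Features whose 90th percentile of reads-per-million across the pooled
    cells falls below ``min_rpm_q90`` are dropped before testing.  The
    fold change is computed on group means of CP10k with a pseudocount of
    one, the p value with a two-sample Wilcoxon rank-sum test on
    log2[CP10k+1], and the FDR with Benjamini-Hochberg.  This rank-based
    test is a stand-in for a negative-binomial Wald test; externally
    computed tables can be supplied verbatim via :func:`de_from_table`.

    Returns a DataFrame indexed by feature with columns ``log2fc``, ``p``,
    ``fdr``, ``mean_a``, ``mean_b`` (means of log2[CP10k+1] per group).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")

    sub = matrix.subset_cells(group_a + group_b)
    totals = sub.counts.sum(axis=0)
    keep_cells = totals[totals > 0].index
    sub = sub.subset_cells(list(keep_cells))
    rpm = sub.counts.div(sub.counts.sum(axis=0), axis=1) * 1e6
    q90 = rpm.quantile(0.9, axis=1)
    kept = q90[q90 >= min_rpm_q90].index
    if len(kept) == 0:
        raise ValueError("no features pass the expression filter")

    cp10k, logx = normalize_cp10k(sub)
    a_cols = [c for c in group_a if c in logx.columns]
    b_cols = [c for c in group_b if c in logx.columns]
    cp10k, logx = cp10k.loc[kept], logx.loc[kept]

    mean_a_cp = cp10k[a_cols].mean(axis=1)
    mean_b_cp = cp10k[b_cols].mean(axis=1)
    log2fc = np.log2(mean_a_cp + 1.0) - np.log2(mean_b_cp + 1.0)

    av = logx[a_cols].to_numpy()
    bv = logx[b_cols].to_numpy()
    # identical value vectors give p=1 directly; mannwhitneyu errors on them
    pvals = np.ones(len(kept))
    for i in range(len(kept)):
        pooled = np.concatenate([av[i], bv[i]])
        if np.all(pooled == pooled[0]):
            continue
        pvals[i] = stats.mannwhitneyu(av[i], bv[i], alternative="two-sided").pvalue
    fdr = multipletests(pvals, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "mean_a": logx[a_cols].mean(axis=1),
            "mean_b": logx[b_cols].mean(axis=1),
        },
        index=kept,
    ).rename_axis("feature")


def wald_differential_upregulation(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_rpm_q90: float = 0.2,
) -> pd.DataFrame:
    """Differential upregulation via a negative-binomial Wald test.

    The fidelity path for upregulation calling: counts are modelled with
    a negative-binomial GLM (DESeq2 model, via pydeseq2) with
    median-of-ratios size factors, so the log2 fold change is not biased
    toward zero for weakly expressed features the way the pseudocount
    fold change of :func:`differential_upregulation` is.  The same
    expression filter is applied first.  Returns the standard DE table
    (``log2fc``, ``p``, ``fdr``, ``mean_a``, ``mean_b``).
    """
    import logging

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")

    sub = matrix.subset_cells(group_a + group_b)
    totals = sub.counts.sum(axis=0)
    keep_cells = list(totals[totals > 0].index)
    sub = sub.subset_cells(keep_cells)
    rpm = sub.counts.div(sub.counts.sum(axis=0), axis=1) * 1e6
    kept = rpm.index[rpm.quantile(0.9, axis=1) >= min_rpm_q90]
    if len(kept) == 0:
        raise ValueError("no features pass the expression filter")

    a_cols = [c for c in group_a if c in sub.cells]
    b_cols = [c for c in group_b if c in sub.cells]
    counts = sub.counts.loc[kept, a_cols + b_cols].T
    meta = pd.DataFrame(
        {"condition": ["A"] * len(a_cols) + ["B"] * len(b_cols)}, index=counts.index
    )
    logging.getLogger("pydeseq2").setLevel(logging.ERROR)
    # poscounts size factors: the bulk median-of-ratios estimator discards
    # every gene with a zero count, which on sparse single-cell matrices
    # leaves only the highest-expressed genes and distorts the factors
    dds = DeseqDataSet(
        counts=counts,
        metadata=meta,
        design="~condition",
        refit_cooks=False,
        quiet=True,
        size_factors_fit_type="poscounts",
    )
    dds.deseq2()
    ds = DeseqStats(dds, contrast=["condition", "A", "B"], quiet=True)
    ds.summary()
    res = ds.results_df

    _, logx = normalize_cp10k(sub)
    logx = logx.loc[kept]
    return pd.DataFrame(
        {
            "log2fc": res["log2FoldChange"].reindex(kept),
            "p": res["pvalue"].reindex(kept).fillna(1.0),
            "fdr": res["padj"].reindex(kept).fillna(1.0),
            "mean_a": logx[a_cols].mean(axis=1),
            "mean_b": logx[b_cols].mean(axis=1),
        },
        index=kept,
    ).rename_axis("feature")


def de_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Adapter: accept an externally computed DE table verbatim.

    The table must be indexed by feature (or carry a ``feature`` column)
    and contain ``log2fc`` and ``fdr`` columns; extra columns pass through.
    """
    df = table.copy()
    if "feature" in df.columns:
        df = df.set_index("feature")
    required = {"log2fc", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"external DE table missing columns: {sorted(missing)}")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("FDR values outside [0, 1]")
    return df


def top_score_set(
    scores: pd.DataFrame, top_fraction: float = 0.10
) -> tuple[set, float]:
    """Features in the top fraction by specificity score, ties inclusive.

    The cutoff is the k-th highest score with ``k = floor(n * fraction)``
    (at least 1); every feature scoring >= the cutoff is included, so the
    realized fraction can exceed the nominal one under ties.  Returns
    ``(feature set, realized fraction)``.
    """
    scored = scores.loc[scores["flag"] == ""] if "flag" in scores.columns else scores
    s = scored["score"].dropna()
    if s.empty:
        raise ValueError("no scored features")
    k = max(1, int(np.floor(len(s) * top_fraction)))
    cutoff = s.sort_values(ascending=False).iloc[k - 1]
    top = set(s[s >= cutoff].index)
    return top, len(top) / len(s)


def classify_features(
    scores: pd.DataFrame,
    de: pd.DataFrame,
    top_fraction: float = 0.10,
    fc_thresh: float = 1.0,
    fdr_thresh: float = 0.05,
    overrides: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Classify features into both / pgclc_only / naive_only / other.

    A feature is "up in PGCLCs" if it lies in the top fraction of
    specificity scores (inclusive tie rule), and "up in naive cells" if
    its DE log2FC exceeds ``fc_thresh`` at FDR below ``fdr_thresh``.  The
    classification operates on the intersection of the scored and tested
    feature universes.  ``overrides`` maps feature id -> label for
    explicit manual reclassifications; they are applied last and recorded
    in the ``override`` column.
    """
    top, realized = top_score_set(scores, top_fraction)
    universe = scores.index[scores.get("flag", "").eq("")].intersection(de.index)
    if len(universe) == 0:
        raise ValueError("empty feature universe")

    naive_up = (de.loc[universe, "log2fc"] > fc_thresh) & (
        de.loc[universe, "fdr"] < fdr_thresh
    )
    pgclc_up = pd.Series([f in top for f in universe], index=universe)
    label = pd.Series("other", index=universe, dtype=object)
    label[pgclc_up & naive_up] = "both"
    label[pgclc_up & ~naive_up] = "pgclc_only"
    label[~pgclc_up & naive_up] = "naive_only"

    out = pd.DataFrame(
        {
            "label": label,
            "pgclc_up": pgclc_up,
            "naive_up": naive_up,
            "override": False,
        }
    ).rename_axis("feature")
    if overrides:
        valid = {"both", "pgclc_only", "naive_only", "other"}
        for feat, lab in overrides.items():
            if lab not in valid:
                raise ValueError(f"invalid override label {lab!r}")
            if feat in out.index:
                out.loc[feat, ["label", "override"]] = [lab, True]
    out.attrs["realized_top_fraction"] = realized
    return out


def compare_species(
    human_labels: pd.DataFrame,
    other_labels: pd.DataFrame,
    ortholog_map: Mapping[str, str],
    adjacency: Mapping[str, bool],
) -> dict:
    """Call genes likely regulated by lineage-specific TE insertions.

    A human gene qualifies when it is upregulated in both cell types in
    human, its one-to-one ortholog is NOT upregulated in both cell types
    in the other species, and the gene lies near an active TE locus.
    Only genes with ortholog information enter the comparison.

    Returns a dict with the ``likely_regulated`` gene set, the two
    both-upregulated sets restricted to the ortholog universe, and their
    intersection size.
    """
    omap = dict(ortholog_map)
    targets = list(omap.values())
    if len(set(targets)) != len(targets):
        dupes = pd.Series(targets).value_counts()
        raise ValueError(
            f"ortholog map is not one-to-one: {list(dupes[dupes > 1].index)[:5]}"
        )
    universe = [
        g for g, o in omap.items() if g in human_labels.index and o in other_labels.index
    ]
    both_human = {g for g in universe if human_labels.loc[g, "label"] == "both"}
    both_other = {
        g for g in universe if other_labels.loc[omap[g], "label"] == "both"
    }
    likely = {
        g for g in both_human if g not in both_other and bool(adjacency.get(g, False))
    }
    return {
        "universe": set(universe),
        "both_human": both_human,
        "both_other_orthologs": both_other,
        "n_shared_both": len(both_human & both_other),
        "likely_regulated": likely,
    }
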