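"""Interval enrichment statistics.

Three complementary tests quantify how a set of genomic regions (peaks,
TF-binding sites) relates to annotated TE loci or genes:

* a genomic permutation test — regions are relocated uniformly at random
  (length-preserving) across the genome; the mean overlap count over the
  permutations serves as the rate lambda of a Poisson distribution from
  which an upper-tail p value for the observed count is drawn;
* a proximity (GREAT-scheme) binomial test — peak counts inside merged
  windows around the TSSs of genes of interest versus background windows,
  with fold = (Ci/Cb)/(Li/Lb) and p = P(X >= Ci | n=Cb, p=Li/Lb);
* Fisher's exact test on 2x2 tables of region category x site overlap.

The module also defines "active" TE loci (transcribed or peak-overlapping),
gene-to-locus proximity, and the combined criteria that call a TF a
candidate regulator of a TE subfamily.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, top_score_set
from .intervals import (
    OverlapIndex,
    merge_intervals,
    overlap_flags,
    total_length,
    point_interval_distance,
)

__all__ = [
    "EnrichmentResult",
    "GreatResult",
    "shuffle_regions",
    "permutation_enrichment",
    "great_enrichment",
    "fisher_category_enrichment",
    "define_active_loci",
    "genes_near_loci",
    "identify_regulators",
]


@dataclass
class EnrichmentResult:
    query: str
    observed: int
    expected: float  # mean overlap count over permutations (Poisson rate)
    fold: float
    p: float
    n_events: int
    fold_is_lower_bound: bool = False  # True when lambda had to be floored


@dataclass
class GreatResult:
    ci: int  # peaks in regions of interest
    cb: int  # peaks in background regions
    li: int  # merged length of regions of interest (bp)
    lb: int  # merged length of background regions (bp)
    fold: float
    p: float


def shuffle_regions(
    regions: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Relocate each region uniformly at random, preserving its length.

    Chromosomes are drawn with probability proportional to length;
    relocated regions may overlap each other and never straddle a
    chromosome end.
    """
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    sizes = (regions["end"] - regions["start"]).to_numpy()
    if sizes.max() > lens.max():
        raise ValueError("a region is longer than every chromosome")
    choice = rng.choice(len(chroms), size=len(sizes), p=probs)
    # redraw chromosomes too short for the region (rare unless lengths vary a lot)
    for _ in range(1000):
        bad = sizes > lens[choice]
        if not bad.any():
            break
        choice[bad] = rng.choice(len(chroms), size=int(bad.sum()), p=probs)
    else:
        raise RuntimeError("could not place all regions after 1000 redraws")
    span = lens[choice] - sizes
    starts = np.floor(rng.random(len(sizes)) * (span + 1)).astype(np.int64)
    return pd.DataFrame(
        {
            "chrom": [chroms[i] for i in choice],
            "start": starts,
            "end": starts + sizes,
        }
    )


def permutation_enrichment(
    regions: pd.DataFrame,
    targets_by_query: Mapping[str, pd.DataFrame],
    chrom_lengths: Mapping[str, int],
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Permutation-based overlap enrichment of regions on target loci.

    For each query (e.g. TE subfamily) the observed number of regions
    overlapping any target locus is compared with the mean count over
    ``n_perm`` length-preserving uniform shuffles of the regions.  The
    mean serves as the Poisson rate; p = P(X >= observed).  A zero rate is
    floored at 1/n_perm (flagged in ``fold_is_lower_bound``).  FDR is
    Benjamini-Hochberg across queries.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    queries = list(targets_by_query)
    indexes = {q: OverlapIndex(targets_by_query[q]) for q in queries}

    def count_all(regs: pd.DataFrame) -> dict[str, int]:
        out = {}
        for q in queries:
            idx = indexes[q]
            n = 0
            for chrom, grp in regs.groupby("chrom"):
                n += int(
                    idx.overlaps_any(
                        chrom, grp["start"].to_numpy(), grp["end"].to_numpy()
                    ).sum()
                )
            out[q] = n
        return out

    observed = count_all(regions)
    perm_counts = {q: np.empty(n_perm) for q in queries}
    for i in range(n_perm):
        shuffled = shuffle_regions(regions, chrom_lengths, rng)
        c = count_all(shuffled)
        for q in queries:
            perm_counts[q][i] = c[q]

    rows = []
    for q in queries:
        lam = float(perm_counts[q].mean())
        floored = lam == 0
        lam_eff = max(lam, 1.0 / n_perm)
        if floored:
            warnings.warn(f"zero permutation overlaps for {q}; rate floored")
        obs = observed[q]
        fold = obs / lam_eff
        p = float(stats.poisson.sf(obs - 1, lam_eff)) if obs > 0 else 1.0
        rows.append(
            {
                "query": q,
                "observed": obs,
                "expected": lam,
                "fold": fold,
                "p": p,
                "n_events": obs,
                "fold_is_lower_bound": floored,
            }
        )
    df = pd.DataFrame(rows).set_index("query")
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    return df


def _tss_windows(
    tss: pd.DataFrame, window: int, chrom_lengths: Mapping[str, int] | None
) -> pd.DataFrame:
    # symmetric extension [pos-w, pos+w), the bedtools-style construction
    start = np.maximum(tss["pos"].to_numpy() - window, 0)
    end = tss["pos"].to_numpy() + window
    if chrom_lengths is not None:
        caps = tss["chrom"].map(chrom_lengths).to_numpy()
        end = np.minimum(end, caps)
    df = pd.DataFrame({"chrom": tss["chrom"].to_numpy(), "start": start, "end": end})
    return merge_intervals(df[df["start"] < df["end"]])


def great_enrichment(
    peaks: pd.DataFrame,
    interest_tss: pd.DataFrame,
    background_tss: pd.DataFrame,
    window: int = 50_000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> GreatResult:
    """Proximity enrichment of peaks near genes of interest (binomial).

    Windows of +/- ``window`` bp around each TSS are merged within the
    interest and background sets; Li/Lb are the merged lengths and Ci/Cb
    the numbers of peaks overlapping each merged set (a peak is counted
    once per set).  fold = (Ci/Cb)/(Li/Lb); p = P(X >= Ci | n=Cb, Li/Lb).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    wi = _tss_windows(interest_tss, window, chrom_lengths)
    wb = _tss_windows(background_tss, window, chrom_lengths)
    li, lb = total_length(wi), total_length(wb)
    ci = int(overlap_flags(peaks, wi).sum()) if len(wi) else 0
    cb = int(overlap_flags(peaks, wb).sum()) if len(wb) else 0
    if li == 0 or lb == 0:
        warnings.warn("zero-length regions of interest; fold/p undefined")
        return GreatResult(ci, cb, li, lb, float("nan"), float("nan"))
    if cb == 0:
        raise ValueError("no peaks in background regions")
    frac = li / lb
    fold = (ci / cb) / frac
    p = float(stats.binom.sf(ci - 1, cb, frac)) if ci > 0 else 1.0
    return GreatResult(ci, cb, li, lb, fold, p)


def fisher_category_enrichment(
    regions: pd.DataFrame,
    categories: pd.Series,
    site_sets: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Fisher's exact test of (region in category) x (region overlaps sites).

    ``categories`` assigns every region a category label (a partition of
    the region universe).  For each (category, site set) pair a 2x2 table
    is built over all regions; odds ratio = ad/bc, two-tailed p, and BH
    FDR across site sets within each category.  Degenerate tables (empty
    category, category covering the whole universe) yield NA rows.
    """
    if not categories.index.equals(regions.index):
        categories = categories.reindex(regions.index)
    rows = []
    overlap_by_set = {
        name: overlap_flags(regions, sites) for name, sites in site_sets.items()
    }
    for cat in pd.unique(categories.dropna()):
        in_cat = (categories == cat).to_numpy()
        for name, hits in overlap_by_set.items():
            h = hits.to_numpy()
            a = int((in_cat & h).sum())
            b = int((in_cat & ~h).sum())
            c = int((~in_cat & h).sum())
            d = int((~in_cat & ~h).sum())
            if a + b == 0 or c + d == 0:
                warnings.warn(f"degenerate table for category {cat!r} vs {name!r}")
                rows.append((cat, name, a, np.nan, np.nan))
                continue
            if b * c == 0:
                odds = np.inf if a * d > 0 else (0.0 if a == 0 else np.nan)
            else:
                odds = (a * d) / (b * c)
            p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            rows.append((cat, name, a, odds, p))
    df = pd.DataFrame(rows, columns=["category", "site_set", "overlap", "odds_ratio", "p"])
    df["fdr"] = np.nan
    for cat in df["category"].unique():
        sel = (df["category"] == cat) & df["p"].notna()
        if sel.any():
            df.loc[sel, "fdr"] = multipletests(df.loc[sel, "p"], method="fdr_bh")[1]
    return df


def define_active_loci(
    te_loci: pd.DataFrame,
    expression_datasets: Mapping[str, ExpressionMatrix] | None = None,
    peak_sets: Mapping[str, pd.DataFrame] | None = None,
    detection_fraction: float = 0.005,
) -> pd.DataFrame:
    """Flag TE loci with transcriptomic or epigenetic activity.

    A locus is active when its expression is detected (count > 0) in
    strictly more than ``detection_fraction`` of cells in ANY expression
    dataset, OR when it overlaps a peak in ANY provided peak set.
    ``te_loci`` must carry a ``locus_id`` column.  Per-source provenance
    flags are retained in the output.
    """
    out = pd.DataFrame(index=pd.Index(te_loci["locus_id"], name="locus_id"))
    for name, mat in (expression_datasets or {}).items():
        frac = (mat.counts > 0).mean(axis=1)
        col = frac.reindex(out.index).fillna(0.0) > detection_fraction
        out[f"expressed_{name}"] = col.to_numpy()
    for name, peaks in (peak_sets or {}).items():
        flags = overlap_flags(te_loci, peaks)
        out[f"peak_{name}"] = flags.to_numpy()
    out["active"] = out.any(axis=1) if out.shape[1] else False
    return out


def genes_near_loci(
    tss_table: pd.DataFrame,
    active_loci: pd.DataFrame,
    distance: int = 50_000,
) -> pd.DataFrame:
    """Per-gene minimum TSS distance to the nearest active locus.

    ``tss_table`` holds one row per transcript TSS (``gene``, ``chrom``,
    ``pos``); the gene-level distance is the minimum over its TSSs, 0 for
    a TSS inside a locus.  A gene is adjacent iff min distance <= the
    threshold (inclusive).  Genes without any TSS row are absent from the
    output (they are dropped upstream with a warning by the GTF reader).
    """
    if tss_table.empty:
        raise ValueError("empty TSS table")
    loci = active_loci.reset_index(drop=True)
    res = point_interval_distance(tss_table[["chrom", "pos"]], loci)
    per_tss = tss_table[["gene"]].assign(
        distance=res["distance"].to_numpy(), nearest=res["nearest"].to_numpy()
    )
    idx = per_tss.groupby("gene")["distance"].idxmin()
    best = per_tss.loc[idx].set_index("gene")
    locus_ids = loci["locus_id"] if "locus_id" in loci.columns else loci.index.to_series()
    best["nearest_locus"] = [
        locus_ids.iloc[i] if i >= 0 else None for i in best["nearest"]
    ]
    best["adjacent"] = best["distance"] <= distance
    return best[["adjacent", "distance", "nearest_locus"]].rename_axis("gene")


def identify_regulators(
    tf_sites: Mapping[str, pd.DataFrame],
    te_loci: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    scores: pd.DataFrame,
    de_table: pd.DataFrame,
    mean_expression: pd.DataFrame,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
    min_log2_fold: float = 2.0,
    max_fdr: float = 0.05,
    min_events: int = 21,
    top_fraction: float = 0.10,
    min_mean_expression: float = 0.4,
    naive_min_log2fc: float = 2.0,
) -> pd.DataFrame:
    """Call TFs that likely regulate a TE subfamily in each cell state.

    Per TF, the permutation test measures enrichment of its binding sites
    on the TE loci.  A TF is a candidate regulator when the enrichment is
    strong (log2 fold > ``min_log2_fold``, FDR < ``max_fdr``, binding
    events >= ``min_events``) AND the TF is specifically expressed:
    in PGCLCs, top-fraction specificity score with mean log2[CP10k+1]
    above ``min_mean_expression``; in naive cells, DE log2FC >
    ``naive_min_log2fc`` at FDR < 0.05 with the same mean floor.

    ``mean_expression`` is indexed by TF with columns ``pgclc`` and
    ``naive`` (mean log2[CP10k+1] in the respective cell type).
    """
    enr_rows = []
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    for tf, sites in tf_sites.items():
        res = permutation_enrichment(
            sites, {"te": te_loci}, chrom_lengths, n_perm=n_perm, seed=rng
        ).loc["te"]
        enr_rows.append(
            {
                "tf": tf,
                "observed": res["observed"],
                "expected": res["expected"],
                "fold": res["fold"],
                "p": res["p"],
                "n_events": res["n_events"],
            }
        )
    enr = pd.DataFrame(enr_rows).set_index("tf")
    enr["fdr"] = multipletests(enr["p"], method="fdr_bh")[1] if len(enr) else []

    top, _ = top_score_set(scores, top_fraction)
    with np.errstate(divide="ignore"):
        log2fold = np.log2(enr["fold"].to_numpy())
    enriched = (
        (log2fold > min_log2_fold)
        & (enr["fdr"] < max_fdr)
        & (enr["n_events"] >= min_events)
    )
    out = enr.assign(log2_fold=log2fold, enriched=enriched)
    reg_pgclc, reg_naive = [], []
    for tf in out.index:
        if tf not in mean_expression.index:
            warnings.warn(f"TF {tf} absent from expression table")
            reg_pgclc.append(None)
            reg_naive.append(None)
            continue
        mean_p = mean_expression.loc[tf, "pgclc"]
        mean_n = mean_expression.loc[tf, "naive"]
        is_enr = bool(out.loc[tf, "enriched"])
        reg_pgclc.append(
            is_enr and tf in top and mean_p > min_mean_expression
        )
        naive_up = (
            tf in de_table.index
            and de_table.loc[tf, "log2fc"] > naive_min_log2fc
            and de_table.loc[tf, "fdr"] < 0.05
        )
        reg_naive.append(is_enr and naive_up and mean_n > min_mean_expression)
    out["regulator_pgclc"] = reg_pgclc
    out["regulator_naive"] = reg_naive
    return out
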