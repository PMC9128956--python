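"""End-to-end orchestration of the synthetic analysis run.

Stages mirror the analysis flow: simulate inputs -> normalize and score
expression -> classify genes -> interval enrichment -> regulator calling
-> proximity genes -> cross-species comparison -> insertion dating ->
polymorphism calling -> gene-set enrichment -> report.  A single seed is
expanded into independent per-stage streams so that skipping one stage
does not shift another stage's randomness, and a rerun with the same
configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (
    PGCLC_MODEL,
    classify_features,
    compare_species,
    de_from_table,
    differential_upregulation,
    normalize_cp10k,
    specificity_score,
    wald_differential_upregulation,
)
from .gene_sets import GeneSetCollection, enrich_gene_sets, prune_redundant
from .genomic_enrichment import (
    define_active_loci,
    fisher_category_enrichment,
    genes_near_loci,
    great_enrichment,
    identify_regulators,
    permutation_enrichment,
)
from .insertion_dating import assign_branches, date_insertions, stratify_genes_by_date
from .polymorphism import (
    call_absent_alleles,
    count_skipping_reads,
    extract_candidates,
    summarize_cohort,
)
from .synthetic_data import (
    ExpressionDesign,
    ExpressionMatrix,
    GenomeDesign,
    HistoryDesign,
    ReadSimDesign,
    simulate_alignments,
    simulate_expression,
    simulate_genome,
    simulate_ortholog_history,
)

__all__ = ["PipelineConfig", "RunReport", "run_all"]

log = logging.getLogger("ervregnet")

STAGES = (
    "expression",
    "classification",
    "enrichment",
    "regulators",
    "proximity",
    "species_comparison",
    "dating",
    "polymorphism",
    "gene_sets",
)


@dataclass
class PipelineConfig:
    """Thresholds and simulation designs for a full synthetic run.

    All thresholds default to the study values: top 10% specificity
    scores, log2FC 1 / FDR 0.05 upregulation, 50 kb proximity, 100
    permutations, dating window 10 with >3 present, 25 nt junction
    tolerance, 2 skipping reads, Jaccard 0.5, and 0.5% detection.
    """

    seed: int = 0
    output_dir: str = "ervregnet_run"
    top_fraction: float = 0.10
    fc_thresh: float = 1.0
    fdr_thresh: float = 0.05
    window_distance: int = 50_000
    n_perm: int = 100
    dating_window: int = 10
    dating_min_present: int = 4
    tolerance: int = 25
    min_reads: int = 2
    jaccard: float = 0.5
    detection_fraction: float = 0.005
    manual_overrides: dict = field(default_factory=dict)
    # simulation sizes
    n_cells_per_type: int = 200
    n_genes_per_class: dict = field(
        default_factory=lambda: {
            "both_up": 100,
            "pgclc_only": 100,
            "naive_only": 100,
            "null": 1700,
        }
    )
    effect_size: float = 4.0
    conserved_fraction: float = 0.5  # fraction of both_up genes also up in species 2
    n_history_missing_rate: float = 0.2
    n_samples: int = 10
    n_absent_loci: int = 5
    external_de_table: str | None = None
    de_method: str = "wald"  # "wald" (NB GLM) or "rank" (Wilcoxon stand-in)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        classes = data.get("n_genes_per_class")
        if isinstance(classes, dict) and None in classes:
            # YAML parses a bare `null` key as None
            classes["null"] = classes.pop(None)
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        for name in ("fdr_thresh", "detection_fraction", "conserved_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_perm < 1 or self.dating_window < 1 or self.min_reads < 0:
            raise ValueError("invalid threshold configuration")
        if self.de_method not in ("wald", "rank"):
            raise ValueError("de_method must be 'wald' or 'rank'")


@dataclass
class RunReport:
    """Per-stage tables plus provenance for one pipeline run."""

    tables: dict[str, pd.DataFrame]
    summary: dict
    output_dir: Path


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t")
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> RunReport:
    """Execute every stage on synthetic inputs and write all tables."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {
        "config": {k: v for k, v in asdict(config).items()},
        "version": __version__,
        "stages": {},
    }
    streams = np.random.SeedSequence(config.seed).spawn(len(STAGES))
    seeds = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in zip(STAGES, streams)}
    t0 = time.time()

    def stage_done(name: str, **info):
        summary["stages"][name] = {"seconds": round(time.time() - t0, 2), **info}
        log.info("stage %s done (%.1fs)", name, time.time() - t0)

    # --- expression: simulate, score, DE -----------------------------------
    design = ExpressionDesign(
        n_cells_per_type={ct: config.n_cells_per_type for ct in ExpressionDesign().cell_types},
        n_genes_per_class=dict(config.n_genes_per_class),
        effect_size=config.effect_size,
        seed=seeds["expression"],
    )
    matrix, truth = simulate_expression(design)
    scores = specificity_score(matrix, PGCLC_MODEL)
    meta = matrix.cell_meta
    naive = list(meta.index[meta["cell_type"] == "naiveESC"])
    primed = list(meta.index[meta["cell_type"] == "primedESC"])
    if config.external_de_table:
        de = de_from_table(pd.read_csv(config.external_de_table, sep="\t"))
    elif config.de_method == "wald":
        de = wald_differential_upregulation(matrix, naive, primed)
    else:
        de = differential_upregulation(matrix, naive, primed)
    tables["scores"] = scores
    tables["de"] = de
    tables["truth_genes"] = truth
    stage_done("expression", n_cells=int(matrix.counts.shape[1]),
               n_genes=int(matrix.counts.shape[0]),
               external_de=bool(config.external_de_table))

    # --- classification -----------------------------------------------------
    labels = classify_features(
        scores, de, config.top_fraction, config.fc_thresh, config.fdr_thresh,
        overrides=config.manual_overrides,
    )
    tables["labels"] = labels
    counts = labels["label"].value_counts().to_dict()
    both_truth = truth.index[truth["gene_class"] == "both_up"]
    both_called = labels.index[labels["label"] == "both"]
    recovery = len(set(both_truth) & set(both_called)) / max(len(both_truth), 1)
    stage_done("classification", label_counts=counts,
               both_recovery=round(recovery, 4),
               realized_top_fraction=round(labels.attrs["realized_top_fraction"], 4))

    # --- genome + interval enrichment ---------------------------------------
    gdesign = GenomeDesign(seed=seeds["enrichment"])
    te, peak_sets, tss = simulate_genome(gdesign)
    targets = {
        sub: grp[["chrom", "start", "end"]].reset_index(drop=True)
        for sub, grp in te.groupby("subfamily")
    }
    perm = permutation_enrichment(
        peak_sets["both"], targets, gdesign.chrom_lengths,
        n_perm=config.n_perm, seed=seeds["enrichment"],
    )
    tables["permutation_enrichment"] = perm
    # proximity enrichment of peaks near a planted gene-of-interest subset
    interest = tss.iloc[: max(len(tss) // 5, 1)]
    great = great_enrichment(
        peak_sets["both"], interest, tss, window=config.window_distance,
        chrom_lengths=gdesign.chrom_lengths,
    )
    all_peaks = pd.concat(
        [p.assign(category=cat) for cat, p in peak_sets.items()], ignore_index=True
    )
    fisher = fisher_category_enrichment(
        all_peaks[["chrom", "start", "end"]],
        all_peaks["category"],
        {"target_te": targets[gdesign.target_subfamily]},
    )
    tables["fisher_enrichment"] = fisher
    tables["great_enrichment"] = pd.DataFrame([vars(great)])
    stage_done("enrichment",
               target_fold=round(float(perm.loc[gdesign.target_subfamily, "fold"]), 3),
               great_fold=None if np.isnan(great.fold) else round(great.fold, 3))

    # --- regulators ----------------------------------------------------------
    rng = np.random.default_rng(seeds["regulators"])
    target_loci = targets[gdesign.target_subfamily]
    planted_tf, null_tf = "both_up_0000", "null_0000"
    on = target_loci.sample(n=min(40, len(target_loci)), random_state=rng.integers(2**31))
    tf_sites = {
        planted_tf: pd.DataFrame(
            {
                "chrom": on["chrom"].to_numpy(),
                "start": on["start"].to_numpy(),
                "end": (on["start"] + 200).to_numpy(),
            }
        ),
        null_tf: pd.DataFrame(
            {
                "chrom": ["chr1"] * 40,
                "start": (s := np.sort(rng.integers(0, 1_900_000, 40))),
                "end": s + 200,
            }
        ),
    }
    _, logx = normalize_cp10k(matrix)
    types = matrix.cell_types()
    mean_expr = pd.DataFrame(
        {
            "pgclc": logx.loc[:, types == "PGCLC"].mean(axis=1),
            "naive": logx.loc[:, types == "naiveESC"].mean(axis=1),
        }
    )
    regulators = identify_regulators(
        tf_sites, target_loci, gdesign.chrom_lengths, scores, de, mean_expr,
        n_perm=config.n_perm, seed=seeds["regulators"],
    )
    tables["regulators"] = regulators
    stage_done("regulators",
               called_pgclc=[t for t in regulators.index if regulators.loc[t, "regulator_pgclc"]])

    # --- active loci + proximity genes --------------------------------------
    rng_act = np.random.default_rng(seeds["proximity"])
    te_lt = te[te["subfamily"] == gdesign.target_subfamily].reset_index(drop=True)
    n_cells_expr = 400
    frac_detected = np.where(rng_act.random(len(te_lt)) < 0.6, 0.02, 0.0)
    locus_counts = pd.DataFrame(
        rng_act.binomial(1, frac_detected[:, None], size=(len(te_lt), n_cells_expr)),
        index=pd.Index(te_lt["locus_id"], name="feature"),
        columns=[f"c{i}" for i in range(n_cells_expr)],
    )
    locus_meta = pd.DataFrame(
        {"cell_type": "PGCLC", "dataset": "sim"},
        index=pd.Index(locus_counts.columns, name="cell_id"),
    )
    locus_matrix = ExpressionMatrix(locus_counts, locus_meta)
    active = define_active_loci(
        te_lt, {"pgclc": locus_matrix}, {"both": peak_sets["both"]},
        detection_fraction=config.detection_fraction,
    )
    active_loci = te_lt[active["active"].to_numpy()].reset_index(drop=True)
    # map simulated genes onto genomic TSSs so labels and intervals connect
    gene_ids = list(truth.index[: len(tss)])
    tss_named = tss.iloc[: len(gene_ids)].assign(gene=gene_ids)
    proximity = genes_near_loci(tss_named, active_loci, distance=config.window_distance)
    tables["active_loci"] = active
    tables["proximity"] = proximity
    stage_done("proximity", n_active=int(active["active"].sum()),
               n_adjacent=int(proximity["adjacent"].sum()))

    # --- cross-species comparison -------------------------------------------
    sp2_classes = truth["gene_class"].copy()
    both_genes = list(truth.index[truth["gene_class"] == "both_up"])
    n_cons = int(round(config.conserved_fraction * len(both_genes)))
    lineage_specific = both_genes[n_cons:]
    sp2_classes.loc[lineage_specific] = "null"
    sp2_design = ExpressionDesign(
        n_cells_per_type=design.n_cells_per_type,
        n_genes_per_class=design.n_genes_per_class,
        effect_size=design.effect_size,
        seed=seeds["species_comparison"],
    )
    sp2_matrix, sp2_truth = simulate_expression(sp2_design, gene_classes=sp2_classes)
    sp2_scores = specificity_score(sp2_matrix, PGCLC_MODEL)
    sp2_meta = sp2_matrix.cell_meta
    sp2_de_fn = (
        wald_differential_upregulation
        if config.de_method == "wald"
        else differential_upregulation
    )
    sp2_de = sp2_de_fn(
        sp2_matrix,
        list(sp2_meta.index[sp2_meta["cell_type"] == "naiveESC"]),
        list(sp2_meta.index[sp2_meta["cell_type"] == "primedESC"]),
    )
    sp2_labels = classify_features(
        sp2_scores, sp2_de, config.top_fraction, config.fc_thresh, config.fdr_thresh
    )
    ortholog_map = {g: g for g in truth.index}
    adjacency = {
        g: bool(proximity.loc[g, "adjacent"]) if g in proximity.index else False
        for g in truth.index
    }
    comparison = compare_species(labels, sp2_labels, ortholog_map, adjacency)
    tables["species2_labels"] = sp2_labels
    likely = sorted(comparison["likely_regulated"])
    tables["likely_regulated"] = pd.DataFrame(
        {"gene": likely}
    ).set_index("gene")
    stage_done("species_comparison",
               n_both_human=len(comparison["both_human"]),
               n_shared_both=comparison["n_shared_both"],
               n_likely_regulated=len(likely))

    # --- insertion dating ----------------------------------------------------
    hdesign = HistoryDesign(
        n_loci=len(te_lt),
        missing_rate=config.n_history_missing_rate,
        seed=seeds["dating"],
    )
    order, otable, branch_truth = simulate_ortholog_history(hdesign)
    boundaries, flags = date_insertions(
        order, otable, window=config.dating_window, min_present=config.dating_min_present
    )
    branches = assign_branches(flags)
    # history locus i corresponds to the i-th target-subfamily locus
    id_map = dict(zip(order, te_lt["locus_id"]))
    locus_branches = {id_map[l]: b for l, b in branches.items()}
    gene_to_loci = {
        g: [proximity.loc[g, "nearest_locus"]]
        for g in likely
        if g in proximity.index and proximity.loc[g, "nearest_locus"] is not None
    }
    gene_branches = stratify_genes_by_date(gene_to_loci, locus_branches)
    tables["locus_branches"] = branches.to_frame()
    tables["gene_branches"] = gene_branches.to_frame()
    hist = gene_branches.value_counts().to_dict() if len(gene_branches) else {}
    stage_done("dating", boundaries={k: v for k, v in boundaries.items()},
               branch_histogram={k: int(v) for k, v in hist.items()})

    # --- polymorphism --------------------------------------------------------
    rng_poly = np.random.default_rng(seeds["polymorphism"])
    absent = tuple(
        te_lt["locus_id"].iloc[
            rng_poly.choice(len(te_lt), size=min(config.n_absent_loci, len(te_lt)), replace=False)
        ]
    )
    counts_by_sample = {}
    for s in range(config.n_samples):
        sample = f"sample{s:02d}"
        has_absence = s < config.n_samples // 2
        rdesign = ReadSimDesign(
            n_loci=len(te_lt),
            absent_loci=absent if has_absence else (),
            reads_per_junction=4,
            noise_reads=20,
            seed=int(rng_poly.integers(2**31)),
        )
        _, records = simulate_alignments(rdesign, te_lt, gdesign.chrom_lengths, sample)
        cands, _ = extract_candidates(records)
        counts_by_sample[sample] = count_skipping_reads(cands, te_lt, config.tolerance)
    calls = call_absent_alleles(counts_by_sample, config.min_reads)
    cohort = summarize_cohort(calls)
    tables["polymorphism_calls"] = calls.set_index(["locus_id", "sample"])
    tables["polymorphism_cohort"] = cohort
    called = set(cohort.index[cohort["n_samples_lacking"] > 0])
    stage_done("polymorphism", n_polymorphic=len(called),
               planted_recovered=sorted(called) == sorted(absent))

    # --- gene sets -----------------------------------------------------------
    rng_gs = np.random.default_rng(seeds["gene_sets"])
    universe = set(truth.index)
    sets = {"planted_both_signature": set(both_genes[: len(both_genes) // 2])}
    gene_list = sorted(universe)
    for i in range(8):
        members = rng_gs.choice(gene_list, size=40, replace=False)
        sets[f"random_set_{i}"] = set(members)
    sets["planted_both_signature_copy"] = set(both_genes[: len(both_genes) // 2 + 2])
    collection = GeneSetCollection(sets, universe)
    enr = enrich_gene_sets(set(both_called), collection)
    pruned = prune_redundant(enr, collection, jaccard_threshold=config.jaccard,
                             fdr_threshold=config.fdr_thresh)
    tables["gene_set_enrichment"] = enr
    tables["gene_set_pruned"] = pruned
    stage_done("gene_sets", n_significant=int((enr["fdr"] < config.fdr_thresh).sum()),
               n_after_pruning=len(pruned))

    # --- write everything ----------------------------------------------------
    hashes = {}
    for name, df in tables.items():
        hashes[name] = _write(df, out / f"{name}.tsv")
    summary["table_hashes"] = hashes
    summary["seeds"] = seeds
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return RunReport(tables=tables, summary=summary, output_dir=out)
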