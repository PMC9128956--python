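"""Gene-set over-representation with redundancy pruning.

Overlap of a query gene list with each named gene set is tested against a
declared background universe by a one-tailed Fisher's exact test
(equivalently the hypergeometric upper tail), with Benjamini-Hochberg
correction across the collection.  Because curated collections contain
near-duplicate sets, significant results are pruned greedily: rows are
ranked by odds ratio and a set is dropped when its membership overlaps an
already-kept set with Jaccard index strictly above a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "enrich_gene_sets",
    "prune_redundant",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested on.

    Sets are intersected with the universe on construction; sets that
    become empty are dropped with a warning.
    """

    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        trimmed = {}
        empty = []
        for name, members in self.sets.items():
            inter = set(members) & self.universe
            if inter:
                trimmed[name] = inter
            else:
                empty.append(name)
        if empty:
            warnings.warn(f"dropped {len(empty)} sets with no members in the universe")
        self.sets = trimmed


def enrich_gene_sets(query: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """One-tailed Fisher enrichment of the query against each gene set.

    Query genes outside the universe are dropped (reported by warning).
    For each set, the 2x2 table of (in query) x (in set) over the universe
    is tested for enrichment; p equals the hypergeometric upper tail.
    Returns a DataFrame indexed by set name with ``overlap``,
    ``odds_ratio``, ``p``, ``fdr`` and the ``hits`` gene list.
    """
    if not collection.universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - collection.universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe were dropped")
        query &= collection.universe
    n_universe = len(collection.universe)
    rows = []
    for name, members in collection.sets.items():
        hits = sorted(query & members)
        a = len(hits)
        b = len(query) - a
        c = len(members) - a
        d = n_universe - a - b - c
        if b * c == 0:
            odds = np.inf if a * d > 0 else (0.0 if a == 0 else np.nan)
        else:
            odds = (a * d) / (b * c)
        p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        rows.append((name, a, odds, p, ",".join(hits)))
    df = pd.DataFrame(
        rows, columns=["set", "overlap", "odds_ratio", "p", "hits"]
    ).set_index("set")
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    return df[["overlap", "odds_ratio", "p", "fdr", "hits"]]


def jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def prune_redundant(
    rows: pd.DataFrame,
    collection: GeneSetCollection,
    jaccard_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
    min_or: float | None = None,
) -> pd.DataFrame:
    """Greedy Jaccard pruning of redundant significant gene sets.

    Only significant rows survive (FDR < ``fdr_threshold``; odds ratio >
    ``min_or`` when given).  Survivors are ranked by odds ratio descending
    (ties broken by smaller p, then set name); scanning down the ranking,
    a set is removed when its full membership (intersected with the
    universe) overlaps any already-kept set with Jaccard STRICTLY greater
    than ``jaccard_threshold``.  The operation is idempotent and always
    keeps the top-ranked significant set.
    """
    sig = rows[rows["fdr"] < fdr_threshold]
    if min_or is not None:
        sig = sig[sig["odds_ratio"] > min_or]
    ranked = sig.sort_values(
        by=["odds_ratio", "p"], ascending=[False, True], kind="stable"
    )
    # deterministic tie-break on name after (OR desc, p asc)
    ranked = ranked.loc[
        sorted(
            ranked.index,
            key=lambda n: (-_key(ranked.loc[n, "odds_ratio"]), ranked.loc[n, "p"], n),
        )
    ]
    kept: list[str] = []
    for name in ranked.index:
        members = collection.sets.get(name, set())
        if any(
            jaccard(members, collection.sets.get(k, set())) > jaccard_threshold
            for k in kept
        ):
            continue
        kept.append(name)
    return rows.loc[kept]


def _key(v: float) -> float:
    return float("inf") if np.isinf(v) else (float("-inf") if np.isnan(v) else v)


# ---------------------------------------------------------------------------
# GMT IO


def read_gmt(path) -> dict[str, set]:
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")
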