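"""Hypergeometric over-representation analysis with kappa-score term grouping.

Each term is tested with the upper-tail hypergeometric probability
P(X >= k) for k query genes falling in a term of size K, a query of size n
and a universe of size N.  GO categories use Bonferroni correction, pathway
collections BH, with Holm ("Bonferroni step-down") also available.
Significant terms are grouped by single-linkage clustering of pairwise
Cohen's kappa between their membership indicator vectors over the universe,
mirroring the redundancy grouping of functional-annotation tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from . import io as mio

logger = logging.getLogger(__name__)

CATEGORIES = ("BP", "MF", "CC", "pathway")


@dataclass
class GeneSetCollection:
    """Terms (id, name, category, gene set) over a background universe."""

    terms: list = field(default_factory=list)
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*(t[3] for t in self.terms)) if self.terms else set()
        for tid, _name, cat, genes in self.terms:
            if not genes:
                raise ValueError(f"term '{tid}' has an empty gene set")
            if cat not in CATEGORIES:
                raise ValueError(f"term '{tid}' has unknown category '{cat}'")
            extra = set(genes) - self.universe
            if extra:
                raise ValueError(f"term '{tid}' has genes outside the universe: {sorted(extra)[:3]}")

    @classmethod
    def from_gmt(cls, paths_with_categories, universe: set | None = None) -> "GeneSetCollection":
        terms = []
        for path, category in paths_with_categories:
            terms.extend(mio.read_gmt(path, category=category))
        return cls(terms=terms, universe=universe or set())


def upper_tail_p(N: int, K: int, n: int, k: int) -> float:
    """Over-representation p-value P(X >= k), X ~ hypergeometric(N, K, n)."""
    return float(min(hypergeom.sf(k - 1, N, K, n), 1.0))


def hypergeom_enrich(
    query: set,
    collection: GeneSetCollection,
    method: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` against every term.

    Query genes outside the universe are dropped with a logged count; the
    result is sorted by p with columns term_id, name, category, k, K, n, N,
    p, adj_p, method, significant.
    """
    universe = collection.universe
    q = set(query) & universe
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.info("%d query genes outside the universe dropped", dropped)
    if not q:
        raise ValueError("query is empty after restriction to the universe")
    n, N = len(q), len(universe)
    rows = []
    for tid, name, cat, genes in collection.terms:
        K = len(genes)
        k = len(q & set(genes))
        rows.append((tid, name, cat, k, K, n, N, upper_tail_p(N, K, n, k)))
    out = pd.DataFrame(rows, columns=["term_id", "name", "category", "k", "K", "n", "N", "p"])
    if method == "bonferroni":
        out["adj_p"] = np.minimum(out["p"] * len(out), 1.0)
    elif method in ("bh", "holm"):
        sm = {"bh": "fdr_bh", "holm": "holm"}[method]
        out["adj_p"] = multipletests(out["p"].to_numpy(), method=sm)[1]
    else:
        raise ValueError(f"unknown correction method '{method}'")
    out["method"] = method
    out["significant"] = out["adj_p"] < alpha
    return out.sort_values(["p", "term_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# kappa grouping
# ---------------------------------------------------------------------------
def cohen_kappa_membership(a: set, b: set, universe: set) -> float:
    """Cohen's kappa between two gene-membership indicators over the universe.

    Identical memberships give 1 by definition (including the degenerate
    all-in/all-out cases where chance agreement is 1).
    """
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    a = a & universe
    b = b & universe
    if a == b:
        return 1.0
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = N - n11 - n10 - n01
    po = (n11 + n00) / N
    pa, pb = len(a) / N, len(b) / N
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1 - pe)


def kappa_group(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    threshold: float = 0.96,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Assign single-linkage kappa groups to (significant) enriched terms.

    Term pairs whose membership kappa is >= ``threshold`` are linked; each
    connected component forms one group labelled by its most significant term
    (smallest p, ties broken by term id).  A threshold above 1 leaves every
    term in its own group.
    """
    out = results.copy()
    out["group_id"] = pd.NA
    sel = out["significant"] if significant_only else pd.Series(True, index=out.index)
    idx = list(out.index[sel])
    if not idx:
        return out
    term_genes = {tid: set(genes) for tid, _n, _c, genes in collection.terms}
    parent = list(range(len(idx)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    universe_set = set(collection.universe)
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            ka = cohen_kappa_membership(
                term_genes[out.at[idx[a], "term_id"]],
                term_genes[out.at[idx[b], "term_id"]],
                universe_set,
            )
            if ka >= threshold:
                parent[find(a)] = find(b)

    comp: dict[int, list[int]] = {}
    for r in range(len(idx)):
        comp.setdefault(find(r), []).append(r)
    for members in comp.values():
        rows = [idx[r] for r in members]
        label_row = min(rows, key=lambda i: (out.at[i, "p"], out.at[i, "term_id"]))
        label = out.at[label_row, "term_id"]
        for i in rows:
            out.at[i, "group_id"] = label
    return out
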