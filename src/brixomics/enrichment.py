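"""GO-category overrepresentation by one-sided hypergeometric tests.

A gene set (e.g. the transcripts significant for one ANOVA effect) is
tested term by term against the annotated reference universe: with N
annotated genes in the universe, K carrying the term, and n set genes
annotated, the p-value is the hypergeometric upper tail P(X >= k).  Only
terms observed in the set (k >= 1) enter the Benjamini-Hochberg family,
and significance is strict adjusted p < alpha.  Annotations may optionally
be propagated to ancestor terms along an acyclic parent map
(the true-path convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anova import bh_adjust


@dataclass
class AnnotationIndex:
    term_to_genes: dict[str, set[str]]
    universe: set[str]
    parents: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        stray = set().union(*self.term_to_genes.values()) - self.universe \
            if self.term_to_genes else set()
        if stray:
            raise ValueError(f"annotated genes outside universe: "
                             f"{sorted(stray)[:5]}")


def _ancestors(term: str, parents: Mapping[str, set[str]],
               seen: set[str] | None = None) -> set[str]:
    seen = seen if seen is not None else set()
    for p in parents.get(term, ()):  # DFS; cycle check done up front
        if p not in seen:
            seen.add(p)
            _ancestors(p, parents, seen)
    return seen


def _check_acyclic(parents: Mapping[str, set[str]]) -> None:
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    def visit(t: str) -> None:
        color[t] = GRAY
        for p in parents.get(t, ()):
            c = color.get(p, WHITE)
            if c == GRAY:
                raise ValueError(f"cycle in term parent map at {p}")
            if c == WHITE:
                visit(p)
        color[t] = BLACK

    for t in list(parents):
        if color.get(t, WHITE) == WHITE:
            visit(t)


def build_annotation_index(gene2term: pd.DataFrame,
                           parents: pd.DataFrame | None = None,
                           propagate: bool = False,
                           universe: Iterable[str] | None = None,
                           ) -> AnnotationIndex:
    """Index a gene→term table, optionally closing annotations upward.

    ``gene2term`` needs columns ``gene`` and ``term``; ``parents`` (child,
    parent edge list) is required when ``propagate`` is set.  The universe
    defaults to the annotated genes (BinGO-style reference semantics) but
    can be widened to the whole array.
    """
    if gene2term.empty:
        raise ValueError("empty annotation table")
    parent_map: dict[str, set[str]] = {}
    if parents is not None and len(parents):
        for child, parent in parents.iloc[:, :2].itertuples(index=False):
            parent_map.setdefault(str(child), set()).add(str(parent))
        _check_acyclic(parent_map)
        known = set(gene2term["term"].astype(str)) | set(parent_map) | \
            {p for ps in parent_map.values() for p in ps}
        stray = set(gene2term["term"].astype(str)) - known
        if stray:
            raise ValueError(f"genes annotated to unknown terms: {sorted(stray)}")
    term_to_genes: dict[str, set[str]] = {}
    for gene, term in gene2term[["gene", "term"]].itertuples(index=False):
        term_to_genes.setdefault(str(term), set()).add(str(gene))
        if propagate:
            for anc in _ancestors(str(term), parent_map):
                term_to_genes.setdefault(anc, set()).add(str(gene))
    if universe is None:
        universe = set(gene2term["gene"].astype(str))
    return AnnotationIndex(term_to_genes=term_to_genes,
                           universe=set(universe), parents=parent_map)


def hypergeom_overrep(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_gene_set(gene_set: Iterable[str],
                    index: AnnotationIndex,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Test every term present in the set; BH across tested terms.

    Genes outside the annotated universe are dropped (their count is in
    ``DataFrame.attrs['n_dropped']``).  Rows are sorted by adjusted then raw
    p-value; ``fold`` is the in-set rate over the universe rate.
    """
    genes = set(gene_set)
    dropped = genes - index.universe
    genes &= index.universe
    N = len(index.universe)
    n = len(genes)
    rows = []
    for term, members in index.term_to_genes.items():
        K = len(members & index.universe)
        k = len(members & genes)
        if k < 1:
            continue
        p = hypergeom_overrep(k, n, K, N)
        fold = (k / n) / (K / N) if n and K else np.nan
        rows.append((term, k, n, K, N, p, fold))
    result = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p", "fold"])
    result["adj_p"] = bh_adjust(result["p"].to_numpy()) if len(result) else []
    result["significant"] = result["adj_p"] < alpha if len(result) else []
    result = result.sort_values(["adj_p", "p", "term"]).reset_index(drop=True)
    result.attrs["n_dropped"] = len(dropped)
    result.attrs["alpha"] = alpha
    return result
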