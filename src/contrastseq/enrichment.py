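"""Hypergeometric over/under-representation tests of annotation terms.

Given a gene list, an annotation (gene -> term pairs) and a reference
universe (by default the genes retained after low-count filtering), each
term with at least one universe gene is tested for over-representation
(``P(X >= k)``) and under-representation (``P(X <= k)``) under the
hypergeometric null; both families are BH-adjusted separately.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datatypes import Annotation
from .glm import adjust_bh

__all__ = ["hypergeom_tail", "enrich"]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """Exact hypergeometric tail probabilities (p_over, p_under).

    ``N`` universe genes of which ``K`` carry the term; a list of ``n``
    genes containing ``k`` carriers.  Both tails include ``X = k``.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    rv = hypergeom(N, K, n)
    p_over = float(rv.sf(k - 1))
    p_under = float(rv.cdf(k))
    return min(p_over, 1.0), min(p_under, 1.0)


def enrich(
    gene_list: list[str],
    annotation: Annotation,
    universe: list[str],
    alpha: float = 0.05,
    adjust: bool = True,
) -> pd.DataFrame:
    """Term-by-term enrichment table for one gene list.

    Genes outside the universe are dropped (with a warning); the annotation
    is restricted to the universe, so terms without universe genes are not
    tested.  Rows are sorted by ascending ``p_over``.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    listed = set(gene_list)
    outside = listed - universe_set
    if outside:
        warnings.warn(
            f"{len(outside)} listed gene(s) outside the universe dropped",
            stacklevel=2,
        )
        listed &= universe_set
    pairs = annotation.pairs
    pairs = pairs[pairs["gene"].isin(universe_set)]
    N, n = len(universe_set), len(listed)
    rows = []
    for term, genes in pairs.groupby("term")["gene"]:
        carriers = set(genes)
        K = len(carriers)
        k = len(carriers & listed)
        p_over, p_under = hypergeom_tail(k, K, n, N)
        rows.append(
            {"term": term, "N": N, "K": K, "n": n, "k": k,
             "p_over": p_over, "p_under": p_under}
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no annotated gene in the universe")
    if adjust:
        table["adj_p_over"] = adjust_bh(table["p_over"].to_numpy())
        table["adj_p_under"] = adjust_bh(table["p_under"].to_numpy())
    else:
        table["adj_p_over"] = table["p_over"]
        table["adj_p_under"] = table["p_under"]
    table["over_represented"] = table["adj_p_over"] <= alpha
    table["under_represented"] = table["adj_p_under"] <= alpha
    return (
        table.sort_values(["p_over", "term"], kind="stable")
        .reset_index(drop=True)
    )
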