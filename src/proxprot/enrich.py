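"""Gene-set over-representation analysis by the hypergeometric test.

For a query list of n genes drawn from a universe of N genes, a set with K
universe members and k query members is scored with the upper-tail
hypergeometric probability P(X >= k), X ~ Hypergeom(N, K, n), with
Benjamini-Hochberg correction across all tested sets. Multi-isoform
protein groups must be collapsed to single gene symbols before testing.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .quant import bh_adjust


def hypergeom_ora(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """Over-representation of each gene set in the query list.

    ``query`` must be a subset of ``universe``; each gene set is
    intersected with the universe before testing. Returns a DataFrame with
    one row per term (sorted by p): k, K, n, N, p, q, overlap_genes.
    """
    query = set(query)
    universe = set(universe)
    outside = sorted(query - universe)
    if outside:
        raise ValueError(f"query genes outside universe: {outside[:10]}")
    n, N = len(query), len(universe)

    rows = []
    for term, genes in sets.sets.items():
        in_universe = set(genes) & universe
        if not in_universe:
            continue
        overlap = sorted(in_universe & query)
        k, K = len(overlap), len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
                "overlap_genes": ";".join(overlap),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result = result.sort_values("p", kind="stable").set_index("term")
    return result
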