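"""Generic over-representation analysis against user-supplied gene sets.

For a query of ``n`` genes drawn from a universe of ``N``, a set with
``K`` members in the universe and ``k`` in the query has upper-tail
hypergeometric p-value ``P(X >= k)``; p-values are BH-adjusted across
sets.  This replaces database-backed GO/KEGG calls with the same test on
GMT input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .io import GeneSetCollection


@dataclass
class ORAResult:
    table: pd.DataFrame
    universe_size: int
    query_size: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]


def hypergeometric_ora(query_genes, gene_sets, universe) -> ORAResult:
    """Exact hypergeometric upper-tail test per gene set.

    Query genes outside the universe are dropped with a warning; gene-set
    members are intersected with the universe before sizing.
    """
    universe = list(dict.fromkeys(universe))
    if len(universe) == 0:
        raise ValueError("empty universe")
    uni = set(universe)
    query = list(dict.fromkeys(query_genes))
    if len(query) == 0:
        raise ValueError("empty query")
    outside = [g for g in query if g not in uni]
    if outside:
        warnings.warn(f"query genes outside universe dropped: {outside}")
        query = [g for g in query if g in uni]
        if not query:
            raise ValueError("no query gene lies in the universe")
    qset = set(query)
    sets = gene_sets.sets if isinstance(gene_sets, GeneSetCollection) else \
        dict(gene_sets)
    N, n = len(universe), len(query)
    rows = []
    for name, genes in sets.items():
        members = [g for g in dict.fromkeys(genes) if g in uni]
        K = len(members)
        overlap = sorted(qset.intersection(members))
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N, "p": p,
                     "genes": overlap})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values("p", kind="stable").reset_index(drop=True)
    return ORAResult(table, N, n)
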