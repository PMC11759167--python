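"""Over-representation analysis of gene lists against user-supplied gene sets.

Standard hypergeometric ORA: for a list of N genes drawn from a universe of
M genes, a set with n members in the universe and k members in the list gets
the upper-tail probability P(X >= k) for X ~ Hypergeometric(M, n, N),
followed by Benjamini-Hochberg adjustment across all tested sets. The
universe should be the genes that survived the expression filter, not the
whole annotation.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection


def hypergeom_ora(
    gene_list, sets: GeneSetCollection, universe
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``gene_list`` in each set.

    Gene sets are intersected with the universe before testing; sets with an
    empty intersection are skipped with a warning. Returns one row per tested
    set, ranked by p-value, with BH q-values.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if not universe:
        raise ValueError("universe is empty")
    if not gene_list:
        raise ValueError("gene list is empty")
    extra = gene_list - universe
    if extra:
        raise ValueError(f"gene list not contained in universe: {sorted(extra)[:5]}")
    M = len(universe)
    N = len(gene_list)
    rows = []
    for name, members in sets.sets.items():
        in_universe = members & universe
        if not in_universe:
            warnings.warn(
                f"gene set {name!r} has no members in the universe; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        n = len(in_universe)
        k = len(in_universe & gene_list)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append(
            {
                "set_name": name,
                "overlap_count": k,
                "set_size": n,
                "list_size": N,
                "universe_size": M,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap_count", "set_size",
            "list_size", "universe_size", "p_value",
        ],
    ).set_index("set_name")
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value")
    else:
        out["q_value"] = []
    return out


def significant_sets(
    result: pd.DataFrame, p_cut: float = 0.05, q_cut: float = 0.05
) -> pd.DataFrame:
    """Filter an ORA result at the conventional p and q cut-offs."""
    return result[(result["p_value"] < p_cut) & (result["q_value"] < q_cut)]
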