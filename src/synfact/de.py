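"""Per-gene arm-versus-control differential expression and DEG overlaps.

Each exposed arm is contrasted against control on log2 CPM expression with a
two-sided Welch t-test; a gene is called differentially expressed (DEG) when
p < 0.05 and linear fold change > 2 (|log2FC| > 1), both thresholds
configurable. No multiple-testing correction is applied at this stage — the
DEG rule is a raw per-gene cut-off.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleDesign

CONTRAST_ARMS = ("uvssr", "ozone", "co")

_ARM_INDICATORS = {"uvssr": (1, 0), "ozone": (0, 1), "co": (1, 1)}


def contrast_de(
    em: ExpressionMatrix,
    design: SampleDesign,
    arm: str,
    p_cut: float = 0.05,
    fc_cut: float = 2.0,
) -> pd.DataFrame:
    """Welch t contrast of one exposed arm against control.

    Returns a per-gene frame with columns log2fc, p_value, is_deg.
    log2fc = mean(arm) - mean(control) on log2 CPM. Genes with zero variance
    in both groups get the degenerate convention p = 1 if the means are equal,
    p = 0 otherwise.
    """
    if arm not in _ARM_INDICATORS:
        raise ValueError(f"arm must be one of {CONTRAST_ARMS}, got {arm!r}")
    if list(design.sample_ids) != list(em.sample_ids):
        raise ValueError("design samples do not match expression samples")
    u, o = _ARM_INDICATORS[arm]
    mask_arm = design.arm_mask(u, o)
    mask_ctrl = design.arm_mask(0, 0)
    if mask_arm.sum() < 2 or mask_ctrl.sum() < 2:
        raise ValueError("need >= 2 replicates in each group")
    x = em.values[:, mask_arm]
    y = em.values[:, mask_ctrl]
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
        p = np.asarray(res.pvalue)
    degenerate = ~np.isfinite(p)
    p[degenerate] = np.where(np.isclose(log2fc[degenerate], 0.0), 1.0, 0.0)
    is_deg = (p < p_cut) & (np.abs(log2fc) > np.log2(fc_cut))
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "is_deg": is_deg},
        index=pd.Index(em.gene_ids, name="gene_id"),
    )


def overlap_summary(results: dict[str, pd.DataFrame]) -> pd.Series:
    """Venn-region DEG counts across the three contrasts.

    ``results`` maps contrast name -> contrast_de output over one shared gene
    universe. Returns counts of DEGs exclusive to each contrast, to each pair,
    and to the triple intersection; the seven region counts sum to the union
    size, reported as ``union``.
    """
    names = list(results)
    universes = [tuple(df.index) for df in results.values()]
    if len(set(universes)) != 1:
        raise ValueError("contrasts have mismatched gene universes")
    sets = {k: set(df.index[df["is_deg"].astype(bool)]) for k, df in results.items()}
    regions: dict[str, int] = {}
    for r in (1, 2, 3):
        for group in combinations(names, r):
            inside = set.intersection(*(sets[g] for g in group))
            outside = set.union(set(), *(sets[g] for g in names if g not in group))
            regions["&".join(group)] = len(inside - outside)
    regions["union"] = len(set.union(*sets.values()))
    return pd.Series(regions, name="count")
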