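"""Per-gene full-factorial linear model on the 2x2 co-exposure design.

For each gene, log2 expression is regressed on (1, u, o, u*o) with
u, o in {0, 1} indicating UVSSR and ozone exposure. The coefficients are

* ``mu`` — control-arm mean (log2),
* ``a`` — UVSSR simple main effect (UVSSR-vs-control log2FC),
* ``b`` — ozone simple main effect,
* ``c`` — interaction: departure of the co-exposure log2FC from a + b.

Derived quantities: ``co_effect`` = a + b + c (co-vs-control log2FC) and the
marginal main effects ``main_uv`` = a + c/2, ``main_o3`` = b + c/2 (each
factor's effect averaged over the other factor's levels — the standard
balanced-design definition). Standard errors of the marginals follow by
linear-combination propagation; all p-values are two-sided t on the residual
degrees of freedom (n_samples - 4).

The model is saturated in the four arms, so on a balanced design the fitted
arm means equal the empirical arm means exactly. The estimator is plain
per-gene OLS; an optional pooled-variance moderation (shrinking each gene's
residual variance toward the genome-wide mean) is available but off by
default, keeping the default estimator fully specified and oracle-checkable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleDesign

_DEGENERATE_VAR = 1e-18  # residual variance below this is treated as zero
_ZERO_COEF = 1e-9

#: contrast vectors over (mu, a, b, c) for the reported effects
_EFFECTS = {
    "a": np.array([0.0, 1.0, 0.0, 0.0]),
    "b": np.array([0.0, 0.0, 1.0, 0.0]),
    "c": np.array([0.0, 0.0, 0.0, 1.0]),
    "main_uv": np.array([0.0, 1.0, 0.0, 0.5]),
    "main_o3": np.array([0.0, 0.0, 1.0, 0.5]),
}


def fit_factorial(
    em: ExpressionMatrix,
    design: SampleDesign,
    moderation_weight: float = 0.0,
) -> pd.DataFrame:
    """OLS factorial fit for every gene; returns the per-gene effect table.

    ``moderation_weight`` w in [0, 1] replaces each gene's residual variance
    s2_g by (1-w) s2_g + w mean(s2) before computing standard errors and
    p-values (w = 0: unmoderated).

    Genes with zero residual variance (noiseless fixtures) get degenerate
    p-values — 1 where the coefficient is also zero, 0 otherwise — and a
    warning is emitted.
    """
    if list(design.sample_ids) != list(em.sample_ids):
        raise ValueError("design samples do not match expression samples")
    if not 0.0 <= moderation_weight <= 1.0:
        raise ValueError("moderation_weight must be in [0, 1]")
    u = design.table["uv"].to_numpy(float)
    o = design.table["ozone"].to_numpy(float)
    X = np.column_stack([np.ones_like(u), u, o, u * o])
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError(f"need n_samples >= 5 for df >= 1, got {n}")
    xtx_inv = np.linalg.inv(X.T @ X)  # nonsingular: all four arms present
    Y = em.values  # genes x samples
    beta = Y @ X @ xtx_inv  # genes x 4
    resid = Y - beta @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / df
    if moderation_weight > 0:
        s2 = (1 - moderation_weight) * s2 + moderation_weight * s2.mean()
    degenerate = s2 < _DEGENERATE_VAR
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero residual variance; "
            "their p-values are degenerate (0 or 1)",
            RuntimeWarning,
            stacklevel=2,
        )

    out: dict[str, np.ndarray] = {
        "mu": beta[:, 0],
        "a": beta[:, 1],
        "b": beta[:, 2],
        "c": beta[:, 3],
    }
    out["co_effect"] = beta[:, 1] + beta[:, 2] + beta[:, 3]
    for name, L in _EFFECTS.items():
        est = beta @ L
        var_unit = float(L @ xtx_inv @ L)
        se = np.sqrt(s2 * var_unit)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / se
            p = 2.0 * stats.t.sf(np.abs(t), df)
        p[degenerate] = np.where(np.abs(est[degenerate]) < _ZERO_COEF, 1.0, 0.0)
        if name in ("main_uv", "main_o3"):
            out[name] = est
        out[f"se_{name}"] = se
        out[f"p_{name}"] = p
    out["df"] = np.full(Y.shape[0], df, dtype=int)
    cols = [
        "mu", "a", "b", "c", "co_effect", "main_uv", "main_o3",
        "se_a", "se_b", "se_c", "se_main_uv", "se_main_o3",
        "p_a", "p_b", "p_c", "p_main_uv", "p_main_o3", "df",
    ]
    return pd.DataFrame(out, index=pd.Index(em.gene_ids, name="gene_id"))[cols]


def predicted_arm_means(fits: pd.DataFrame) -> pd.DataFrame:
    """Model-implied arm means (log2) per gene, from the fitted coefficients."""
    return pd.DataFrame(
        {
            "control": fits["mu"],
            "uvssr": fits["mu"] + fits["a"],
            "ozone": fits["mu"] + fits["b"],
            "co": fits["mu"] + fits["co_effect"],
        },
        index=fits.index,
    )


def gate_interaction(fits: pd.DataFrame, alpha: float = 0.05) -> pd.Index:
    """Genes passing the interaction gate: interaction p-value < alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return fits.index[fits["p_c"] < alpha]


def add_gate(fits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Copy of ``fits`` with a 0/1 ``gated`` column at the given alpha."""
    out = fits.copy()
    out["gated"] = (fits["p_c"] < alpha).astype(int)
    return out
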