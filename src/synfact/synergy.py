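"""Per-gene synergy scores and the synergy-gene selection rule.

The synergy score compares the co-exposure response to the additive
expectation from the two single exposures, on the log2 fold-change scale:

    raw_ratio = |fc_co| / |fc_uv + fc_o3|
    score     = log2(raw_ratio)          (default "log2_ratio" variant)

A positive score means the co-exposure effect exceeds the additive
expectation in log2 magnitude — a potential synergistic response. The
"abs_ratio" variant reports the raw ratio itself (synergy then reads as
ratio > 1). A gene is selected as a synergy gene when its score is strictly
positive and its expression change is significant: p < 0.05 and linear
|fold change| > 1.2 of the main effect (either marginal main effect by
default; the co-exposure effect as an alternative rule).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .components import SUBMODE_PRINT, UNCLASSIFIABLE

VARIANTS = ("log2_ratio", "abs_ratio")
MAIN_RULES = ("either_main", "co_effect")


def synergy_score(
    fc_uv: float, fc_o3: float, fc_co: float, variant: str = "log2_ratio"
) -> tuple[float, float]:
    """(score, raw_ratio) from the three log2 fold changes versus control.

    Degenerate inputs are flagged with infinite sentinels rather than
    silently dropped: fc_uv + fc_o3 = 0 gives raw_ratio = +inf (score +inf
    under either variant), fc_co = 0 gives raw_ratio = 0 and log2 score -inf.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    denom = abs(fc_uv + fc_o3)
    if denom == 0.0:
        warnings.warn(
            "single-exposure log2 fold changes cancel exactly; "
            "synergy ratio is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf, math.inf
    raw_ratio = abs(fc_co) / denom
    if variant == "abs_ratio":
        return raw_ratio, raw_ratio
    score = math.log2(raw_ratio) if raw_ratio > 0 else -math.inf
    return score, raw_ratio


def select_synergy_genes(
    fits: pd.DataFrame,
    labels: pd.DataFrame,
    p_cut: float = 0.05,
    fc_cut: float = 1.2,
    main_rule: str = "either_main",
    variant: str = "log2_ratio",
) -> pd.DataFrame:
    """Score classified interaction genes and flag the synergy genes.

    ``fits`` is the factorial-fit table; ``labels`` the per-gene component
    table (classified, interaction-gated genes). Returns one record per
    labeled gene — component submode as printed (Concordant / Discordant /
    UVSSR-dominant / Ozone-dominant), score, raw_ratio, the main-effect fold
    change and p-value used in the filter, and the ``is_synergy`` flag —
    sorted by descending score.

    is_synergy requires score > 0 (strictly super-additive; under the
    abs_ratio variant, ratio > 1) and the main-effect significance rule:
    p < ``p_cut`` with linear |FC| > ``fc_cut`` for either marginal main
    effect ("either_main", default) or for the co-exposure effect
    ("co_effect").
    """
    if main_rule not in MAIN_RULES:
        raise ValueError(f"main_rule must be one of {MAIN_RULES}, got {main_rule!r}")
    log2_fc_cut = math.log2(fc_cut)
    records = []
    for gene_id, lab in labels.iterrows():
        row = fits.loc[gene_id]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            score, raw_ratio = synergy_score(
                row["a"], row["b"], row["co_effect"], variant=variant
            )
        if main_rule == "either_main":
            candidates = [
                (row["main_uv"], row["p_main_uv"]),
                (row["main_o3"], row["p_main_o3"]),
            ]
            passing = [
                (e, p) for e, p in candidates if p < p_cut and abs(e) > log2_fc_cut
            ]
            # report the strongest passing effect, else the strongest overall
            pool = passing or candidates
            eff, p = max(pool, key=lambda ep: abs(ep[0]))
            rule_ok = bool(passing)
        else:
            eff, p = row["co_effect"], row["p_c"]
            rule_ok = p < p_cut and abs(eff) > log2_fc_cut
        positive = score > 0 if variant == "log2_ratio" else score > 1
        records.append(
            {
                "gene_id": gene_id,
                "component": SUBMODE_PRINT.get(lab["submode"], UNCLASSIFIABLE),
                "score": score,
                "raw_ratio": raw_ratio,
                "is_synergy": bool(positive and rule_ok),
                "main_effect_fc": float(np.sign(eff) * 2.0 ** abs(eff)),
                "main_effect_p": p,
            }
        )
    cols = [
        "gene_id", "component", "score", "raw_ratio",
        "is_synergy", "main_effect_fc", "main_effect_p",
    ]
    out = pd.DataFrame(records, columns=cols).set_index("gene_id")
    return out.sort_values("score", ascending=False)


def format_synergy_table(records: pd.DataFrame, synergy_only: bool = True) -> str:
    """Render selected genes as the printable gene/component/score table."""
    sub = records[records["is_synergy"]] if synergy_only else records
    lines = ["Gene\tComponent\tSynergy Score"]
    for gene_id, row in sub.iterrows():
        lines.append(f"{gene_id}\t{row['component']}\t{row['score']:.2f}")
    return "\n".join(lines)
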