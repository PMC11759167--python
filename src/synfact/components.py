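"""Eight-component expression-profile classification for interaction genes.

A gene with a significant stressor interaction is classified by the signs of
its three log2 fold changes versus control: UVSSR alone (``fc_uv``), ozone
alone (``fc_o3``) and co-exposure (``fc_co`` = a + b + c in the factorial
parameterization). The two single-stressor signs decide cooperative (same
direction) versus competitive (opposite directions); the co-exposure sign then
decides concordant/discordant within cooperative genes, and UVSSR-dominant/
ozone-dominant within competitive genes. The eight sign patterns of
(fc_uv, fc_o3, fc_co) map bijectively onto the eight components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPONENTS = (
    "coop_up_concordant",
    "coop_up_discordant",
    "coop_down_concordant",
    "coop_down_discordant",
    "comp_uvUp_uvDominant",
    "comp_uvUp_o3Dominant",
    "comp_uvDown_uvDominant",
    "comp_uvDown_o3Dominant",
)

UNCLASSIFIABLE = "unclassifiable"

#: submode labels as printed in synergy tables
SUBMODE_PRINT = {
    "concordant": "Concordant",
    "discordant": "Discordant",
    "uvssr_dominant": "UVSSR-dominant",
    "ozone_dominant": "Ozone-dominant",
}


@dataclass(frozen=True)
class ComponentLabel:
    component: str  # one of COMPONENTS or UNCLASSIFIABLE
    mode: str  # "cooperative" | "competitive" | UNCLASSIFIABLE
    submode: str  # "concordant" | "discordant" | "uvssr_dominant" | "ozone_dominant"


def classify_gene(fc_uv: float, fc_o3: float, fc_co: float) -> ComponentLabel:
    """Classify one gene from its three log2 fold changes versus control.

    Any exactly-zero input yields the distinct ``unclassifiable`` outcome:
    the sign rules have no tie-breaking provision, and silently assigning a
    component would corrupt downstream fraction summaries. With continuous
    estimates zeros occur only in degenerate fixtures.
    """
    if fc_uv == 0 or fc_o3 == 0 or fc_co == 0:
        return ComponentLabel(UNCLASSIFIABLE, UNCLASSIFIABLE, UNCLASSIFIABLE)
    su, so, sc = np.sign(fc_uv), np.sign(fc_o3), np.sign(fc_co)
    if su == so:  # both stressors regulate in the same direction
        mode = "cooperative"
        submode = "concordant" if sc == su else "discordant"
        direction = "up" if su > 0 else "down"
        component = f"coop_{direction}_{submode}"
    else:
        mode = "competitive"
        submode = "uvssr_dominant" if sc == su else "ozone_dominant"
        direction = "uvUp" if su > 0 else "uvDown"
        dom = "uvDominant" if sc == su else "o3Dominant"
        component = f"comp_{direction}_{dom}"
    return ComponentLabel(component, mode, submode)


def component_parts(component: str) -> tuple[str, str]:
    """(mode, submode) implied by a component name."""
    if component.startswith("coop_"):
        return "cooperative", component.rsplit("_", 1)[1]
    if component.endswith("uvDominant"):
        return "competitive", "uvssr_dominant"
    if component.endswith("o3Dominant"):
        return "competitive", "ozone_dominant"
    raise ValueError(f"unknown component {component!r}")


def component_sign_pattern(component: str) -> tuple[int, int, int]:
    """Canonical (sign a, sign b, sign a+b+c) realizing a component."""
    patterns = {
        "coop_up_concordant": (1, 1, 1),
        "coop_up_discordant": (1, 1, -1),
        "coop_down_concordant": (-1, -1, -1),
        "coop_down_discordant": (-1, -1, 1),
        "comp_uvUp_uvDominant": (1, -1, 1),
        "comp_uvUp_o3Dominant": (1, -1, -1),
        "comp_uvDown_uvDominant": (-1, 1, -1),
        "comp_uvDown_o3Dominant": (-1, 1, 1),
    }
    return patterns[component]


def classify_all(fits: pd.DataFrame, gated_only: bool = True) -> pd.DataFrame:
    """Label every (gated) gene; returns per-gene table.

    ``fits`` is the per-gene factorial-fit table (needs columns ``a``, ``b``,
    ``co_effect`` and, when ``gated_only``, ``gated``). Classification uses
    the factorial-fit fold changes so gating and labels come from one model.
    """
    sub = fits[fits["gated"].astype(bool)] if gated_only else fits
    records = []
    for gene_id, row in sub.iterrows():
        lab = classify_gene(row["a"], row["b"], row["co_effect"])
        records.append(
            {
                "gene_id": gene_id,
                "fc_uv": row["a"],
                "fc_o3": row["b"],
                "fc_co": row["co_effect"],
                "mode": lab.mode,
                "submode": lab.submode,
                "component": lab.component,
            }
        )
    cols = ["gene_id", "fc_uv", "fc_o3", "fc_co", "mode", "submode", "component"]
    return pd.DataFrame(records, columns=cols).set_index("gene_id")


def component_summary(labels: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per component, mode and submode.

    Fractions are over classified genes (unclassifiable excluded); with no
    classified genes, fractions are reported as NaN rather than invented.
    Returns rows keyed (level, name) with columns count, fraction.
    """
    rows = []
    classified = labels[labels["component"] != UNCLASSIFIABLE]
    n = len(classified)
    for comp in COMPONENTS:
        cnt = int((classified["component"] == comp).sum())
        rows.append(("component", comp, cnt, cnt / n if n else float("nan")))
    for mode in ("cooperative", "competitive"):
        cnt = int((classified["mode"] == mode).sum())
        rows.append(("mode", mode, cnt, cnt / n if n else float("nan")))
    coop = classified[classified["mode"] == "cooperative"]
    comp = classified[classified["mode"] == "competitive"]
    for submode, parent in (
        ("concordant", coop),
        ("discordant", coop),
        ("uvssr_dominant", comp),
        ("ozone_dominant", comp),
    ):
        cnt = int((parent["submode"] == submode).sum())
        denom = len(parent)
        rows.append(("submode", submode, cnt, cnt / denom if denom else float("nan")))
    rows.append(("special", UNCLASSIFIABLE, int(len(labels) - n), float("nan")))
    return pd.DataFrame(
        rows, columns=["level", "name", "count", "fraction"]
    ).set_index(["level", "name"])
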