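"""One-way ANOVA with Tukey HSD across the four exposure arms.

Used for continuous phenotype replicates such as CIELAB L* lightness: a
global F-test across arms followed by all pairwise comparisons with the
studentized-range (Tukey HSD) adjustment on the pooled within-group
variance; the Tukey-Kramer form handles unbalanced groups. Adjusted
p-values below alpha flag significant pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import ARM_LABELS, PhenotypeTable


@dataclass
class PhenotypeStats:
    anova_p: float
    tukey: pd.DataFrame  # per pair: arm_1, arm_2, mean_diff, adjusted_p, significant
    degenerate: bool = False


def anova_tukey(ph: PhenotypeTable, alpha: float = 0.05) -> PhenotypeStats:
    """One-way ANOVA F-test plus Tukey HSD pairwise comparisons.

    With zero within-group variance everywhere the F statistic is undefined;
    the degenerate convention reports p = 0 when any arm means differ
    (differences are then certain) and p = 1 otherwise, with every pairwise
    comparison flagged accordingly.
    """
    groups = [ph.arm_values(arm) for arm in ARM_LABELS]
    pooled_var = sum(((g - g.mean()) ** 2).sum() for g in groups) / sum(
        len(g) - 1 for g in groups
    )
    if pooled_var == 0.0:
        means = np.array([g.mean() for g in groups])
        distinct = not np.allclose(means, means[0])
        rows = []
        for i in range(len(ARM_LABELS)):
            for j in range(i + 1, len(ARM_LABELS)):
                diff = means[j] - means[i]
                rows.append(
                    {
                        "arm_1": ARM_LABELS[i],
                        "arm_2": ARM_LABELS[j],
                        "mean_diff": diff,
                        "adjusted_p": 0.0 if diff != 0 else 1.0,
                        "significant": diff != 0,
                    }
                )
        return PhenotypeStats(
            anova_p=0.0 if distinct else 1.0,
            tukey=pd.DataFrame(rows),
            degenerate=True,
        )

    anova_p = float(stats.f_oneway(*groups).pvalue)
    values = np.concatenate(groups)
    arm_of = np.concatenate(
        [np.repeat(arm, len(g)) for arm, g in zip(ARM_LABELS, groups)]
    )
    hsd = pairwise_tukeyhsd(values, arm_of, alpha=alpha)
    table = pd.DataFrame(
        hsd.summary().data[1:], columns=hsd.summary().data[0]
    )
    out = pd.DataFrame(
        {
            "arm_1": table["group1"],
            "arm_2": table["group2"],
            "mean_diff": table["meandiff"].astype(float),
            "adjusted_p": np.asarray(hsd.pvalues, dtype=float),
            "significant": np.asarray(hsd.pvalues, dtype=float) < alpha,
        }
    )
    return PhenotypeStats(anova_p=anova_p, tukey=out)
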