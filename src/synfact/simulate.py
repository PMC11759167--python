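"""Synthetic 2x2 factorial RNA-seq counts with planted interaction structure.

The generator emulates the study design the analysis assumes: four arms
(control, UVSSR, ozone, co-exposure) with a fixed number of replicates each,
negative-binomial counts, and a planted mixture of the eight interaction
components plus null genes. Every non-null gene carries true log2 effects
(a, b, c) whose sign pattern realizes its assigned component exactly, so the
classifier applied to the true effects recovers the assignment with 100%
accuracy — the contract recovery tests rely on.

Negative-binomial parameterization: mean mu and dispersion phi with
variance mu + phi * mu**2; phi is shared across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import (
    COMPONENTS,
    classify_gene,
    component_sign_pattern,
)
from .io import CountMatrix, PhenotypeTable, SampleDesign

ARM_ORDER = (("control", 0, 0), ("uvssr", 1, 0), ("ozone", 0, 1), ("co", 1, 1))

#: components whose co-exposure direction is set by the interaction alone
_FLIP_COMPONENTS = tuple(c for c in COMPONENTS if "concordant" not in c)


class ComponentRealizabilityError(ValueError):
    """A requested component's sign pattern cannot be realized."""


def default_component_fractions(effect_fraction: float = 0.2) -> dict[str, float]:
    """Mixture with ``effect_fraction`` split evenly over the 8 components."""
    per = effect_fraction / len(COMPONENTS)
    fractions = {c: per for c in COMPONENTS}
    fractions["null"] = 1.0 - effect_fraction
    return fractions


@dataclass
class SimulationConfig:
    """Parameters of the factorial count simulation.

    Defaults mirror the emulated study where stated (3 replicates per arm)
    and conventional bulk RNA-seq values elsewhere (library size 1e7,
    dispersion 0.1, log2-normal baseline abundances).
    """

    n_genes: int = 2000
    replicates_per_arm: int = 3
    baseline_log_mean: float = 4.0  # mean of log2 baseline abundance
    baseline_log_sd: float = 2.0
    dispersion: float = 0.1  # phi; variance = mu + phi mu^2
    library_size: int = 10_000_000  # expected total counts per sample
    library_jitter_sd: float = 0.0  # log2-scale sd of per-sample depth factor
    component_fractions: dict[str, float] = field(
        default_factory=lambda: default_component_fractions(0.2)
    )
    effect_size_log2: float = 2.0  # |a| and |b| of planted simple effects
    interaction_size_log2: float = 2.0  # interaction magnitude
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.replicates_per_arm < 2:
            raise ValueError("replicates_per_arm must be >= 2 (variance inestimable)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.baseline_log_sd <= 0:
            raise ValueError("baseline_log_sd must be > 0")
        if self.library_size < 1:
            raise ValueError("library_size must be positive")
        names = set(self.component_fractions)
        unknown = names - set(COMPONENTS) - {"null"}
        if unknown:
            raise ValueError(f"unknown component names: {sorted(unknown)}")
        vals = np.array(list(self.component_fractions.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("component fractions must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"component fractions sum to {vals.sum()}, expected 1")
        non_null = [
            c for c in self.component_fractions
            if c != "null" and self.component_fractions[c] > 0
        ]
        if non_null and self.effect_size_log2 <= 0:
            raise ValueError("effect_size_log2 must be > 0 when effects are planted")
        for comp in non_null:
            if comp in _FLIP_COMPONENTS and self.interaction_size_log2 <= 0:
                raise ComponentRealizabilityError(
                    f"component {comp!r} needs the interaction to set (or flip) the "
                    f"co-exposure direction; interaction_size_log2 must be > 0"
                )


def _planted_effects(component: str, effect: float, interaction: float):
    """(a, b, c) in log2 units realizing a component's sign pattern.

    Simple effects get magnitude ``effect`` with the component's signs. For
    concordant components the interaction reinforces the shared direction
    (c = sign * interaction). For discordant and dominant components the
    co-exposure sign must differ from sign(a + b) (or a + b is 0), so
    c = -sign(a+b) * (|a+b| + interaction), which realizes the pattern exactly.
    """
    su, so, sco = component_sign_pattern(component)
    a = su * effect
    b = so * effect
    if "concordant" in component:
        c = sco * interaction
    else:
        c = -np.sign(a + b) * abs(a + b) + sco * interaction
    return a, b, c


def _assign_components(
    fractions: dict[str, float], n_genes: int
) -> dict[str, int]:
    """Exact gene counts per label via floor + largest remainder.

    Deterministic by construction so fixture gene counts are assertable;
    remainder ties break in canonical component order.
    """
    order = [c for c in (*COMPONENTS, "null") if c in fractions]
    raw = {c: fractions[c] * n_genes for c in order}
    counts = {c: int(np.floor(raw[c])) for c in order}
    short = n_genes - sum(counts.values())
    by_remainder = sorted(order, key=lambda c: (-(raw[c] - counts[c]), order.index(c)))
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleDesign, pd.DataFrame]:
    """Simulate counts, design and ground truth for the 2x2 factorial design.

    Returns (CountMatrix, SampleDesign, truth) where ``truth`` is a per-gene
    frame with columns component, a, b, c (log2 effects; zeros for null
    genes). Identical config and seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(4, len(str(n)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]

    # deterministic per-label counts, random placement among genes
    counts_per_label = _assign_components(config.component_fractions, n)
    labels = np.array(
        [lab for lab, k in counts_per_label.items() for _ in range(k)], dtype=object
    )
    labels = labels[rng.permutation(n)]

    a = np.zeros(n)
    b = np.zeros(n)
    c = np.zeros(n)
    for comp in COMPONENTS:
        mask = labels == comp
        if not mask.any():
            continue
        a_c, b_c, c_c = _planted_effects(
            comp, config.effect_size_log2, config.interaction_size_log2
        )
        a[mask], b[mask], c[mask] = a_c, b_c, c_c

    truth = pd.DataFrame(
        {"component": labels, "a": a, "b": b, "c": c},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # baseline relative abundances
    z = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    weights = np.exp2(z)
    rel = weights / weights.sum()

    sample_ids: list[str] = []
    design_rows = []
    mean_cols = []
    for arm, u, o in ARM_ORDER:
        log2fc = a * u + b * o + c * (u * o)
        arm_mean = rel * np.exp2(log2fc)
        for r in range(1, config.replicates_per_arm + 1):
            sid = f"{arm}_r{r}"
            sample_ids.append(sid)
            design_rows.append(
                {"sample_id": sid, "uv": u, "ozone": o, "replicate": f"r{r}"}
            )
            depth = config.library_size
            if config.library_jitter_sd > 0:
                depth = depth * np.exp2(rng.normal(0.0, config.library_jitter_sd))
            mean_cols.append(arm_mean * depth)

    mu = np.column_stack(mean_cols)
    r_nb = 1.0 / config.dispersion
    p_nb = r_nb / (r_nb + mu)
    counts = rng.negative_binomial(r_nb, p_nb)

    cm = CountMatrix(gene_ids, sample_ids, counts.astype(np.int64))
    design = SampleDesign(pd.DataFrame(design_rows))

    # generator contract: true effects classify back to the assigned component
    for gene, row in truth[truth["component"] != "null"].iterrows():
        lab = classify_gene(row["a"], row["b"], row["a"] + row["b"] + row["c"])
        assert lab.component == row["component"], (gene, lab.component)

    return cm, design, truth


def simulate_phenotype(
    arm_means: tuple[float, float, float, float],
    sd: float,
    replicates: int = 5,
    seed: int = 0,
) -> PhenotypeTable:
    """Gaussian phenotype replicates (e.g. L* lightness) per arm.

    ``arm_means`` is (control, uvssr, ozone, co). The phenotype is modeled
    as Gaussian around each arm mean with shared noise sd.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for (arm, _, _), mean in zip(ARM_ORDER, arm_means):
        values = rng.normal(mean, sd, size=replicates)
        for r, v in enumerate(values, start=1):
            rows.append({"arm": arm, "replicate": f"r{r}", "value": v})
    return PhenotypeTable(pd.DataFrame(rows))


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def read_truth(path) -> pd.DataFrame:
    # keep_default_na: the component label "null" is a real value, not NaN
    return pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
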