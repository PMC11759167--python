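import numpy as np
import pandas as pd
import pytest

from synfact.io import CountMatrix, ExpressionMatrix, SampleDesign


def make_design(replicates: int = 3) -> SampleDesign:
    rows = []
    for arm, u, o in (("control", 0, 0), ("uvssr", 1, 0), ("ozone", 0, 1), ("co", 1, 1)):
        for r in range(1, replicates + 1):
            rows.append({"sample_id": f"{arm}_r{r}", "uv": u, "ozone": o, "replicate": f"r{r}"})
    return SampleDesign(pd.DataFrame(rows))


def expression_from_arm_means(
    arm_means: np.ndarray, replicates: int = 3, noise_sd: float = 0.0, seed: int = 0
) -> tuple[ExpressionMatrix, SampleDesign]:
    """Expression matrix whose per-arm values equal arm_means (+ noise).

    ``arm_means`` is genes x 4 in arm order control, uvssr, ozone, co.
    """
    arm_means = np.atleast_2d(np.asarray(arm_means, dtype=float))
    design = make_design(replicates)
    rng = np.random.default_rng(seed)
    values = np.repeat(arm_means, replicates, axis=1)
    if noise_sd > 0:
        values = values + rng.normal(0, noise_sd, size=values.shape)
    gene_ids = [f"g{i}" for i in range(arm_means.shape[0])]
    return ExpressionMatrix(gene_ids, design.sample_ids, values), design


@pytest.fixture
def design3() -> SampleDesign:
    return make_design(3)


@pytest.fixture
def small_counts() -> CountMatrix:
    counts = np.array(
        [
            [10, 20, 30, 40],
            [0, 0, 0, 0],
            [5, 5, 5, 5],
            [100, 200, 150, 120],
            [1, 0, 2, 0],
        ]
    )
    return CountMatrix(
        [f"g{i}" for i in range(5)], [f"s{j}" for j in range(4)], counts
    )


@pytest.fixture(scope="session")
def mixture_run():
    """One strong-effect mixture simulation fitted end to end (shared)."""
    import synfact as sf
    from synfact.factorial import add_gate, fit_factorial

    cfg = sf.SimulationConfig(n_genes=1000, dispersion=0.05, seed=7)
    cm, design, truth = sf.simulate_counts(cfg)
    em = sf.log_cpm(sf.filter_low_expression(cm))
    fits = add_gate(fit_factorial(em, design))
    return cfg, cm, design, truth, em, fits
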