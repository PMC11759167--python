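# synfact

Full-factorial interaction analysis of two-stressor co-exposure
transcriptomics: which genes do two skin stressors — solar-simulated UV
radiation (UVSSR) and ozone — regulate *jointly* rather than independently,
and which of those joint responses are super-additive (synergistic)?

The package is written for analysts working with 2×2 co-exposure designs
(control, stressor A, stressor B, co-exposure) measured by bulk RNA-seq,
with a companion phenotype readout such as CIELAB L\* lightness. Because
such datasets are rarely public, it ships a ground-truthed negative-binomial
simulator so the whole chain is testable end to end.

## The model

Per gene, log2 expression is regressed on the saturated 2×2 design

```
y = mu + a·u + b·o + c·(u·o) + e,     u, o ∈ {0, 1}
```

* `a`, `b` — simple main effects: UVSSR-vs-control and ozone-vs-control
  log2 fold changes,
* `c` — interaction: departure of the co-exposure response from additivity;
  the co-exposure log2FC is `a + b + c`,
* marginal main effects `a + c/2`, `b + c/2` (balanced-design average of a
  factor's effect over the other factor's levels).

Genes with interaction p < 0.05 are classified into eight expression-profile
components by the signs of `(a, b, a+b+c)`: **cooperative** when the two
single-stressor effects share a direction (further **concordant** /
**discordant** by whether co-exposure follows that direction) and
**competitive** when they oppose (**UVSSR-dominant** / **ozone-dominant** by
which stressor the co-exposure response follows). Each classified gene gets
a synergy score

```
score = log2( |a + b + c| / |a + b| )
```

positive when the co-exposure effect exceeds the additive expectation; genes
with a positive score and a significant main effect (p < 0.05, linear
|FC| > 1.2) are called synergy genes. Supporting stages: Welch-test
differential expression per arm (DEG: p < 0.05, |FC| > 2), hypergeometric
over-representation analysis against GMT gene sets, and one-way
ANOVA + Tukey HSD for the phenotype.

## Worked example

```python
import synfact as sf
from synfact.factorial import add_gate

cfg = sf.SimulationConfig(n_genes=2000, dispersion=0.05, seed=20260922)
counts, design, truth = sf.simulate_counts(cfg)           # 4 arms x 3 reps
em = sf.log_cpm(sf.filter_low_expression(counts))
fits = add_gate(sf.fit_factorial(em, design), alpha=0.05)
labels = sf.classify_all(fits)                             # 8 components
print(int(fits["gated"].sum()), "interaction genes")
```

Run as a pipeline (the `analysis/` scripts do exactly this, step by step):

```
939 interaction genes
  cooperative: 554 (59.0%)
  concordant within cooperative: 63.2%
against ground truth: sensitivity 90.8% on 400 planted genes,
  100.0% of gated planted genes receive their true component
```

Read: of 2,000 simulated genes (20% carrying planted factorial effects,
|a| = |b| = |c| = 2 log2 units), 939 pass the interaction gate — 90.8% of
the planted genes plus null genes pulled in by CPM composition shift (see
`docs/methods.md`) — and every gated planted gene lands in its true
component. The same chain is scriptable: `synfact run --config cfg.yaml
--out-dir out --seed 1`, or stage by stage via `synfact simulate / de /
factorial / classify / synergy / enrich / phenotype / report`.

The numbered scripts under `analysis/` narrate the full study on the
synthetic cohort: simulate (01), phenotype ANOVA (02), differential
expression and DEG overlaps (03), factorial fits (04), components and
synergy (05), enrichment (06), calibration and recovery (07). Each prints
its findings and writes tables under `results/`.

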