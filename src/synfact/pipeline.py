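"""End-to-end orchestration: simulate/load -> normalize -> DE -> factorial ->
classify -> score -> enrich -> report.

Every stage writes a tab-delimited table under the output directory and is
recorded in ``manifest.json`` with its parameters and the SHA-256 of each
output file, so a run is auditable and byte-reproducible: the same config and
seed give identical manifests and tables. All randomness flows from the
single run seed through stage-name-keyed substreams (SHA-256 of
"<seed>:<stage>", reduced below 2**31).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import de, enrich, factorial, io, phenotype, simulate, synergy
from .components import classify_all, component_summary


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, thresholds and options for one pipeline run.

    Exactly one input source: ``counts_path``/``design_path`` for user data,
    or ``simulation`` for synthetic data. Thresholds default to the standard
    cut-offs: DEG p < 0.05 with linear FC > 2, interaction alpha 0.05,
    synergy p < 0.05 with main-effect FC > 1.2, enrichment p and q < 0.05.
    """

    counts_path: str | None = None
    design_path: str | None = None
    gene_sets_path: str | None = None
    phenotype_path: str | None = None
    simulation: simulate.SimulationConfig | None = None
    simulate_phenotype_arms: tuple[float, float, float, float] | None = None
    phenotype_sd: float = 1.0
    phenotype_replicates: int = 5

    deg_p: float = 0.05
    deg_fc: float = 2.0
    interaction_alpha: float = 0.05
    synergy_p: float = 0.05
    synergy_fc: float = 1.2
    enrich_p: float = 0.05
    enrich_q: float = 0.05

    score_variant: str = "log2_ratio"
    main_rule: str = "either_main"
    moderation_weight: float = 0.0
    min_cpm: float = 1.0
    min_samples: int = 3
    pseudocount: float = 1.0
    seed: int = 0
    plot: bool = False

    def validate(self) -> None:
        has_paths = self.counts_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValueError("exactly one of counts_path / simulation is required")
        if has_paths and self.design_path is None:
            raise ValueError("design_path required with counts_path")
        for name in ("deg_p", "interaction_alpha", "synergy_p", "enrich_p", "enrich_q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.deg_fc < 1.0 or self.synergy_fc < 1.0:
            raise ValueError("fold-change thresholds must be >= 1")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage, write tables + manifest + summary, return the summary.

    When ground truth is available (simulated input) the summary includes
    recovery metrics: interaction-detection sensitivity and specificity at
    the gate, and component-classification accuracy among gated planted
    genes. A stage failure aborts with the stage name; a FAILED marker and
    the partial manifest are retained in the output directory.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    summary: dict = {}

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "params": params,
                "outputs": {f.name: _sha256(f) for f in files},
            }
        )

    def fail(stage: str, exc: Exception) -> StageError:
        manifest["stages"].append({"stage": stage, "status": "FAILED"})
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        _write_json(out / "manifest.json", manifest)
        return StageError(stage, exc)

    truth = None
    # --- input stage -------------------------------------------------------
    try:
        if config.simulation is not None:
            sim_cfg = dataclasses.replace(
                config.simulation, seed=stage_seed(config.seed, "simulate")
            )
            cm, design, truth = simulate.simulate_counts(sim_cfg)
            io.write_counts(cm, out / "counts.tsv")
            io.write_design(design, out / "design.tsv")
            simulate.write_truth(truth, out / "truth.tsv")
            record(
                "simulate",
                {k: v for k, v in dataclasses.asdict(sim_cfg).items()},
                [out / "counts.tsv", out / "design.tsv", out / "truth.tsv"],
            )
        else:
            cm = io.read_counts(config.counts_path)
            design = io.read_design(config.design_path)
            record("load", {"counts": config.counts_path}, [])
    except StageError:
        raise
    except Exception as exc:
        raise fail("input", exc) from exc

    # --- normalize ---------------------------------------------------------
    try:
        filtered = io.filter_low_expression(cm, config.min_cpm, config.min_samples)
        em = io.log_cpm(filtered, config.pseudocount)
        em.to_frame().to_csv(
            out / "log_cpm.tsv", sep="\t", index_label="gene_id",
            lineterminator="\n", float_format="%.6f",
        )
        record(
            "normalize",
            {
                "min_cpm": config.min_cpm,
                "min_samples": config.min_samples,
                "pseudocount": config.pseudocount,
                "genes_kept": filtered.n_genes,
                "genes_in": cm.n_genes,
            },
            [out / "log_cpm.tsv"],
        )
        summary["genes_total"] = cm.n_genes
        summary["genes_after_filter"] = filtered.n_genes
    except Exception as exc:
        raise fail("normalize", exc) from exc

    # --- differential expression ------------------------------------------
    try:
        de_results = {}
        de_files = []
        for arm in de.CONTRAST_ARMS:
            res = de.contrast_de(em, design, arm, config.deg_p, config.deg_fc)
            de_results[arm] = res
            f = out / f"de_{arm}_vs_control.tsv"
            res.to_csv(f, sep="\t", lineterminator="\n", float_format="%.6g")
            de_files.append(f)
        overlaps = de.overlap_summary(de_results)
        f = out / "deg_overlaps.tsv"
        overlaps.to_csv(f, sep="\t", lineterminator="\n", header=True)
        de_files.append(f)
        record("de", {"p_cut": config.deg_p, "fc_cut": config.deg_fc}, de_files)
        summary["deg_counts"] = {
            arm: int(res["is_deg"].sum()) for arm, res in de_results.items()
        }
        summary["deg_overlaps"] = {k: int(v) for k, v in overlaps.items()}
    except Exception as exc:
        raise fail("de", exc) from exc

    # --- factorial fit + interaction gate ----------------------------------
    try:
        fits = factorial.fit_factorial(em, design, config.moderation_weight)
        fits = factorial.add_gate(fits, config.interaction_alpha)
        f = out / "factorial_fits.tsv"
        fits.to_csv(f, sep="\t", lineterminator="\n", float_format="%.6g")
        record(
            "factorial",
            {
                "alpha": config.interaction_alpha,
                "moderation_weight": config.moderation_weight,
            },
            [f],
        )
        summary["interaction_genes"] = int(fits["gated"].sum())
        summary["interaction_gated_fraction"] = (
            float(fits["gated"].mean()) if len(fits) else float("nan")
        )
    except Exception as exc:
        raise fail("factorial", exc) from exc

    # --- component classification ------------------------------------------
    try:
        labels = classify_all(fits, gated_only=True)
        comp_summary = component_summary(labels)
        f1 = out / "component_labels.tsv"
        labels.to_csv(f1, sep="\t", lineterminator="\n", float_format="%.6g")
        f2 = out / "component_summary.tsv"
        comp_summary.to_csv(f2, sep="\t", lineterminator="\n", float_format="%.6g")
        record("classify", {}, [f1, f2])
        summary["component_counts"] = {
            name: int(row["count"])
            for (level, name), row in comp_summary.iterrows()
            if level == "component"
        }
        mode_rows = comp_summary.loc["mode"]
        summary["cooperative_fraction"] = float(
            mode_rows.loc["cooperative", "fraction"]
        )
        summary["concordant_within_cooperative"] = float(
            comp_summary.loc[("submode", "concordant"), "fraction"]
        )
        if config.plot:
            _plot_components(comp_summary, out / "component_fractions.png")
    except Exception as exc:
        raise fail("classify", exc) from exc

    # --- synergy scoring ----------------------------------------------------
    try:
        records = synergy.select_synergy_genes(
            fits,
            labels,
            p_cut=config.synergy_p,
            fc_cut=config.synergy_fc,
            main_rule=config.main_rule,
            variant=config.score_variant,
        )
        f = out / "synergy_table.tsv"
        records.to_csv(f, sep="\t", lineterminator="\n", float_format="%.6g")
        record(
            "synergy",
            {
                "p_cut": config.synergy_p,
                "fc_cut": config.synergy_fc,
                "main_rule": config.main_rule,
                "variant": config.score_variant,
            },
            [f],
        )
        selected = records[records["is_synergy"]]
        summary["synergy_genes"] = int(len(selected))
        if len(selected):
            summary["synergy_competitive_fraction"] = float(
                selected["component"]
                .isin(["UVSSR-dominant", "Ozone-dominant"])
                .mean()
            )
    except Exception as exc:
        raise fail("synergy", exc) from exc

    # --- enrichment ---------------------------------------------------------
    if config.gene_sets_path is not None:
        try:
            gsc = io.read_gmt(config.gene_sets_path)
            universe = list(em.gene_ids)
            enrich_files = []
            for list_name, genes in (
                ("interaction", list(labels.index)),
                ("synergy", list(records.index[records["is_synergy"]])),
            ):
                if not genes:
                    continue
                res = enrich.hypergeom_ora(genes, gsc, universe)
                f = out / f"enrichment_{list_name}.tsv"
                res.to_csv(f, sep="\t", lineterminator="\n", float_format="%.6g")
                enrich_files.append(f)
                summary[f"enriched_sets_{list_name}"] = int(
                    len(enrich.significant_sets(res, config.enrich_p, config.enrich_q))
                )
            record(
                "enrich",
                {"p": config.enrich_p, "q": config.enrich_q},
                enrich_files,
            )
        except Exception as exc:
            raise fail("enrich", exc) from exc

    # --- phenotype ----------------------------------------------------------
    ph = None
    try:
        if config.phenotype_path is not None:
            ph = io.read_phenotype(config.phenotype_path)
        elif config.simulate_phenotype_arms is not None:
            ph = simulate.simulate_phenotype(
                config.simulate_phenotype_arms,
                sd=config.phenotype_sd,
                replicates=config.phenotype_replicates,
                seed=stage_seed(config.seed, "phenotype"),
            )
            io.write_phenotype(ph, out / "phenotype.tsv")
        if ph is not None:
            stats_result = phenotype.anova_tukey(ph)
            f = out / "phenotype_tukey.tsv"
            stats_result.tukey.to_csv(
                f, sep="\t", index=False, lineterminator="\n", float_format="%.6g"
            )
            record("phenotype", {"anova_p": stats_result.anova_p}, [f])
            summary["phenotype_anova_p"] = stats_result.anova_p
            summary["phenotype_significant_pairs"] = int(
                stats_result.tukey["significant"].sum()
            )
    except Exception as exc:
        raise fail("phenotype", exc) from exc

    # --- recovery metrics (ground truth available) --------------------------
    if truth is not None:
        truth_kept = truth.loc[truth.index.intersection(fits.index)]
        planted = truth_kept[truth_kept["component"] != "null"]
        nulls = truth_kept[truth_kept["component"] == "null"]
        gated = set(fits.index[fits["gated"] == 1])
        sens = (
            float(planted.index.isin(gated).mean()) if len(planted) else float("nan")
        )
        spec_ = (
            float((~nulls.index.isin(gated)).mean()) if len(nulls) else float("nan")
        )
        gated_planted = planted.index[planted.index.isin(gated)]
        if len(gated_planted):
            acc = float(
                (
                    labels.loc[gated_planted, "component"]
                    == planted.loc[gated_planted, "component"]
                ).mean()
            )
        else:
            acc = float("nan")
        summary["recovery"] = {
            "interaction_sensitivity": sens,
            "interaction_specificity": spec_,
            "component_accuracy_gated": acc,
            "n_planted_kept": int(len(planted)),
        }

    _write_json(out / "summary.json", summary)
    manifest["stages"].append(
        {
            "stage": "report",
            "params": {},
            "outputs": {"summary.json": _sha256(out / "summary.json")},
        }
    )
    _write_json(out / "manifest.json", manifest)
    return summary


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _plot_components(comp_summary: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comp = comp_summary.loc["component"]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(comp.index, comp["fraction"])
    ax.set_ylabel("fraction of interaction genes")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
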