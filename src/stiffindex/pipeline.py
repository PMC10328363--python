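"""End-to-end orchestration: simulate -> preprocess -> reference fit ->
stiffness index -> screening -> thresholds -> tree -> rules -> evaluation.

Every stage writes its artifact under the run directory; the manifest
records the config snapshot, seed, per-stage row counts and output paths,
so a run is fully reproducible from config + seed. All stage constants
(0.05 entry/stay, 0.70 rate floor, 20 minimum leaf, 5-SD outlier band,
100 CV splits) live in configuration objects, not in stage logic.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import BIOMARKERS, read_cohort, write_cohort
from .constants import DEFAULT_CONSTANTS, ClinicalConstants
from .evaluation import collinearity_matrix, confusion_metrics, delong_test
from .preprocessing import derive_flags, exclude_asi_outliers, select_cohorts
from .reference import ReferenceASIModel, fit_reference_model, stiffness_index
from .screening import (
    forward_backward_select,
    rank_auc,
    roc_and_auc,
    screen_report,
    univariate_screen,
    youden_threshold,
)
from .simulate import GeneratorConfig, config_to_text, simulate_cohort
from .tree import (
    CartParams,
    binarize_features,
    extract_rules,
    grow_tree,
    predict_rates,
    prune_tree,
    repeated_cv,
    rules_to_json,
)


@dataclass
class RunManifest:
    seed: int
    version: str
    outdir: str
    config_path: str
    stages: list[dict] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0

    def add(self, name: str, outputs: list[str], rows: int | None = None) -> None:
        self.stages.append({"stage": name, "outputs": outputs, "rows": rows})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def run_pipeline(
    config: GeneratorConfig,
    outdir,
    cart: CartParams | None = None,
    frozen_coefficients: dict[str, float] | None = None,
    cohort: pd.DataFrame | None = None,
    run_repeated_cv: bool = False,
    constants: ClinicalConstants = DEFAULT_CONSTANTS,
) -> RunManifest:
    """Execute every stage, writing intermediate artifacts under ``outdir``.

    ``frozen_coefficients`` injects fixed reference-equation coefficients
    (e.g. the published ones) instead of fitting the reference cohort of
    the run. ``cohort`` skips simulation and analyses the given table.
    A stage failure raises with the stage name and row-count context.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cart = cart or CartParams(seed=config.seed)
    manifest = RunManifest(
        seed=config.seed,
        version=__version__,
        outdir=str(outdir),
        config_path=str(outdir / "config.txt"),
        started=time.time(),
    )
    (outdir / "config.txt").write_text(config_to_text(config))
    stage = "simulate"
    try:
        if cohort is None:
            cohort = simulate_cohort(config, constants)
        write_cohort(cohort, outdir / "cohort.csv")
        manifest.add(stage, ["cohort.csv"], len(cohort))

        stage = "preprocess"
        flagged = derive_flags(cohort, constants)
        filtered, n_outliers = exclude_asi_outliers(flagged, constants)
        reference, analysis, log = select_cohorts(filtered)
        write_cohort(reference, outdir / "reference.csv")
        write_cohort(analysis, outdir / "analysis.csv")
        log_lines = [f"asi outliers dropped: {n_outliers}"] + log.steps
        (outdir / "preprocess_log.txt").write_text(
            "\n".join(f"[preprocess] {line}" for line in log_lines) + "\n"
        )
        manifest.add(
            stage,
            ["reference.csv", "analysis.csv", "preprocess_log.txt"],
            len(filtered),
        )

        stage = "fit-reference"
        if frozen_coefficients is not None:
            model = ReferenceASIModel.from_coefficients(frozen_coefficients)
        else:
            model = fit_reference_model(reference)
        (outdir / "reference_model.txt").write_text(model.to_text())
        manifest.add(stage, ["reference_model.txt"], model.n_fit_)

        stage = "stiffness-index"
        scored = analysis.copy()
        result = stiffness_index(
            scored["asi_measured"].to_numpy(), model.predict(scored)
        )
        for col in result.columns:
            scored[col] = result[col].to_numpy()
        write_cohort(scored, outdir / "analysis_scored.csv")
        manifest.add(stage, ["analysis_scored.csv"], len(scored))

        stage = "univariate-screen"
        uni = univariate_screen(scored, "stiffness_class", BIOMARKERS)
        uni_table = pd.DataFrame([dataclasses.asdict(u) for u in uni])
        uni_table.to_csv(outdir / "univariate.csv", index=False)
        manifest.add(stage, ["univariate.csv"], len(uni_table))

        stage = "stepwise-logistic"
        candidates = [u.variable for u in uni if u.candidate]
        logistic = forward_backward_select(scored, candidates, "stiffness_class")
        (outdir / "logistic_model.json").write_text(
            json.dumps(dataclasses.asdict(logistic), indent=2)
        )
        manifest.add(stage, ["logistic_model.json"], logistic.n)

        stage = "youden-thresholds"
        thresholds = {
            var: youden_threshold(
                scored[var].to_numpy(), scored["stiffness_class"].to_numpy(), var
            )
            for var in logistic.variables
        }
        report_table = screen_report(uni, logistic, thresholds)
        report_table.to_csv(outdir / "thresholds.csv", index=False)
        manifest.add(stage, ["thresholds.csv"], len(report_table))

        stage = "binarize"
        features = binarize_features(scored, list(thresholds.values()))
        features.to_csv(outdir / "features.csv", index=False)
        manifest.add(stage, ["features.csv"], len(features))

        stage = "tree"
        labels = scored["stiffness_class"].to_numpy()
        grown = grow_tree(features, labels, cart)
        pruned, alpha = prune_tree(grown, features, labels, cart)
        rules = extract_rules(pruned, thresholds, cart)
        (outdir / "tree.json").write_text(
            json.dumps(
                {"alpha": alpha, "n_leaves": len(pruned.leaves()), "tree": pruned.to_dict()},
                indent=2,
            )
        )
        (outdir / "rules.json").write_text(rules_to_json(rules))
        manifest.add(stage, ["tree.json", "rules.json"], len(rules))

        stage = "evaluate"
        tree_scores = predict_rates(pruned, features)
        logit_scores = logistic.predict_proba(scored)
        comparison = delong_test(tree_scores, logit_scores, labels)
        cm = confusion_metrics((tree_scores > 0.5).astype(int), labels)
        payload = {
            "auc_tree": comparison.auc_a,
            "auc_logistic": comparison.auc_b,
            "delong_z": comparison.delong_z,
            "delong_p": comparison.delong_p,
            "n": comparison.n,
            "confusion": dataclasses.asdict(cm),
            "comparison_scope": "in-sample, full analysis cohort",
        }
        if run_repeated_cv:
            cv_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(987654321,))
            )
            mean_auc, _ = repeated_cv(features, labels, cart, cv_rng)
            payload["auc_tree_repeated_cv"] = mean_auc
        (outdir / "comparison.json").write_text(json.dumps(payload, indent=2))
        collinearity_matrix(scored, list(BIOMARKERS)).to_csv(
            outdir / "collinearity.csv"
        )
        curve_tree, _ = roc_and_auc(tree_scores, labels)
        curve_logit, _ = roc_and_auc(logit_scores, labels)
        curve_tree["model"] = "tree"
        curve_logit["model"] = "logistic"
        pd.concat([curve_logit, curve_tree]).to_csv(
            outdir / "roc_coordinates.csv", index=False
        )
        manifest.add(
            stage, ["comparison.json", "collinearity.csv", "roc_coordinates.csv"], len(labels)
        )
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed "
            f"(input rows: {len(cohort) if cohort is not None else 'n/a'}): {exc}"
        ) from exc

    manifest.finished = time.time()
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def plot_roc_panels(outdir) -> Path:
    """Two-panel ROC figure from the written coordinates (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    coords = pd.read_csv(outdir / "roc_coordinates.csv")
    comparison = json.loads((outdir / "comparison.json").read_text())
    fig, axes = plt.subplots(1, 2, figsize=(9, 4.5), sharey=True)
    for ax, model, auc in (
        (axes[0], "logistic", comparison["auc_logistic"]),
        (axes[1], "tree", comparison["auc_tree"]),
    ):
        sub = coords[coords["model"] == model]
        ax.plot(sub["fpr"], sub["tpr"], lw=1.5)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_title(f"{model} (AUC = {auc:.3f})")
        ax.set_xlabel("1 - specificity")
    axes[0].set_ylabel("sensitivity")
    fig.tight_layout()
    path = outdir / "roc_panels.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def report(outdir) -> str:
    """Human-readable run summary from the written artifacts."""
    outdir = Path(outdir)
    required = [
        "manifest.json",
        "reference_model.txt",
        "thresholds.csv",
        "rules.json",
        "comparison.json",
    ]
    for name in required:
        if not (outdir / name).exists():
            raise FileNotFoundError(f"missing artifact {name} in {outdir}")
    manifest = json.loads((outdir / "manifest.json").read_text())
    lines = [
        f"stiffness-index analysis run (seed {manifest['seed']}, "
        f"version {manifest['version']})",
        "",
        "Reference model (predicted ASI, m/s):",
    ]
    lines += [
        "  " + line for line in (outdir / "reference_model.txt").read_text().splitlines()
    ]
    thresholds = pd.read_csv(outdir / "thresholds.csv")
    lines.append("")
    lines.append("Retained classifiers (by sensitivity at the Youden cutpoint):")
    if len(thresholds):
        comparators = {"ge": ">=", "le": "<="}
        for _, row in thresholds.iterrows():
            lines.append(
                f"  {row['variable']} {comparators[row['direction']]} "
                f"{row['threshold']:.4g}  Se={row['sensitivity']:.3f} "
                f"Sp={row['specificity']:.3f} AUC={row['auc']:.3f}"
            )
    else:
        lines.append("  none retained")
    rules = json.loads((outdir / "rules.json").read_text())
    lines.append("")
    lines.append(f"Retained decision rules: {len(rules)}")
    for i, rule in enumerate(rules, start=1):
        conds = ", ".join(
            f"{c['variable']} {c['comparator']} {c['cutpoint']:.4g}"
            for c in rule["conditions"]
        )
        lines.append(
            f"  Rule {i}: if {conds} -> N={rule['leaf_n']}, "
            f"{100 * rule['positive_rate']:.1f}% positive"
        )
    comparison = json.loads((outdir / "comparison.json").read_text())
    lines.append("")
    lines.append(
        "Model comparison (in-sample): tree AUC "
        f"{comparison['auc_tree']:.3f} vs logistic AUC "
        f"{comparison['auc_logistic']:.3f}, DeLong p = {comparison['delong_p']:.3g}"
    )
    if "auc_tree_repeated_cv" in comparison:
        lines.append(
            f"Tree AUC, repeated cross-validation: "
            f"{comparison['auc_tree_repeated_cv']:.3f}"
        )
    return "\n".join(lines) + "\n"


__all__ = ["RunManifest", "run_pipeline", "report", "read_cohort", "plot_roc_panels"]
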