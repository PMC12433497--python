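"""End-to-end orchestration: data in (or simulated), phenotypes out.

``run_pipeline`` chains the full analysis — load or simulate a trial,
compute per-bird digestibility coefficients and efficiency indicators,
screen outliers with Tukey fences, compare lines with t-tests, summarise
trait coherence with masked correlations and PCA, and fit the linear
feed-efficiency prediction models — and writes every stage's table to CSV
alongside a run log with seed and attrition counts. ``render_report``
turns the resulting bundle into fixed-width summary tables with one-
decimal means, SEs in parentheses and banded p-values; rounding happens
only at render time, the CSVs carry full precision.
"""

from __future__ import annotations

import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .digestibility import compute_all_dcs
from .feed_efficiency import RFCCoefficients, compute_efficiency
from .stats import (
    CorrelationMatrix,
    ModelFit,
    PCAResult,
    correlation_matrix,
    fit_dc_model,
    fit_performance_model,
    iqr_filter,
    line_ttest,
    p_value_band,
    pca_summary,
)
from .synthetic import LineParams, SimConfig, default_sim_config, simulate_trial
from .trial_data import (
    FeedComposition,
    TrialDataset,
    TrialValidationError,
    read_trial,
    write_trial,
)

__all__ = [
    "PipelineConfig",
    "PipelineBundle",
    "StageError",
    "config_from_yaml",
    "run_pipeline",
    "render_report",
]

PERFORMANCE_TRAITS = ["dfc", "em", "dmw", "dbw", "lp"]
EFFICIENCY_TRAITS = ["fcr", "rfc"]
DC_TRAITS = ["dc_dm", "dc_fat", "dc_n", "dc_org"]
PCA_TRAITS = PERFORMANCE_TRAITS + DC_TRAITS
CORRELATION_TRAITS = EFFICIENCY_TRAITS + DC_TRAITS
MODEL_RESPONSES = ["fcr", "rfc"]
MODEL_DCS = ["dc_dm", "dc_n", "dc_org"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything one run needs. Exactly one of ``inputs``/``simulate`` is set.

    ``inputs`` maps the keys ``records``/``assays``/``feed`` to CSV paths;
    ``simulate`` is a :class:`~layerdig.synthetic.SimConfig`.
    """

    out_dir: str | Path = "results"
    inputs: dict[str, str] | None = None
    simulate: SimConfig | None = None
    rfc_coefficients: RFCCoefficients = field(default_factory=RFCCoefficients)
    rfc_per_day: bool = False
    fence_k: float = 1.5
    alpha: float = 0.05
    pca_standardize: bool = True
    equal_var: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise TrialValidationError(
                "config must set exactly one of 'inputs' (real-data mode) and "
                "'simulate' (simulation mode)"
            )
        if not 0 < self.alpha < 1:
            raise TrialValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fence_k <= 0:
            raise TrialValidationError(f"fence_k must be > 0, got {self.fence_k}")


@dataclass
class PipelineBundle:
    """All stage outputs of one run, ready for rendering or file export."""

    dataset: TrialDataset
    traits: pd.DataFrame
    retained: pd.DataFrame
    removed: dict[str, list[str]]
    line_comparison: pd.DataFrame
    correlations: dict[str, CorrelationMatrix]
    pca: dict[str, PCAResult]
    models: dict[tuple[str, str, str], ModelFit]
    ground_truth: pd.DataFrame | None
    log: list[str]


def _parse_line_params(d: dict) -> LineParams:
    return LineParams(**d)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML document.

    ``simulate`` may be the string ``default`` (two-line study conditions),
    or a full mapping with ``feed``, ``lines`` and ``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("out_dir", "rfc_per_day", "fence_k", "alpha", "pca_standardize",
                "equal_var", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "rfc_coefficients" in raw:
        kwargs["rfc_coefficients"] = RFCCoefficients(**raw["rfc_coefficients"])
    if "inputs" in raw:
        kwargs["inputs"] = dict(raw["inputs"])
    if "simulate" in raw:
        sim = raw["simulate"]
        seed = int(kwargs.get("seed", 0))
        if sim in ("default", True):
            kwargs["simulate"] = default_sim_config(seed)
        else:
            sim = dict(sim)
            sim.setdefault("seed", seed)
            sim["feed"] = FeedComposition(**sim["feed"])
            sim["lines"] = {k: _parse_line_params(v) for k, v in sim["lines"].items()}
            kwargs["simulate"] = SimConfig(**sim)
    return PipelineConfig(**kwargs)


def _trait_table(config: PipelineConfig, dataset: TrialDataset, log: list[str]) -> pd.DataFrame:
    rows = []
    for bird in dataset.birds:
        assay = dataset.assays.get(bird.bird_id)
        if assay is None:
            log.append(f"bird {bird.bird_id}: no manure assay; DCs missing")
        dcs = compute_all_dcs(bird, assay, dataset.feed) if assay is not None else None
        eff = compute_efficiency(
            bird, config.rfc_coefficients, rfc_per_day=config.rfc_per_day
        )
        flags = list(eff.flags) + (list(dcs.flags) if dcs else ["no_assay"])
        rows.append(
            {
                "bird_id": bird.bird_id,
                "line": bird.line,
                "dfc": bird.dfc,
                "dmw": bird.dmw,
                "dbw": bird.dbw,
                "lp": eff.lp,
                "em": eff.em,
                "fcr": eff.fcr,
                "rfc": eff.rfc,
                "dc_dm": dcs.dc_dm if dcs else np.nan,
                "dc_fat": dcs.dc_fat if dcs else np.nan,
                "dc_n": dcs.dc_n if dcs else np.nan,
                "dc_org": dcs.dc_org if dcs else np.nan,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Execute every stage and write the output bundle under ``config.out_dir``.

    Identical config and seed give byte-identical CSV outputs. Stage
    failures raise :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"layerdig {__version__} on python {platform.python_version()}, "
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed: {config.seed}",
    ]

    ground_truth = None
    try:
        if config.simulate is not None:
            dataset, ground_truth = simulate_trial(config.simulate)
            log.append(
                f"simulated {len(dataset)} birds in lines "
                f"{sorted(config.simulate.lines)} (seed {config.simulate.seed})"
            )
            write_trial(dataset, out)
            ground_truth.to_csv(out / "ground_truth.csv", index=False)
        else:
            dataset = read_trial(
                config.inputs["records"], config.inputs["assays"], config.inputs["feed"]
            )
            log.append(f"read {len(dataset)} birds from {config.inputs['records']}")
    except (TrialValidationError, FileNotFoundError, KeyError) as exc:
        raise StageError("load", str(exc)) from exc

    try:
        traits = _trait_table(config, dataset, log)
        traits.to_csv(out / "dcs.csv", index=False, columns=[
            "bird_id", "line", "dc_dm", "dc_fat", "dc_n", "dc_org", "flags"])
        traits.to_csv(out / "efficiency.csv", index=False, columns=[
            "bird_id", "line", "lp", "em", "dbw", "fcr", "rfc", "flags"])
    except (ValueError, KeyError) as exc:
        raise StageError("phenotypes", str(exc)) from exc

    try:
        retained, removed = iqr_filter(traits, k=config.fence_k)
        for label in sorted(removed):
            n0 = int((traits["line"] == label).sum())
            log.append(
                f"line {label}: {n0} -> {n0 - len(removed[label])} records after "
                f"k={config.fence_k} fence filter (removed: {removed[label] or 'none'})"
            )
    except (ValueError, KeyError) as exc:
        raise StageError("outlier_filter", str(exc)) from exc

    labels = sorted(retained["line"].unique())
    comparisons = []
    try:
        if len(labels) == 2:
            a, b = labels
            for trait in PERFORMANCE_TRAITS + EFFICIENCY_TRAITS + DC_TRAITS:
                lc = line_ttest(
                    retained.loc[retained["line"] == a, trait],
                    retained.loc[retained["line"] == b, trait],
                    trait,
                    equal_var=config.equal_var,
                )
                comparisons.append(
                    {
                        "trait": trait,
                        f"mean_{a}": lc.mean_a, f"se_{a}": lc.se_a, f"n_{a}": lc.n_a,
                        f"mean_{b}": lc.mean_b, f"se_{b}": lc.se_b, f"n_{b}": lc.n_b,
                        "t": lc.t_statistic, "p_value": lc.p_value,
                    }
                )
                if min(lc.n_a, lc.n_b) < 10:
                    log.append(f"t-test for {trait}: under-powered (n < 10 in a line)")
        else:
            log.append(f"{len(labels)} line(s); between-line t-tests skipped")
    except ValueError as exc:
        raise StageError("line_tests", str(exc)) from exc
    line_comparison = pd.DataFrame(comparisons)
    line_comparison.to_csv(out / "line_comparison.csv", index=False)

    correlations: dict[str, CorrelationMatrix] = {}
    pca: dict[str, PCAResult] = {}
    models: dict[tuple[str, str, str], ModelFit] = {}
    model_rows, r2_rows = [], []
    for label in labels:
        sub = retained[retained["line"] == label]
        try:
            correlations[label] = correlation_matrix(
                sub, CORRELATION_TRAITS, alpha=config.alpha
            )
        except ValueError as exc:
            raise StageError("correlations", f"line {label}: {exc}") from exc
        try:
            pca[label] = pca_summary(sub, PCA_TRAITS, standardize=config.pca_standardize)
        except ValueError as exc:
            raise StageError("pca", f"line {label}: {exc}") from exc
        for response in MODEL_RESPONSES:
            specs = [("performance", None)] + [(dc, dc) for dc in MODEL_DCS]
            for name, dc in specs:
                try:
                    fit = (
                        fit_performance_model(sub, response)
                        if dc is None
                        else fit_dc_model(sub, response, dc)
                    )
                except ValueError as exc:
                    log.append(f"model {label}/{response}/{name} skipped: {exc}")
                    continue
                models[(label, response, name)] = fit
                for _, row in fit.coefficients.iterrows():
                    model_rows.append(
                        {
                            "line": label, "trait": response, "model": name,
                            "coefficient": row["coefficient"],
                            "estimate": row["estimate"], "se": row["se"],
                            "t": row["t"], "p": row["p"],
                        }
                    )
                r2_rows.append(
                    {"line": label, "trait": response, "model": name,
                     "r_squared": fit.r_squared, "n": fit.n_obs}
                )

    corr_frames = []
    for label, cm in correlations.items():
        r_long = cm.r.stack().rename("r").reset_index()
        r_long.columns = ["trait_1", "trait_2", "r"]
        r_long["p"] = cm.p.stack().values
        r_long["significant"] = cm.significant.stack().values
        r_long.insert(0, "line", label)
        corr_frames.append(r_long)
    pd.concat(corr_frames, ignore_index=True).to_csv(out / "correlations.csv", index=False)

    pca_rows = []
    for label, pr in pca.items():
        for d, pct in enumerate(pr.explained_pct):
            for trait in pr.contributions.index:
                pca_rows.append(
                    {
                        "line": label, "dimension": d + 1, "explained_pct": pct,
                        "trait": trait,
                        "loading": pr.loadings.loc[trait].iloc[d],
                        "contribution_pct": pr.contributions.loc[trait].iloc[d],
                    }
                )
    pd.DataFrame(pca_rows).to_csv(out / "pca.csv", index=False)
    pd.DataFrame(model_rows).to_csv(out / "models.csv", index=False)
    pd.DataFrame(r2_rows).to_csv(out / "r_squared.csv", index=False)
    retained.to_csv(out / "retained_traits.csv", index=False)

    bundle = PipelineBundle(
        dataset=dataset,
        traits=traits,
        retained=retained,
        removed=removed,
        line_comparison=line_comparison,
        correlations=correlations,
        pca=pca,
        models=models,
        ground_truth=ground_truth,
        log=log,
    )
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return bundle


# ---------------------------------------------------------------------------
# Report rendering


def _fmt_mean_se(mean: float, se: float) -> str:
    return f"{mean:.1f} ({se:.1f})"


def render_report(bundle: PipelineBundle) -> str:
    """Human-readable fixed-width summary of a pipeline bundle."""
    lines: list[str] = []
    labels = sorted(bundle.retained["line"].unique())

    lines.append("Line comparison (mean (SE); two-sample t-test)")
    lines.append("-" * 56)
    if bundle.line_comparison.empty:
        lines.append("  not computed (need exactly two lines)")
    else:
        a, b = labels
        header = f"{'trait':<8}{'line ' + a:>16}{'line ' + b:>16}{'p':>10}"
        lines.append(header)
        for _, row in bundle.line_comparison.iterrows():
            lines.append(
                f"{row['trait']:<8}"
                f"{_fmt_mean_se(row[f'mean_{a}'], row[f'se_{a}']):>16}"
                f"{_fmt_mean_se(row[f'mean_{b}'], row[f'se_{b}']):>16}"
                f"{p_value_band(row['p_value']):>10}"
            )
    lines.append("")

    for label in labels:
        cm = bundle.correlations.get(label)
        if cm is None:
            continue
        lines.append(f"Correlations, line {label} (x = not significant at alpha={cm.alpha})")
        traits = list(cm.r.columns)
        lines.append("        " + "".join(f"{t:>8}" for t in traits))
        for t1 in traits:
            cells = []
            for t2 in traits:
                r = cm.r.loc[t1, t2]
                if pd.isna(r):
                    cells.append(f"{'NA':>8}")
                elif not cm.significant.loc[t1, t2]:
                    cells.append(f"{'x':>8}")
                else:
                    cells.append(f"{r:>8.2f}")
            lines.append(f"{t1:<8}" + "".join(cells))
        lines.append("")

    for label in labels:
        pr = bundle.pca.get(label)
        if pr is None:
            continue
        pct = ", ".join(
            f"dim{i + 1} {v:.1f}%" for i, v in enumerate(pr.explained_pct[:4])
        )
        lines.append(f"PCA, line {label}: explained variance {pct}")
        top1 = pr.contributions.iloc[:, 0].idxmax() if pr.contributions.shape[1] else "NA"
        lines.append(f"  largest dim1 contribution: {top1}")
    lines.append("")

    lines.append("Prediction models (response ~ predictors; OLS)")
    lines.append("-" * 72)
    if not bundle.models:
        lines.append("  no models could be fitted (insufficient or degenerate data)")
    else:
        lines.append(
            f"{'line':<6}{'resp':<6}{'model':<13}{'coef':<12}"
            f"{'est':>10}{'se':>9}{'t':>8}{'p':>9}{'R2':>7}"
        )
        for (label, response, name), fit in bundle.models.items():
            for i, row in fit.coefficients.iterrows():
                r2 = f"{fit.r_squared:.2f}" if i == 0 else ""
                lines.append(
                    f"{label:<6}{response:<6}{name:<13}{row['coefficient']:<12}"
                    f"{row['estimate']:>10.2f}{row['se']:>9.2f}{row['t']:>8.2f}"
                    f"{p_value_band(row['p']):>9}{r2:>7}"
                )
    lines.append("")
    for entry in bundle.log:
        lines.append(f"# {entry}")
    return "\n".join(lines) + "\n"
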