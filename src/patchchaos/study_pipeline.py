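"""End-to-end study orchestration.

Extracts the per-experiment metric bundle (normalized variance, spatial
autocorrelation and correlation rates, Lyapunov classification rates,
PERMANOVA R^2 for time and position), categorizes experiments into
high/medium/low-variance groups, and runs the two statistical
comparisons of the study design: HV/MV/LV group differences (one-way
ANOVA + Tukey HSD) and experiment-versus-model-ensemble differences
(two-sided Wilcoxon rank-sum with Holm correction across metrics).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from patchchaos.chaos_metrics import (
    DEFAULT_THETA_GRID,
    LE_LOWER_BOUND_THRESHOLD,
    chaos_battery,
    sliding_window_le,
)
from patchchaos.chip_topology import ChipGraph
from patchchaos.community_analysis import bray_curtis_matrix, dtw_matrix, permanova, permanova_position
from patchchaos.population_models import AbundanceSeries
from patchchaos.spatial_stats import moran_by_timestep, normalize_by_total, pairwise_spearman_holm
from patchchaos.synthetic_data import ExperimentSet

__all__ = [
    "AnalysisConfig",
    "StudySummary",
    "ComparisonReport",
    "normalized_variance",
    "categorize_experiments",
    "compare_groups",
    "compare_model_experiment",
    "summarize_experiment",
    "run_full_analysis",
]

#: metrics entering the model-vs-experiment Wilcoxon family
METRIC_FIELDS = (
    "mean_normalized_variance",
    "pct_moran_positive",
    "pct_pairs_correlated",
    "pct_jacobian_positive",
    "pct_chaotic_nonlinear",
    "pct_rosenstein_positive",
    "r2_time",
    "r2_position",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full analysis; defaults follow the study protocol."""

    n_perm_moran: int = 12_000
    n_perm_permanova: int = 999
    alpha: float = 0.05
    include_chaos: bool = True
    include_windows: bool = False   # sliding-window battery is costly; opt in
    window: int = 50
    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID
    n_boot: int = 200
    transform: str = "log1p"
    seed: int | None = 0


@dataclass
class StudySummary:
    """Metric bundle for one experiment (percentages in 0..100)."""

    experiment: int
    initial_total: float
    mean_normalized_variance: float
    pct_moran_positive: float
    pct_pairs_correlated: float
    pct_jacobian_positive: float = float("nan")
    pct_chaotic_nonlinear: float = float("nan")
    pct_rosenstein_positive: float = float("nan")
    pct_windows_unstable: float = float("nan")
    r2_time: float = float("nan")
    r2_position: float = float("nan")
    category: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ComparisonReport:
    """Experiment-vs-model Wilcoxon rank-sum results per metric."""

    table: pd.DataFrame = field(repr=False)  # metric, stat, p_raw, p_adj, medians

    def to_dict(self) -> dict:
        return {"comparison": self.table.to_dict(orient="records")}


def normalized_variance(series: AbundanceSeries) -> tuple[np.ndarray, float]:
    """Across-patch abundance variance / total abundance, per timestep.

    Uses the population variance (divide by P).  Doubling all counts
    doubles the statistic (variance scales with the square, the total
    linearly); equal patches give exactly 0.  Returns the per-timestep
    values and their mean.
    """
    totals = series.totals()
    if np.any(totals <= 0):
        raise ValueError("total abundance must be positive at every timestep")
    v = series.values.var(axis=0, ddof=0) / totals
    return v, float(v.mean())


def categorize_experiments(
    variances: Sequence[float], k: int = 3, seed: int | None = 0
) -> list[str]:
    """Group experiments into variance categories by 1-D k-means.

    Clusters log10 mean normalized variance into ``k`` groups and labels
    them by decreasing group mean: HV, MV, LV for k = 3 (C1 >= C2 >= ...
    otherwise).  Deterministic given the seed.
    """
    x = np.asarray(variances, float)
    if x.size < k:
        raise ValueError(f"need at least k={k} experiments")
    if np.any(x <= 0):
        raise ValueError("variances must be positive")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(np.log10(x)[:, None])
    order = np.argsort(-np.asarray([x[km.labels_ == c].mean() for c in range(k)]))
    names = ["HV", "MV", "LV"] if k == 3 else [f"C{i + 1}" for i in range(k)]
    label_of = {int(c): names[rank] for rank, c in enumerate(order)}
    return [label_of[int(c)] for c in km.labels_]


def compare_groups(
    summaries: Sequence[StudySummary], metric: str
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across categories plus Tukey HSD pairwise p-values.

    Returns (F, p, tidy pairwise table).  Requires categorized summaries.
    """
    df = pd.DataFrame([s.to_dict() for s in summaries])
    if df["category"].isna().any():
        raise ValueError("summaries must be categorized first")
    groups = [g[metric].to_numpy(float) for _, g in df.groupby("category")]
    names = [name for name, _ in df.groupby("category")]
    if len(groups) < 2:
        raise ValueError("need at least 2 categories")
    F, p = stats.f_oneway(*groups)
    tk = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append({"group_a": names[i], "group_b": names[j],
                         "p_tukey": float(tk.pvalue[i, j])})
    return float(F), float(p), pd.DataFrame(rows)


def compare_model_experiment(
    exp: Sequence[StudySummary],
    model: Sequence[StudySummary],
    metrics: Sequence[str] = METRIC_FIELDS,
) -> ComparisonReport:
    """Two-sided Wilcoxon rank-sum per metric, Holm-adjusted as one family."""
    if not exp or not model:
        raise ValueError("both arms must be non-empty")
    de = pd.DataFrame([s.to_dict() for s in exp])
    dm = pd.DataFrame([s.to_dict() for s in model])
    rows = []
    for metric in metrics:
        if metric not in de or metric not in dm:
            raise ValueError(f"metric {metric!r} missing in one arm")
        a = de[metric].to_numpy(float)
        b = dm[metric].to_numpy(float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size == 0 or b.size == 0:
            raise ValueError(f"metric {metric!r} has no values in one arm")
        stat, p = stats.ranksums(a, b)
        rows.append({"metric": metric, "statistic": float(stat), "p_raw": float(p),
                     "median_experiment": float(np.median(a)), "median_model": float(np.median(b))})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"], method="holm")[1]
    return ComparisonReport(table)


def null_model_chaos_rates(
    graph: ChipGraph,
    n_runs: int = 20,
    seed: int | None = 1,
    init_range: tuple[float, float] = (1159.0, 5869.0),
    transform: str = "log1p",
) -> dict[str, float]:
    """Chaos-detection rates over a stochastic null-model ensemble.

    Simulates ``n_runs`` chip experiments under the null model and runs
    both Lyapunov estimators on every patch series.  Returns percentages
    over all P x n_runs series: ``pct_jacobian_positive`` (lower bound
    above 0.01), ``pct_rosenstein_positive`` (point estimate above 0) and
    ``pct_chaotic_nonlinear`` (positive bound AND theta > 0) — the
    pipeline's false-positive chaos rate, since the null model contains
    no deterministic structure.
    """
    from patchchaos.population_models import SimulationConfig, run_stochastic_model

    rng = np.random.default_rng(seed)
    n_jac_pos = n_chaotic = n_ros_pos = n_jac = n_ros = 0
    for _ in range(n_runs):
        total = rng.uniform(*init_range)
        series = run_stochastic_model(graph, SimulationConfig(), init=total, rng=rng)
        bat = chaos_battery(series, transform=transform, seed=int(rng.integers(2**31)))
        jac = bat[bat.method == "jacobian"].dropna(subset=["lam"])
        ros = bat[bat.method == "rosenstein"].dropna(subset=["lam"])
        n_jac += len(jac)
        n_ros += len(ros)
        n_jac_pos += int((jac["lam_lb"] > LE_LOWER_BOUND_THRESHOLD).sum())
        n_chaotic += int((jac["classification"] == "chaotic_nonlinear").sum())
        n_ros_pos += int((ros["lam"] > 0).sum())
    return {
        "pct_jacobian_positive": 100.0 * n_jac_pos / n_jac,
        "pct_chaotic_nonlinear": 100.0 * n_chaotic / n_jac,
        "pct_rosenstein_positive": 100.0 * n_ros_pos / n_ros,
        "n_series": n_jac,
    }


def summarize_experiment(
    series: AbundanceSeries,
    graph: ChipGraph,
    config: AnalysisConfig,
    experiment: int = 0,
    rng: np.random.Generator | None = None,
) -> StudySummary:
    """Run the full metric battery on one experiment."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rel = normalize_by_total(series)
    _, mean_nv = normalized_variance(series)
    moran = moran_by_timestep(series, graph, n_perm=config.n_perm_moran,
                              rng=rng, alpha=config.alpha)
    pct_moran = 100.0 * float(np.mean(moran["significant"] & (moran["I"] > 0)))
    cs = pairwise_spearman_holm(rel, alpha=config.alpha)
    pct_pairs = 100.0 * cs.fraction_significant()
    out = StudySummary(
        experiment=experiment,
        initial_total=float(series.totals()[0]),
        mean_normalized_variance=mean_nv,
        pct_moran_positive=pct_moran,
        pct_pairs_correlated=pct_pairs,
    )
    if config.include_chaos:
        bat = chaos_battery(series, transform=config.transform,
                            theta_grid=config.theta_grid, n_boot=config.n_boot,
                            seed=int(rng.integers(2**31)))
        jac = bat[bat.method == "jacobian"].dropna(subset=["lam"])
        ros = bat[bat.method == "rosenstein"].dropna(subset=["lam"])
        if len(jac):
            out.pct_jacobian_positive = 100.0 * float(np.mean(jac["lam_lb"] > LE_LOWER_BOUND_THRESHOLD))
            out.pct_chaotic_nonlinear = 100.0 * float(np.mean(jac["classification"] == "chaotic_nonlinear"))
        if len(ros):
            out.pct_rosenstein_positive = 100.0 * float(np.mean(ros["lam"] > 0))
    if config.include_windows:
        fracs = []
        for k in range(series.n_patches):
            ws = sliding_window_le(series.values[k], w=config.window,
                                   transform=config.transform, theta_grid=config.theta_grid,
                                   n_boot=config.n_boot, seed=int(rng.integers(2**31)))
            fracs.append(ws.fraction("chaotic_nonlinear"))
        out.pct_windows_unstable = 100.0 * float(np.mean(fracs))
    bc = bray_curtis_matrix(series)
    out.r2_time = 100.0 * permanova(bc, np.arange(series.n_steps, dtype=float), "time",
                                    config.n_perm_permanova, rng).R2
    dtw = dtw_matrix(series)
    out.r2_position = 100.0 * permanova_position(dtw, graph, config.n_perm_permanova, rng)["position"].R2
    return out


def run_full_analysis(
    experiments: ExperimentSet,
    graph: ChipGraph,
    config: AnalysisConfig | None = None,
    model_experiments: ExperimentSet | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[StudySummary], dict]:
    """Analyze an experiment set end to end; optionally compare to a model arm.

    Returns the per-experiment summaries (categorized when >= 3 runs) and
    a JSON-serializable report; a master seed in ``config`` fixes every
    stochastic stage.  When ``out_dir`` is given, the summary table and
    report are written as CSV/JSON.
    """
    config = AnalysisConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    summaries = [
        summarize_experiment(s, graph, config, experiment=k, rng=rng)
        for k, s in enumerate(experiments.experiments)
    ]
    if len(summaries) >= 3:
        cats = categorize_experiments([s.mean_normalized_variance for s in summaries],
                                      seed=config.seed)
        for s, c in zip(summaries, cats):
            s.category = c
    report: dict = {
        "config": dataclasses.asdict(config),
        "summaries": [s.to_dict() for s in summaries],
    }
    if model_experiments is not None:
        model_summaries = [
            summarize_experiment(s, graph, config, experiment=k, rng=rng)
            for k, s in enumerate(model_experiments.experiments)
        ]
        metrics = [m for m in METRIC_FIELDS
                   if not (config.include_chaos is False and m.startswith("pct_") and
                           ("jacobian" in m or "chaotic" in m or "rosenstein" in m))]
        comparison = compare_model_experiment(summaries, model_summaries, metrics)
        report["model_summaries"] = [s.to_dict() for s in model_summaries]
        report["comparison"] = comparison.to_dict()["comparison"]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([s.to_dict() for s in summaries]).to_csv(out_dir / "study_summaries.csv", index=False)
        (out_dir / "study_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return summaries, report
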