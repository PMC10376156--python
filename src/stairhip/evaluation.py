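"""Evaluation harness: rRMSE / R^2 metrics, subject-wise leave-one-out
cross-validation, discrete-point paired t-tests and violin (KDE) summaries.

The LOO-CV protocol follows the wearable-ANN study design: for each of
``n_rounds`` training rounds and each held-out subject, a fresh network is
initialized and trained on the remaining subjects and evaluated on the
held-out subject's gait-normalized curves (17 subjects x 10 rounds = 170
trained and tested iterates at the default cohort size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import gait_events as ge
from .ann import HipAnn, TrainConfig, TrainingFailure
from .pipeline import prepare_trial
from .synth import TARGET_NAMES, TARGET_UNITS

__all__ = ["rrmse", "r_squared", "loocv", "LoocvResult",
           "discrete_point_tests", "violin_summary", "plot_violins",
           "DISCRETE_POINTS"]

DISCRETE_POINTS = (0, 30, 60, 80)  # % gait: HS, mid-stance, ~toe off, mid-swing


def rrmse(y_true, y_pred):
    """Relative RMSE in percent: RMSE over the mean of the two signal ranges."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("series must share a length of at least 2")
    denom = 0.5 * (np.ptp(y_true) + np.ptp(y_pred))
    if denom == 0.0:
        raise ValueError("rRMSE undefined: both series are constant")
    rmse = np.sqrt(np.mean((y_true - y_pred) ** 2))
    return 100.0 * rmse / denom


def r_squared(y_true, y_pred, method="ss"):
    """Coefficient of determination.

    ``method="ss"`` (default): ``1 - SS_res / SS_tot`` (may be negative).
    ``method="corr"``: squared Pearson correlation.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("series must share a length of at least 2")
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: y_true has zero variance")
    if method == "corr":
        if np.std(y_pred) == 0.0:
            return 0.0
        return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    ss_res = np.sum((y_true - y_pred) ** 2)
    return float(1.0 - ss_res / ss_tot)


def _normalized_stack(series, prepared, name, units):
    """Gait-normalize one output series of a prepared trial."""
    return ge.normalize_to_gait_percent(
        series, prepared.fs, prepared.events, t0=prepared.t0,
        metric_name=name, units=units)


@dataclass
class LoocvResult:
    """All LOO-CV iterates plus per-subject curves and aggregate summaries."""

    records: pd.DataFrame          # subject, round, output, r2, rrmse
    mean_curves: dict              # output -> (n_subjects, 101) benchmark means
    pred_curves: dict              # output -> (n_subjects, 101) predicted means
    n_subjects: int
    n_rounds: int
    failures: list = field(default_factory=list)

    @property
    def n_iterates(self):
        return self.records[["subject", "round"]].drop_duplicates().shape[0]

    def aggregate(self):
        """Mean +/- SD of each metric per output across all iterates, plus the
        grand means across outputs."""
        g = self.records.groupby("output", sort=False)[["r2", "rrmse"]]
        out = g.agg(["mean", "std"])
        out.loc["overall", ("r2", "mean")] = self.records["r2"].mean()
        out.loc["overall", ("rrmse", "mean")] = self.records["rrmse"].mean()
        return out

    def discrete_tests(self, points=DISCRETE_POINTS):
        return discrete_point_tests(self.mean_curves, self.pred_curves,
                                    points=points)

    def summary(self):
        """Text summary mirroring the benchmark-vs-ANN table layout."""
        agg = self.aggregate()
        try:
            tests = self.discrete_tests()
        except ValueError:
            tests = None  # fewer than 3 subjects: no paired tests
        lines = [
            "Leave-one-out cross-validation of the wearable-ANN workflow",
            "=" * 64,
            f"iterates: {self.n_iterates} "
            f"({self.n_subjects} subjects x {self.n_rounds} rounds)"
            + (f", training failures: {len(self.failures)}"
               if self.failures else ""),
            "-" * 64,
            f"{'output':<18}{'R^2':>14}{'rRMSE %':>16}",
        ]
        for name in TARGET_NAMES:
            r2m = agg.loc[name, ("r2", "mean")]
            r2s = agg.loc[name, ("r2", "std")]
            rrm = agg.loc[name, ("rrmse", "mean")]
            rrs = agg.loc[name, ("rrmse", "std")]
            lines.append(f"{name:<18}{r2m:>8.2f} +/-{r2s:4.2f}"
                         f"{rrm:>9.1f} +/-{rrs:5.1f}")
        lines.append(f"{'overall mean':<18}"
                     f"{agg.loc['overall', ('r2', 'mean')]:>8.2f}        "
                     f"{agg.loc['overall', ('rrmse', 'mean')]:>9.1f}")
        if tests is None:
            return "\n".join(lines)
        lines.append("-" * 64)
        lines.append("benchmark vs ANN, discrete gait points "
                     "(paired t-test, subject means)")
        lines.append(f"{'output':<18}{'gait %':>7}{'bench':>10}{'ANN':>10}"
                     f"{'t':>9}{'p':>9}")
        for _, row in tests.iterrows():
            star = " *" if row["significant"] else ""
            lines.append(
                f"{row['output']:<18}{row['gait_percent']:>7.0f}"
                f"{row['benchmark_mean']:>10.2f}{row['predicted_mean']:>10.2f}"
                f"{row['t']:>9.2f}{row['p']:>9.4f}{star}")
        return "\n".join(lines)

    def to_csv(self, path):
        self.records.to_csv(path, index=False, float_format="%.6g")


def loocv(cohort, train_config=None, n_rounds=10, seed=0, stride=32,
          hidden=(5, 5)):
    """Subject-wise leave-one-out cross-validation.

    Parameters
    ----------
    cohort : list of TrialRecord (one trial per subject)
    n_rounds : independent training rounds (fresh initialization each round)
    stride : training-row subsampling step on the 128 Hz grid (evaluation
        always uses every sample of the held-out subject)

    Any single training failure is logged in ``result.failures`` and skipped,
    not fatal.
    """
    if len(cohort) < 2:
        raise ValueError("LOO-CV needs at least two subjects")
    prepared = [prepare_trial(tr) for tr in cohort]
    # canonical subject order: the experiment (training-row stacking, seed
    # assignment) is then invariant to the order trials are passed in
    idx = [p.subject_index for p in prepared]
    if len(set(idx)) == len(idx) and min(idx) >= 0:
        prepared.sort(key=lambda p: p.subject_index)
    n_sub = len(prepared)
    records = []
    failures = []
    pred_acc = {name: np.zeros((n_sub, 101)) for name in TARGET_NAMES}
    pred_cnt = np.zeros(n_sub)
    bench = {}
    for s, p in enumerate(prepared):
        for k, name in enumerate(TARGET_NAMES):
            cm = _normalized_stack(p.Y[:, k], p, name, TARGET_UNITS[k])
            bench.setdefault(name, np.zeros((n_sub, 101)))
            bench[name][s] = cm.values.mean(axis=0)

    ss = np.random.SeedSequence(seed)
    round_seeds = ss.generate_state(n_rounds * n_sub).reshape(n_rounds, n_sub)
    for r in range(n_rounds):
        for s in range(n_sub):
            train = [p for i, p in enumerate(prepared) if i != s]
            test = prepared[s]
            model = HipAnn.from_trials(train, stride=stride, hidden=hidden)
            cfg = train_config or TrainConfig()
            cfg = TrainConfig(**{**cfg.__dict__,
                                 "seed": int(round_seeds[r, s] % (2 ** 31))})
            try:
                res = model.fit(cfg)
            except TrainingFailure as exc:
                failures.append({"round": r, "subject": s, "error": str(exc)})
                continue
            yhat = res.predict(test.X)
            pred_cnt[s] += 1
            for k, name in enumerate(TARGET_NAMES):
                true_cm = _normalized_stack(test.Y[:, k], test, name,
                                            TARGET_UNITS[k])
                pred_cm = _normalized_stack(yhat[:, k], test, name,
                                            TARGET_UNITS[k])
                pred_acc[name][s] += pred_cm.values.mean(axis=0)
                records.append({
                    "subject": s, "round": r, "output": name,
                    "r2": r_squared(true_cm.values.ravel(),
                                    pred_cm.values.ravel()),
                    "rrmse": rrmse(true_cm.values.ravel(),
                                   pred_cm.values.ravel()),
                })
    pred = {name: acc / np.maximum(pred_cnt, 1)[:, None]
            for name, acc in pred_acc.items()}
    return LoocvResult(records=pd.DataFrame(records), mean_curves=bench,
                       pred_curves=pred, n_subjects=n_sub, n_rounds=n_rounds,
                       failures=failures)


def discrete_point_tests(benchmark, predicted, points=DISCRETE_POINTS,
                         alpha=0.05):
    """Two-sided paired t-tests of benchmark vs predicted subject-level means
    at discrete gait percents.

    ``benchmark``/``predicted``: dicts output -> (n_subjects, 101) arrays (or
    a single pair of arrays).  Degenerate pairs (zero variance of the
    differences) are reported with NaN statistics and flagged ``undefined``.
    """
    if isinstance(benchmark, np.ndarray):
        benchmark = {"metric": benchmark}
        predicted = {"metric": predicted}
    grid = np.linspace(0.0, 100.0, 101)
    rows = []
    for name, bench in benchmark.items():
        pred = predicted[name]
        if bench.shape[0] < 3:
            raise ValueError("paired t-tests need at least 3 subjects")
        for pt in points:
            idx = int(np.argmin(np.abs(grid - pt)))
            b, p_ = bench[:, idx], pred[:, idx]
            diff = b - p_
            if np.allclose(diff, 0.0):
                t_stat, pval, undefined = 0.0, 1.0, False
            elif np.allclose(diff, diff[0]):
                # nonzero constant offset: zero variance of differences
                t_stat, pval, undefined = np.nan, np.nan, True
            else:
                t_stat, pval = stats.ttest_rel(b, p_)
                undefined = False
            rows.append({"output": name, "gait_percent": pt,
                         "benchmark_mean": b.mean(),
                         "predicted_mean": p_.mean(),
                         "t": t_stat, "p": pval,
                         "significant": bool(pval < alpha)
                         if not undefined else False,
                         "undefined": undefined})
    return pd.DataFrame(rows)


def violin_summary(values, grid_size=256, fence_factor=1.5, pad_factor=0.25):
    """KDE violin ingredients for one per-subject metric distribution.

    Values outside ``median +/- fence_factor * IQR`` are removed before the
    Gaussian KDE (Silverman bandwidth).  Returns a dict with the KDE grid and
    density, the median and IQR of the retained values, and the retained
    values themselves.  All-identical values yield a zero-width violin with
    ``degenerate=True``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("violin summary needs at least 3 values")
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = med - fence_factor * iqr, med + fence_factor * iqr
    retained = values[(values >= lo) & (values <= hi)]
    if retained.size == 0 or np.ptp(retained) == 0.0:
        center = retained[0] if retained.size else med
        return {"grid": np.array([center]), "density": np.array([np.inf]),
                "median": center, "iqr": (center, center),
                "retained": retained, "degenerate": True}
    kde = stats.gaussian_kde(retained, bw_method="silverman")
    pad = pad_factor * np.ptp(retained) + 4.0 * kde.factor * np.std(retained)
    grid = np.linspace(retained.min() - pad, retained.max() + pad, grid_size)
    density = kde(grid)
    return {"grid": grid, "density": density,
            "median": float(np.median(retained)),
            "iqr": tuple(np.percentile(retained, [25, 75])),
            "retained": retained, "degenerate": False}


def plot_violins(result, metric="r2", ax=None):
    """Violin plot of per-subject LOO-CV performance (one violin per output).

    Dots are per-subject means across rounds; the white dot is the median and
    the grey bar the interquartile range of the retained values.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    subject_means = (result.records
                     .groupby(["output", "subject"], sort=False)[metric]
                     .mean())
    for i, name in enumerate(TARGET_NAMES):
        vals = subject_means.loc[name].to_numpy()
        v = violin_summary(vals)
        if not v["degenerate"]:
            width = 0.35 * v["density"] / v["density"].max()
            ax.fill_betweenx(v["grid"], i - width, i + width, color="0.75")
        ax.plot(np.full(vals.size, i), vals, "o", color="0.3", ms=3)
        ax.plot([i, i], list(v["iqr"]), color="0.45", lw=4)
        ax.plot(i, v["median"], "o", color="white", mec="black", ms=6)
    ax.set_xticks(range(len(TARGET_NAMES)))
    ax.set_xticklabels(TARGET_NAMES, rotation=20)
    ax.set_ylabel({"r2": "$R^2$", "rrmse": "rRMSE (%)"}.get(metric, metric))
    return ax
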