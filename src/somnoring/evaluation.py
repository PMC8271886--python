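"""Standardized performance evaluation for sleep stagers.

Two complementary views, following the standardized assessment framework
for sleep-tracking technology:

- **Epoch level**: per-stage one-vs-rest accuracy, sensitivity and
  specificity computed per night, then summarized over nights as
  mean (SD) [95% CI]; plus pooled overall accuracy and f1 scores
  (macro / micro / weighted). For two-stage scoring, specificity for wake
  is by definition identical to sensitivity for sleep.

- **Stage-duration agreement**: Bland-Altman analysis of per-night stage
  minutes (device vs reference) with data-driven model selection. The
  difference is regressed on the reference; a significant slope gives a
  proportional bias b0 + b1*ref, otherwise the bias is the constant mean
  difference. Absolute residuals are then regressed on the reference; a
  significant slope gives heteroscedastic limits of agreement
  bias +/- 2.46*(c0 + c1*ref), where 2.46 = 1.96*sqrt(pi/2) converts the
  fitted mean absolute residual to a standard-deviation scale, otherwise
  the classic bias +/- 1.96*SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import f1_score

from .core import Hypnogram, VOCABS

#: 1.96 * sqrt(pi / 2): mean absolute residual -> 1.96 SD under normality
HETERO_LOA_MULT = 1.96 * np.sqrt(np.pi / 2.0)
SLOPE_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Epoch-level metrics
# ---------------------------------------------------------------------------

@dataclass
class EpochMetrics:
    """Per-stage group statistics and pooled summary metrics (percent scale)."""

    per_stage: pd.DataFrame      # rows: stage; cols: metric mean/sd/ci_low/ci_high
    per_night: pd.DataFrame      # rows: (night, stage); per-night raw values
    overall_accuracy: float      # pooled over all epochs, %
    f1_macro: float
    f1_micro: float
    f1_weighted: float


def _night_stage_metrics(pred: np.ndarray, ref: np.ndarray, stage: str) -> dict[str, float]:
    p = pred == stage
    r = ref == stage
    tp = int(np.sum(p & r))
    fn = int(np.sum(~p & r))
    fp = int(np.sum(p & ~r))
    tn = int(np.sum(~p & ~r))
    return {
        "accuracy": 100.0 * (tp + tn) / len(ref),
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
    }


def _group_stats(values: np.ndarray) -> dict[str, float]:
    v = values[~np.isnan(values)]
    n = len(v)
    if n == 0:
        return {"mean": np.nan, "sd": np.nan, "ci_low": np.nan, "ci_high": np.nan, "n": 0}
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
    if n > 1:
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    else:
        half = 0.0
    return {"mean": mean, "sd": sd, "ci_low": mean - half, "ci_high": mean + half, "n": n}


def epoch_metrics(pred: dict[str, Hypnogram] | list[Hypnogram],
                  ref: dict[str, Hypnogram] | list[Hypnogram],
                  scheme: str) -> EpochMetrics:
    """Epoch-by-epoch agreement between predicted and reference hypnograms.

    ``pred`` and ``ref`` pair up by key (or position); every pair must have
    equal length and the requested scheme's vocabulary.
    """
    if isinstance(pred, dict) != isinstance(ref, dict):
        raise ValueError("pred and ref must both be dicts or both be sequences")
    if isinstance(pred, dict):
        keys = sorted(pred)
        if sorted(ref) != keys:
            raise ValueError("pred and ref night ids differ")
        pairs = [(k, pred[k], ref[k]) for k in keys]
    else:
        pairs = [(str(i), p, r) for i, (p, r) in enumerate(zip(pred, ref, strict=True))]
    stages = VOCABS[scheme]
    rows = []
    all_pred, all_ref = [], []
    for night_id, p, r in pairs:
        if len(p) != len(r):
            raise ValueError(f"night {night_id}: prediction and reference lengths differ")
        ps, rs = np.asarray(p.stages), np.asarray(r.stages)
        all_pred.append(ps)
        all_ref.append(rs)
        for stage in stages:
            m = _night_stage_metrics(ps, rs, stage)
            rows.append({"night": night_id, "stage": stage, **m})
    per_night = pd.DataFrame(rows)
    per_stage = pd.DataFrame({
        (metric, stat): {
            stage: _group_stats(
                per_night.loc[per_night["stage"] == stage, metric].to_numpy()
            )[stat]
            for stage in stages
        }
        for metric in ("accuracy", "sensitivity", "specificity")
        for stat in ("mean", "sd", "ci_low", "ci_high")
    })
    per_stage.index.name = "stage"
    yp = np.concatenate(all_pred).astype(str)
    yr = np.concatenate(all_ref).astype(str)
    return EpochMetrics(
        per_stage=per_stage,
        per_night=per_night,
        overall_accuracy=100.0 * float(np.mean(yp == yr)),
        f1_macro=float(f1_score(yr, yp, average="macro")),
        f1_micro=float(f1_score(yr, yp, average="micro")),
        f1_weighted=float(f1_score(yr, yp, average="weighted")),
    )


# ---------------------------------------------------------------------------
# Bland-Altman stage-duration agreement
# ---------------------------------------------------------------------------

@dataclass
class AgreementModel:
    """Bias and limits-of-agreement model for one duration measure (minutes)."""

    measure: str
    device: np.ndarray
    reference: np.ndarray
    proportional_bias: bool          # bias = b0 + b1 * ref vs constant b0
    heteroscedastic: bool            # LoA from |resid| ~ ref regression
    b0: float
    b1: float                        # 0 when bias is constant
    sd_resid: float                  # SD of residuals (homoscedastic branch)
    c0: float                        # |resid| regression intercept
    c1: float                        # |resid| regression slope
    b0_ci: tuple[float, float]
    b1_ci: tuple[float, float]

    def bias_at(self, ref: np.ndarray) -> np.ndarray:
        return self.b0 + self.b1 * np.asarray(ref, dtype=float)

    def loa_at(self, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ref = np.asarray(ref, dtype=float)
        bias = self.bias_at(ref)
        if self.heteroscedastic:
            half = HETERO_LOA_MULT * (self.c0 + self.c1 * ref)
        else:
            half = 1.96 * self.sd_resid * np.ones_like(ref)
        return bias - half, bias + half

    @property
    def bias_text(self) -> str:
        if self.proportional_bias:
            return f"{self.b0:.2f} + {self.b1:.2f} x ref"
        return f"{self.b0:.2f} ({self.sd_resid:.2f})"

    def loa_text(self, side: str) -> str:
        sign = "-" if side == "lower" else "+"
        if self.heteroscedastic:
            return f"bias {sign} 2.46({self.c0:.2f} + {self.c1:.2f} x ref)"
        return f"bias {sign} {1.96 * self.sd_resid:.2f}"


def bland_altman(device: np.ndarray, reference: np.ndarray,
                 measure: str = "", alpha: float = SLOPE_ALPHA,
                 min_nights: int = 10) -> AgreementModel:
    """Fit the two-branch Bland-Altman agreement model to per-night minutes."""
    device = np.asarray(device, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(device) != len(reference):
        raise ValueError("device and reference must pair up")
    if len(device) < min_nights:
        raise ValueError(f"need at least {min_nights} nights, got {len(device)}")
    diff = device - reference
    X = sm.add_constant(reference)

    if np.ptp(diff) == 0 or np.ptp(reference) == 0:
        # degenerate: constant differences or constant reference
        b0, b1, prop = float(np.mean(diff)), 0.0, False
        resid = diff - b0
        b0_ci = (b0, b0)
        b1_ci = (0.0, 0.0)
    else:
        fit = sm.OLS(diff, X).fit()
        prop = bool(fit.pvalues[1] < alpha)
        ci = np.asarray(fit.conf_int())
        if prop:
            b0, b1 = float(fit.params[0]), float(fit.params[1])
            resid = diff - fit.fittedvalues
            b0_ci, b1_ci = tuple(ci[0]), tuple(ci[1])
        else:
            b0, b1 = float(np.mean(diff)), 0.0
            resid = diff - b0
            se = np.std(diff, ddof=1) / np.sqrt(len(diff))
            half = stats.t.ppf(0.975, len(diff) - 1) * se
            b0_ci, b1_ci = (b0 - half, b0 + half), (0.0, 0.0)

    sd_resid = float(np.std(resid, ddof=1)) if np.ptp(resid) > 0 else 0.0
    hetero, c0, c1 = False, 0.0, 0.0
    if np.ptp(resid) > 0 and np.ptp(reference) > 0:
        afit = sm.OLS(np.abs(resid), X).fit()
        if afit.pvalues[1] < alpha:
            hetero = True
            c0, c1 = float(afit.params[0]), float(afit.params[1])
    return AgreementModel(
        measure=measure, device=device, reference=reference,
        proportional_bias=prop, heteroscedastic=hetero,
        b0=b0, b1=b1, sd_resid=sd_resid, c0=c0, c1=c1,
        b0_ci=b0_ci, b1_ci=b1_ci,
    )


# ---------------------------------------------------------------------------
# Report tables and plots
# ---------------------------------------------------------------------------

def _fmt(mean: float, sd: float) -> str:
    return f"{mean:.2f} ({sd:.2f})"


def agreement_table(models: dict[str, dict[str, AgreementModel]]) -> pd.DataFrame:
    """Rows (Model, Measure) with device/reference means, bias and LoA text."""
    rows = []
    for model_name, measures in models.items():
        for measure, am in measures.items():
            rows.append({
                "Model": model_name,
                "Measure": measure,
                "Device": _fmt(np.mean(am.device), np.std(am.device, ddof=1)),
                "Reference": _fmt(np.mean(am.reference), np.std(am.reference, ddof=1)),
                "Bias": am.bias_text,
                "LOA.Lower": am.loa_text("lower"),
                "LOA.Upper": am.loa_text("upper"),
            })
    return pd.DataFrame(rows)


def metrics_table(models: dict[str, EpochMetrics]) -> pd.DataFrame:
    """Rows (Model, Stage) with 'mean (SD) [CI]' cells per metric."""
    rows = []
    for model_name, em in models.items():
        for stage in em.per_stage.index:
            row = {"Model": model_name, "Stage": stage}
            for metric in ("accuracy", "sensitivity", "specificity"):
                s = em.per_stage.loc[stage]
                row[metric.capitalize()] = (
                    f"{s[(metric, 'mean')]:.2f} ({s[(metric, 'sd')]:.2f}) "
                    f"[{s[(metric, 'ci_low')]:.2f}, {s[(metric, 'ci_high')]:.2f}]"
                )
            rows.append(row)
    return pd.DataFrame(rows)


def bland_altman_plot(am: AgreementModel, ax=None):
    """Scatter of difference vs reference with bias and LoA curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ref = am.reference
    ax.scatter(ref, am.device - ref, s=12, alpha=0.6)
    xs = np.linspace(ref.min(), ref.max(), 100)
    ax.plot(xs, am.bias_at(xs), color="k", label="bias")
    lo, hi = am.loa_at(xs)
    ax.plot(xs, lo, "k--", lw=0.8)
    ax.plot(xs, hi, "k--", lw=0.8, label="LoA")
    ax.set_xlabel(f"reference {am.measure} (min)")
    ax.set_ylabel("device - reference (min)")
    ax.legend(frameon=False)
    return ax


def sensitivity_boxplot(models: dict[str, EpochMetrics], metric: str = "sensitivity", ax=None):
    """Per-stage box plots of per-night values; whiskers at 1.5 x IQR."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels, data = [], []
    for model_name, em in models.items():
        for stage in em.per_stage.index:
            vals = em.per_night.loc[em.per_night["stage"] == stage, metric].dropna()
            labels.append(f"{model_name}\n{stage}")
            data.append(vals.to_numpy())
    ax.boxplot(data, tick_labels=labels, whis=1.5)
    ax.set_ylabel(f"{metric} (%)")
    return ax
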