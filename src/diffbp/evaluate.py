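"""Agreement statistics and device-standard verdicts for BP predictions.

Computes the full error panel for true-vs-predicted blood pressure —
MD/SD/MAD/MAPD, MSE/RMSE/MAE, R² and adjusted R², cumulative percentages
within 5/10/15 mmHg, the 95% CI of errors (md ± 1.96·sd), Bland–Altman
limits of agreement and the Durbin–Watson d-statistic — and grades them
against the BHS (A–D by CP5/CP10/CP15), AAMI (|MD| < 5 and SD < 8 mmHg)
and IEEE 1708 (A–D by MAD) device standards.

Conventions: differences are predicted − true; SD uses the sample convention
(ddof=1); MAPD's denominator is the true value; adjusted R² uses p = 1
predictor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.stattools import durbin_watson as _sm_dw

__all__ = [
    "ErrorStats", "GradingResult", "BlandAltman", "GradingThresholds",
    "error_stats", "bhs_grade", "aami_check", "ieee_grade",
    "bland_altman", "durbin_watson", "grade_stats", "evaluate_report",
    "render_table", "plot_report",
]

#: BHS tiers: grade -> (min CP5, min CP10, min CP15), in %.
BHS_TIERS = (("A", (60.0, 85.0, 95.0)),
             ("B", (50.0, 75.0, 90.0)),
             ("C", (40.0, 65.0, 85.0)))


@dataclass(frozen=True)
class GradingThresholds:
    """Configurable standard thresholds (defaults: published protocols;
    the IEEE A bound follows the MAD ≤ 4 mmHg table convention)."""

    aami_md: float = 5.0
    aami_sd: float = 8.0
    ieee_a: float = 4.0
    ieee_b: float = 5.0
    ieee_c: float = 6.0


@dataclass(frozen=True)
class ErrorStats:
    md: float          # mean difference (pred - true), mmHg
    sd: float          # sample SD of differences, mmHg
    mad: float         # mean absolute difference, mmHg
    mapd: float        # mean absolute percentage difference, %
    mse: float         # mmHg^2
    rmse: float        # mmHg
    mae: float         # mmHg (== mad; kept for the regression-metric panel)
    r2: float
    adj_r2: float
    cp5: float         # % of |diff| <= 5 mmHg
    cp10: float
    cp15: float
    ci95: tuple[float, float]   # md -+ 1.96*sd
    dw: float          # Durbin-Watson d (nan when residuals are all zero)
    n: int


@dataclass(frozen=True)
class GradingResult:
    bhs_grade: str
    aami_pass: bool
    ieee_grade: str


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray
    diffs: np.ndarray


def _check_pairs(true_bp, pred_bp, min_n=3):
    t = np.asarray(true_bp, dtype=float)
    p = np.asarray(pred_bp, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(f"paired 1-D series required, got {t.shape} vs {p.shape}")
    if t.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {t.size}")
    if not (np.isfinite(t).all() and np.isfinite(p).all()):
        raise ValueError("inputs must be finite")
    return t, p


def error_stats(true_bp, pred_bp) -> ErrorStats:
    """Full agreement panel for one BP target; differences are pred − true."""
    t, p = _check_pairs(true_bp, pred_bp)
    d = p - t
    n = d.size
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    mad = float(np.abs(d).mean())
    mapd = float(100.0 * np.mean(np.abs(d) / np.abs(t)))
    mse = float(np.mean(d ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 - float(np.sum(d ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    adj_r2 = (1.0 - (1.0 - r2) * (n - 1) / (n - 2)) if n > 2 else float("nan")
    cp = lambda lim: float(100.0 * np.count_nonzero(np.abs(d) <= lim) / n)
    dw = float(_sm_dw(d)) if np.sum(d ** 2) > 0 else float("nan")
    return ErrorStats(
        md=md, sd=sd, mad=mad, mapd=mapd, mse=mse, rmse=float(np.sqrt(mse)),
        mae=mad, r2=r2, adj_r2=adj_r2, cp5=cp(5.0), cp10=cp(10.0),
        cp15=cp(15.0), ci95=(md - 1.96 * sd, md + 1.96 * sd), dw=dw, n=n,
    )


def bhs_grade(cp5: float, cp10: float, cp15: float) -> str:
    """BHS grade A-D from cumulative percentages within 5/10/15 mmHg.

    A requires (>=60, >=85, >=95); B (>=50, >=75, >=90); C (>=40, >=65,
    >=85); anything weaker is D. The grade is the best tier whose three
    thresholds are all met.
    """
    cps = (cp5, cp10, cp15)
    if not all(0.0 <= c <= 100.0 for c in cps):
        raise ValueError(f"cumulative percentages must lie in [0, 100]: {cps}")
    if not cp5 <= cp10 <= cp15:
        raise ValueError(f"cumulative percentages must be monotone: {cps}")
    for grade, bounds in BHS_TIERS:
        if all(c >= b for c, b in zip(cps, bounds)):
            return grade
    return "D"


def aami_check(md: float, sd: float,
               thresholds: GradingThresholds = GradingThresholds()) -> bool:
    """AAMI verdict: pass iff |MD| < 5 mmHg and SD < 8 mmHg (strict bounds)."""
    if not (np.isfinite(md) and np.isfinite(sd)):
        raise ValueError("md and sd must be finite")
    return bool(abs(md) < thresholds.aami_md and sd < thresholds.aami_sd)


def ieee_grade(mad: float,
               thresholds: GradingThresholds = GradingThresholds()) -> str:
    """IEEE 1708 grade by mean absolute difference: A ≤ 4, B ≤ 5, C ≤ 6, else D."""
    if mad < 0 or not np.isfinite(mad):
        raise ValueError(f"mad must be finite and >= 0, got {mad}")
    if mad <= thresholds.ieee_a:
        return "A"
    if mad <= thresholds.ieee_b:
        return "B"
    if mad <= thresholds.ieee_c:
        return "C"
    return "D"


def bland_altman(true_bp, pred_bp) -> BlandAltman:
    """Bias and ±1.96·SD limits of agreement with plottable arrays."""
    t, p = _check_pairs(true_bp, pred_bp)
    d = p - t
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_lower=bias - 1.96 * sd,
                       loa_upper=bias + 1.96 * sd,
                       means=(t + p) / 2.0, diffs=d)


def durbin_watson(residuals) -> float:
    """d = Σ(e_t − e_{t−1})² / Σe_t² over time-ordered residuals; in [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if e.ndim != 1 or e.size < 3:
        raise ValueError(f"need a 1-D series of >= 3 residuals, got shape {e.shape}")
    if not np.isfinite(e).all():
        raise ValueError("residuals must be finite")
    if np.sum(e ** 2) == 0:
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(_sm_dw(e))


def grade_stats(stats: ErrorStats,
                thresholds: GradingThresholds = GradingThresholds()
                ) -> GradingResult:
    return GradingResult(
        bhs_grade=bhs_grade(stats.cp5, stats.cp10, stats.cp15),
        aami_pass=aami_check(stats.md, stats.sd, thresholds),
        ieee_grade=ieee_grade(stats.mad, thresholds),
    )


# ---------------------------------------------------------------------------
# Whole-report evaluation
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("sbp_true", "dbp_true", "sbp_pred", "dbp_pred")


def evaluate_report(predictions: pd.DataFrame | str,
                    thresholds: GradingThresholds = GradingThresholds()
                    ) -> dict:
    """Per-target (SBP, DBP) ErrorStats, grading and Bland–Altman summary.

    ``predictions`` is a DataFrame or CSV path with columns sbp_true,
    dbp_true, sbp_pred, dbp_pred, ordered in acquisition order (the
    Durbin–Watson statistic is computed over that ordering).
    """
    if not isinstance(predictions, pd.DataFrame):
        predictions = pd.read_csv(predictions)
    missing = [c for c in REQUIRED_COLUMNS if c not in predictions.columns]
    if missing:
        raise ValueError(f"predictions are missing columns: {missing}")
    report = {}
    for target in ("SBP", "DBP"):
        key = target.lower()
        t = predictions[f"{key}_true"].to_numpy(dtype=float)
        p = predictions[f"{key}_pred"].to_numpy(dtype=float)
        stats = error_stats(t, p)
        grading = grade_stats(stats, thresholds)
        ba = bland_altman(t, p)
        report[target] = {
            "stats": dataclasses.asdict(stats),
            "grading": dataclasses.asdict(grading),
            "bland_altman": {"bias": ba.bias, "loa_lower": ba.loa_lower,
                             "loa_upper": ba.loa_upper},
        }
    return report


def render_table(report: dict) -> str:
    """Human-readable summary mirroring the standard assessment columns."""
    hdr = (f"{'Target':<7}{'MAD':>7}{'MAPD%':>8}{'MD':>8}{'SD':>7}"
           f"{'CP5':>7}{'CP10':>7}{'CP15':>7}  {'BHS':>4}{'AAMI':>6}{'IEEE':>5}")
    lines = [hdr, "-" * len(hdr)]
    for target, entry in report.items():
        s, g = entry["stats"], entry["grading"]
        lines.append(
            f"{target:<7}{s['mad']:>7.2f}{s['mapd']:>8.2f}{s['md']:>8.2f}"
            f"{s['sd']:>7.2f}{s['cp5']:>7.1f}{s['cp10']:>7.1f}{s['cp15']:>7.1f}"
            f"  {g['bhs_grade']:>4}{('pass' if g['aami_pass'] else 'fail'):>6}"
            f"{g['ieee_grade']:>5}"
        )
    return "\n".join(lines)


def plot_report(predictions: pd.DataFrame, outdir) -> list[str]:
    """Bland–Altman and error-histogram figures per target; returns paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for target in ("SBP", "DBP"):
        key = target.lower()
        t = predictions[f"{key}_true"].to_numpy(dtype=float)
        p = predictions[f"{key}_pred"].to_numpy(dtype=float)
        ba = bland_altman(t, p)
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        axes[0].scatter(ba.means, ba.diffs, s=8, alpha=0.5)
        for y, style in ((ba.bias, "-"), (ba.loa_lower, "--"), (ba.loa_upper, "--")):
            axes[0].axhline(y, color="r", linestyle=style, linewidth=1)
        axes[0].set_xlabel(f"mean {target} (mmHg)")
        axes[0].set_ylabel("pred - true (mmHg)")
        axes[0].set_title(f"Bland-Altman, {target}")
        axes[1].hist(ba.diffs, bins=40)
        axes[1].set_xlabel("error (mmHg)")
        axes[1].set_title(f"Error distribution, {target}")
        fig.tight_layout()
        path = outdir / f"agreement_{key}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(str(path))
    return paths


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
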