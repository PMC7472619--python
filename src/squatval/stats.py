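"""Concurrent-validity statistics and the trial-by-variable report.

For each outcome variable and trial the paired per-subject samples from the
two systems are summarised as mean (SD) with a t-based 95% CI per system,
the paired mean difference (new system minus reference) with its 95% CI,
and a correlation coefficient: Pearson's r when both samples pass the
Shapiro-Wilk normality test at alpha = 0.05, Spearman's rho (average ranks
for ties) otherwise.  Coefficients are labelled perfect / very strong /
moderate / fair / poor on |r| with breakpoints 1.0 / 0.8 / 0.6 / 0.3; the
sign is reported separately.  Significance is flagged at p < 0.05 per test,
with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ValidityRow",
    "shapiro_wilk",
    "correlation",
    "classify_strength",
    "mean_sd_ci",
    "mean_diff_ci",
    "build_validity_table",
    "render_text_table",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ValidityRow:
    """One variable x trial agreement summary (degrees; Table-style)."""

    variable: str
    trial: int
    n: int
    mean_ref: float
    sd_ref: float
    ci_ref: tuple[float, float]
    mean_new: float
    sd_new: float
    ci_new: tuple[float, float]
    mean_diff: float
    ci_diff: tuple[float, float]
    coefficient: float
    kind: str  # "pearson" or "spearman"
    strength: str
    p_value: float
    significant: bool


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def correlation(a: np.ndarray, b: np.ndarray) -> tuple[float, str, float]:
    """Normality-gated correlation between paired samples.

    Pearson's r if both vectors pass Shapiro-Wilk at alpha = 0.05,
    otherwise Spearman's rho with average ranks for ties.  Returns
    (coefficient, kind, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("need n >= 3 for a correlation test")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a zero-variance sample")
    normal = shapiro_wilk(a)[1] >= ALPHA and shapiro_wilk(b)[1] >= ALPHA
    if normal:
        r, p = sps.pearsonr(a, b)
        return float(r), "pearson", float(p)
    rho, p = sps.spearmanr(a, b)
    return float(rho), "spearman", float(p)


def classify_strength(coefficient: float) -> str:
    """Strength label on |coefficient| with breakpoints {0.3, 0.6, 0.8, 1.0}.

    perfect (|r| = 1), very strong (0.8 <= |r| < 1), moderate
    (0.6 <= |r| < 0.8), fair (0.3 <= |r| < 0.6), poor (|r| < 0.3).
    """
    c = abs(float(coefficient))
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"correlation coefficient out of range: {coefficient}")
    if c == 1.0:
        return "perfect"
    if c >= 0.8:
        return "very strong"
    if c >= 0.6:
        return "moderate"
    if c >= 0.3:
        return "fair"
    return "poor"


def mean_sd_ci(
    x: np.ndarray, confidence: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Sample mean, SD (n-1 denominator) and t-based confidence interval."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2 for mean/SD/CI")
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    h = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / np.sqrt(n))
    return m, sd, (m - h, m + h)


def ci_from_summary(
    mean: float, sd: float, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """t-based CI reconstructed from printed summary statistics."""
    if n < 2:
        raise ValueError("need n >= 2")
    h = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / np.sqrt(n))
    return (mean - h, mean + h)


def mean_diff_ci(
    a: np.ndarray, b: np.ndarray, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Paired mean difference b - a (new minus reference) with t-based CI."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    if np.ptp(d) == 0:
        m = float(np.mean(d))
        return m, (m, m)
    m, _, ci = mean_sd_ci(d, confidence)
    return m, ci


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _paired(
    peaks_ref: pd.DataFrame, peaks_new: pd.DataFrame, variable: str, trial: int
) -> tuple[np.ndarray, np.ndarray]:
    ref = peaks_ref[peaks_ref["trial"] == trial].set_index("subject")[variable]
    new = peaks_new[peaks_new["trial"] == trial].set_index("subject")[variable]
    missing = sorted(set(ref.index) ^ set(new.index))
    if missing:
        raise ValueError(
            f"unpaired subjects for {variable} trial {trial}: {missing}"
        )
    subjects = sorted(ref.index)
    return ref.loc[subjects].to_numpy(), new.loc[subjects].to_numpy()


def build_validity_table(
    peaks_ref: pd.DataFrame,
    peaks_new: pd.DataFrame,
    variables: tuple[str, ...] = (
        "knee_flexion", "hip_flexion", "hip_sway", "spine_flexion", "spine_sway",
    ),
) -> pd.DataFrame:
    """Agreement report: one row per variable per trial.

    Inputs are peaks tables (columns subject, trial, modality + variables)
    for the reference and the new system.  Raises on missing subject/trial
    pairs, listing them.
    """
    trials = sorted(set(peaks_ref["trial"]) | set(peaks_new["trial"]))
    rows = []
    for trial in trials:
        for var in variables:
            a, b = _paired(peaks_ref, peaks_new, var, trial)
            if len(a) < 3:
                raise ValueError(f"need >= 3 paired subjects, got {len(a)} "
                                 f"for {var} trial {trial}")
            m_ref, sd_ref, ci_ref = mean_sd_ci(a)
            m_new, sd_new, ci_new = mean_sd_ci(b)
            md, ci_d = mean_diff_ci(a, b)
            r, kind, p = correlation(a, b)
            rows.append(
                ValidityRow(
                    variable=var,
                    trial=int(trial),
                    n=len(a),
                    mean_ref=m_ref,
                    sd_ref=sd_ref,
                    ci_ref=ci_ref,
                    mean_new=m_new,
                    sd_new=sd_new,
                    ci_new=ci_new,
                    mean_diff=md,
                    ci_diff=ci_d,
                    coefficient=r,
                    kind=kind,
                    strength=classify_strength(r),
                    p_value=p,
                    significant=p < ALPHA,
                )
            )
    recs = []
    for r in rows:
        recs.append(
            {
                "variable": r.variable,
                "trial": r.trial,
                "n": r.n,
                "mean_ref": round(r.mean_ref, 1),
                "sd_ref": round(r.sd_ref, 1),
                "ci_ref_low": round(r.ci_ref[0], 1),
                "ci_ref_high": round(r.ci_ref[1], 1),
                "mean_new": round(r.mean_new, 1),
                "sd_new": round(r.sd_new, 1),
                "ci_new_low": round(r.ci_new[0], 1),
                "ci_new_high": round(r.ci_new[1], 1),
                "mean_diff": round(r.mean_diff, 1),
                "ci_diff_low": round(r.ci_diff[0], 1),
                "ci_diff_high": round(r.ci_diff[1], 1),
                "coefficient": round(r.coefficient, 3),
                "kind": r.kind,
                "strength": r.strength,
                "p_value": float(f"{r.p_value:.3g}"),
                "significant": r.significant,
            }
        )
    return pd.DataFrame(recs)


def render_text_table(table: pd.DataFrame) -> str:
    """Plain-text agreement table, one block per trial.

    Column order mirrors the report: per-system mean (SD) (95% CI), mean
    difference (95% CI), correlation with kind and strength.  Footer notes
    the per-test alpha (no multiple-testing correction).
    """
    lines = []
    for trial, grp in table.groupby("trial"):
        lines.append(f"Trial {trial}")
        header = (
            f"{'variable':<16}{'reference (deg)':<26}{'new system (deg)':<26}"
            f"{'mean diff (95% CI)':<22}{'correlation':<26}"
        )
        lines.append(header)
        lines.append("-" * len(header))
        for _, r in grp.iterrows():
            ref = f"{r.mean_ref:.1f} ({r.sd_ref:.1f}) ({r.ci_ref_low:.1f}-{r.ci_ref_high:.1f})"
            new = f"{r.mean_new:.1f} ({r.sd_new:.1f}) ({r.ci_new_low:.1f}-{r.ci_new_high:.1f})"
            diff = f"{r.mean_diff:.1f} ({r.ci_diff_low:.1f}-{r.ci_diff_high:.1f})"
            sym = "r" if r.kind == "pearson" else "rho"
            sig = "*" if r.significant else ""
            corr = f"{sym}={r.coefficient:.3f}{sig} ({r.strength})"
            lines.append(f"{r.variable:<16}{ref:<26}{new:<26}{diff:<22}{corr:<26}")
        lines.append("")
    lines.append("mean diff = new system - reference; * p < 0.05 per test "
                 "(no multiple-testing correction)")
    return "\n".join(lines)
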