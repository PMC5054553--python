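"""Agreement statistics for comparing two Ki-67 examination series.

Spearman's rank correlation (with the large-sample t approximation for the
p-value) measures monotone concordance; Bland-Altman analysis reports the
mean difference and 1.96-SD limits of agreement, on a linear scale or --
because Ki-67 indices are far from uniformly distributed and the
clinically relevant cut-offs sit at low values -- on a base-10 logarithmic
scale with a small offset so zero indices remain representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, ValidationError

#: Offset added before taking log10 so Ki-67 = 0 cases stay finite.
LOG_OFFSET = 0.1
#: Limits of agreement multiplier (standard 95% Bland-Altman).
LOA_SD_MULTIPLIER = 1.96


@dataclass
class AgreementReport:
    spearman_rho: float | None
    p_value: float | None
    mean_difference: float
    sd_difference: float
    limits_of_agreement: tuple[float, float]
    differences: np.ndarray
    means: np.ndarray
    scale: str = "linear"


def _validate_pair(a, b, min_len=1):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("series must be 1-D and of equal length")
    if len(a) < min_len:
        raise ValidationError(f"series must have length >= {min_len}")
    return a, b


def spearman_rho(series_a, series_b) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, p).  Errors on length mismatch, length < 3, or a
    constant series (the rank correlation is undefined there).
    """
    a, b = _validate_pair(series_a, series_b, min_len=3)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValidationError("spearman_rho undefined for a constant series")
    res = sps.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def bland_altman(series_a, series_b, scale: str = "linear",
                 log_offset: float = LOG_OFFSET) -> AgreementReport:
    """Bland-Altman agreement of two paired series.

    Differences (a - b) against means ((a + b)/2) on the chosen scale;
    ``scale='log'`` applies log10(value + log_offset) first and errors if
    any offset value is non-positive.
    """
    a, b = _validate_pair(series_a, series_b, min_len=2)
    if scale == "log":
        if np.any(a + log_offset <= 0) or np.any(b + log_offset <= 0):
            raise ConfigError("log scale needs all values + offset > 0")
        a = np.log10(a + log_offset)
        b = np.log10(b + log_offset)
    elif scale != "linear":
        raise ConfigError(f"unknown scale {scale!r}")
    diffs = a - b
    means = (a + b) / 2.0
    md = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    loa = (md - LOA_SD_MULTIPLIER * sd, md + LOA_SD_MULTIPLIER * sd)
    try:
        rho, p = spearman_rho(series_a, series_b)
    except ValidationError:
        rho, p = None, None
    return AgreementReport(
        spearman_rho=rho,
        p_value=p,
        mean_difference=md,
        sd_difference=sd,
        limits_of_agreement=loa,
        differences=diffs,
        means=means,
        scale=scale,
    )


def plot_bland_altman(report: AgreementReport, ax=None, title: str = ""):
    """Render the standard Bland-Altman panel (scatter, bias, limits)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report.means, report.differences, s=18, alpha=0.7)
    ax.axhline(report.mean_difference, color="k", lw=1.2, label="mean difference")
    for lim in report.limits_of_agreement:
        ax.axhline(lim, color="r", lw=1.0, ls="--")
    unit = "log10 Ki-67" if report.scale == "log" else "Ki-67 (%)"
    ax.set_xlabel(f"mean of the two examinations [{unit}]")
    ax.set_ylabel(f"difference [{unit}]")
    if title:
        ax.set_title(title)
    return ax
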