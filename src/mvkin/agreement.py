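"""Concurrent-validation statistics for paired joint-angle waveforms.

Two measurement protocols (e.g. a markerless pipeline and a marker-based
reference) produce cycle-segmented, time-normalized joint-angle curves.
Their agreement is summarized by:

* the inter-protocol coefficient of multiple correlation (CMC), a
  variance-ratio statistic jointly sensitive to correlation, gain and
  offset — 1 for perfectly overlapping curves, NaN ("complex") when the
  mean inter-protocol offset exceeds the grand mean range of motion;
* Pearson's r pooled over all cycles and frames (correlation alone);
* paired per-cycle range-of-motion differences with a Shapiro-Wilk
  normality check and a paired t-test (gain);
* Bland-Altman bias and 95% limits of agreement, bias ± 1.96 sd of the
  pooled differences, with a heteroscedasticity flag (offset).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mvkin.timeseries import CycleSet, segment_and_normalize

__all__ = [
    "WaveformSet",
    "AgreementReport",
    "cmc_interprotocol",
    "classify_cmc",
    "pearson_pooled",
    "rom_error_test",
    "RomErrorResult",
    "bland_altman",
    "BlandAltmanResult",
    "rmse",
    "summarize",
    "bland_altman_plot",
]

ALPHA = 0.05  # significance threshold used throughout (5% level)


@dataclass
class WaveformSet:
    """Cycle-segmented waveforms of two protocols.

    ``Y`` has shape (2, G, F): protocol, cycle, normalized frame.
    """

    Y: np.ndarray
    angle_name: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 3 or self.Y.shape[0] != 2:
            raise ValueError("Y must have shape (2, cycles, frames)")
        if np.isnan(self.Y).any():
            raise ValueError("waveform sets must not contain missing samples")

    @property
    def n_cycles(self) -> int:
        return self.Y.shape[1]

    @property
    def n_frames(self) -> int:
        return self.Y.shape[2]


def cmc_interprotocol(w: WaveformSet) -> float:
    """Inter-protocol coefficient of multiple correlation.

    With protocols p = 1..P (P = 2), cycles g = 1..G and frames f = 1..F::

        CMC = sqrt(1 - [sum_gpf (Y_pgf - Ybar_gf)^2 / (G F (P-1))]
                       / [sum_gpf (Y_pgf - Ybar_g)^2 / (G (P F - 1))])

    where ``Ybar_gf`` is the between-protocol mean at frame f of cycle g and
    ``Ybar_g`` the grand mean of cycle g over protocols and frames.  When
    the inter-protocol offset exceeds the grand mean range of motion the
    radicand goes negative and the CMC is complex; it is reported as NaN.
    Two identical constant protocols have no variance at all and return 1
    by convention (with a warning).
    """
    Y = w.Y
    P, G, F = Y.shape
    if G < 1 or F < 2:
        raise ValueError("need at least one cycle and two frames")
    mean_gf = Y.mean(axis=0)  # (G, F) between-protocol mean per frame
    mean_g = Y.mean(axis=(0, 2))  # (G,) grand mean per cycle
    num = np.sum((Y - mean_gf[None]) ** 2) / (G * F * (P - 1))
    den = np.sum((Y - mean_g[None, :, None]) ** 2) / (G * (P * F - 1))
    if den == 0.0:
        warnings.warn("degenerate waveforms: zero grand variance, CMC = 1", stacklevel=2)
        return 1.0
    radicand = 1.0 - num / den
    if radicand < 0.0:
        return math.nan
    return math.sqrt(radicand)


def classify_cmc(cmc: float) -> str:
    """Interpretation bands: >=0.95 excellent, 0.85-0.94 very good,
    0.75-0.84 good, below poor; NaN (complex) means no agreement at all."""
    if math.isnan(cmc):
        return "none"
    if cmc >= 0.95:
        return "excellent"
    if cmc >= 0.85:
        return "very good"
    if cmc >= 0.75:
        return "good"
    return "poor"


def pearson_pooled(w: WaveformSet) -> float:
    """Pearson correlation pooled over all (cycle, frame) pairs."""
    a = w.Y[0].ravel()
    b = w.Y[1].ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation: a protocol has zero variance")
    return float(stats.pearsonr(a, b).statistic)


@dataclass
class RomErrorResult:
    rom_per_cycle: np.ndarray  # (2, G)
    diffs: np.ndarray  # (G,) protocol1 - protocol2
    mean: float
    sd: float
    shapiro_p: float = math.nan
    ttest_p: float = math.nan
    normal: bool = True


def rom_error_test(w: WaveformSet) -> RomErrorResult:
    """Paired per-cycle range-of-motion differences (gain agreement).

    ROM is max - min per cycle per protocol.  With at least 3 cycles, the
    paired differences are checked for normality (Shapiro-Wilk) and tested
    against zero mean with a paired t-test; with fewer cycles the metrics
    are still returned but the p-values are absent (with a warning).
    """
    rom = w.Y.max(axis=2) - w.Y.min(axis=2)  # (2, G)
    diffs = rom[0] - rom[1]
    G = len(diffs)
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1)) if G > 1 else math.nan
    if G < 3:
        warnings.warn("fewer than 3 cycles: ROM tests not performed", stacklevel=2)
        return RomErrorResult(rom, diffs, mean, sd)
    if np.allclose(diffs, diffs[0]):
        # identical differences: normality test undefined, t-test degenerate
        return RomErrorResult(rom, diffs, mean, sd, math.nan,
                              0.0 if abs(mean) > 0 else 1.0, True)
    shapiro_p = float(stats.shapiro(diffs).pvalue)
    ttest_p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
    return RomErrorResult(rom, diffs, mean, sd, shapiro_p, ttest_p, shapiro_p >= ALPHA)


@dataclass
class BlandAltmanResult:
    bias: float
    loa: tuple  # (lo, hi) = bias -/+ 1.96 sd
    sd: float
    heteroscedastic: bool
    differences: np.ndarray  # pooled per-point differences
    means: np.ndarray  # pooled per-point means
    shapiro_p: float = math.nan  # normality of per-cycle mean differences
    bias_ttest_p: float = math.nan
    hetero_p: float = math.nan


def bland_altman(w: WaveformSet) -> BlandAltmanResult:
    """Bland-Altman agreement over all angular points at all time instances.

    Differences ``d = Y1 - Y2`` are pooled over cycles and frames; the bias
    is their mean and the 95% limits of agreement are bias ± 1.96 sd, the
    interval within which 95% of differences are expected if they are
    normal.  The normality of the per-cycle mean differences is checked
    before testing the bias against zero.  Heteroscedasticity is flagged
    when |d| correlates significantly with the paired means.
    """
    d = (w.Y[0] - w.Y[1]).ravel()
    m = 0.5 * (w.Y[0] + w.Y[1]).ravel()
    if d.size < 2:
        raise ValueError("need at least 2 pooled points")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    cycle_means = (w.Y[0] - w.Y[1]).mean(axis=1)
    shapiro_p = math.nan
    ttest_p = math.nan
    if len(cycle_means) >= 3 and not np.allclose(cycle_means, cycle_means[0]):
        shapiro_p = float(stats.shapiro(cycle_means).pvalue)
        ttest_p = float(stats.ttest_1samp(cycle_means, 0.0).pvalue)
    hetero_p = math.nan
    hetero = False
    if sd > 0 and np.std(m) > 0:
        r = stats.pearsonr(np.abs(d), m)
        hetero_p = float(r.pvalue)
        hetero = hetero_p < ALPHA
    return BlandAltmanResult(bias, loa, sd, hetero, d, m, shapiro_p, ttest_p, hetero_p)


def rmse(w: WaveformSet) -> float:
    """Root-mean-square of the pooled inter-protocol differences."""
    d = w.Y[0] - w.Y[1]
    return float(np.sqrt(np.mean(d ** 2)))


@dataclass
class AgreementReport:
    """One joint angle's full agreement row."""

    angle: str
    task: str
    cmc: float
    cmc_class: str
    pearson_r: float
    rom_err_mean: float
    rom_err_sd: float
    rom_shapiro_p: float
    rom_ttest_p: float
    mean_err: float
    loa_lo: float
    loa_hi: float
    ba_shapiro_p: float
    bias_ttest_p: float
    heteroscedastic: bool
    rmse: float
    flags: str = ""


def build_waveform_set(
    test_signal: np.ndarray,
    ref_signal: np.ndarray,
    cycles: CycleSet,
    angle_name: str = "",
    task: str = "",
) -> WaveformSet:
    """Segment and time-normalize two protocols on the same events."""
    a = segment_and_normalize(test_signal, cycles)
    b = segment_and_normalize(ref_signal, cycles)
    return WaveformSet(np.stack([a, b]), angle_name, task)


def summarize(
    test_angles: dict,
    ref_angles: dict,
    cycles: CycleSet,
    task: str = "",
) -> pd.DataFrame:
    """Long-format agreement table, one row per joint angle.

    Degenerate angles (zero variance, too few cycles) are flagged in the
    ``flags`` column rather than aborting the table.
    """
    rows = []
    for angle in test_angles:
        if angle not in ref_angles:
            continue
        flags = []
        w = build_waveform_set(test_angles[angle], ref_angles[angle], cycles, angle, task)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmc = cmc_interprotocol(w)
            try:
                r = pearson_pooled(w)
            except ValueError:
                r = math.nan
                flags.append("zero-variance")
            rom = rom_error_test(w)
            ba = bland_altman(w)
        if math.isnan(cmc):
            flags.append("complex-cmc")
        if not rom.normal:
            flags.append("rom-non-normal")
        rows.append(
            AgreementReport(
                angle=angle,
                task=task,
                cmc=cmc,
                cmc_class=classify_cmc(cmc),
                pearson_r=r,
                rom_err_mean=rom.mean,
                rom_err_sd=rom.sd,
                rom_shapiro_p=rom.shapiro_p,
                rom_ttest_p=rom.ttest_p,
                mean_err=ba.bias,
                loa_lo=ba.loa[0],
                loa_hi=ba.loa[1],
                ba_shapiro_p=ba.shapiro_p,
                bias_ttest_p=ba.bias_ttest_p,
                heteroscedastic=ba.heteroscedastic,
                rmse=rmse(w),
                flags=";".join(flags),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])


def bland_altman_plot(w: WaveformSet, ax=None):
    """Difference-vs-mean plot with solid bias and dotted LoA lines."""
    import matplotlib.pyplot as plt

    ba = bland_altman(w)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba.means, ba.differences, s=4, alpha=0.4)
    ax.axhline(ba.bias, color="k", lw=2)
    for y in ba.loa:
        ax.axhline(y, color="k", ls=":")
    ax.set_xlabel("mean of protocols (deg)")
    ax.set_ylabel("difference (deg)")
    ax.set_title(w.angle_name or "Bland-Altman")
    return ax
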