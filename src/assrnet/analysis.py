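"""Spectral measures, inter-trial phase coherence and estimation statistics.

The two headline spectral measures follow the stimulation-response naming
convention: *4040* is evoked power at 40 Hz under 40 Hz drive, *2040* the
power at the 20 Hz subharmonic under the same drive (beat-skipping moves
power from 4040 to 2040).  Evoked power is computed on the across-trial
average of the LFP (phase-locked component), with a Welch PSD integrated
over ±2 Hz bands.  Inter-trial phase coherence (ITC) at 40 Hz uses Morlet
wavelet phases: ITC(t) is the modulus of the across-trial mean unit phasor,
averaged over the analysis window; 1 means perfect phase locking, and for n
trials of pure noise the expected value is √π/(2√n) (Rayleigh).

Group comparisons use estimation statistics rather than hypothesis tests:
the mean difference between per-subject values of a condition and the shared
control, with a percentile bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "SpectralSummary",
    "ITCSummary",
    "GroupEstimate",
    "evoked_psd",
    "band_power",
    "itc",
    "rayleigh_itc_null",
    "mean_difference",
    "correlate",
    "subject_measures",
    "cohort_table",
    "group_table",
]

BAND_HALF_WIDTH_HZ = 2.0


@dataclass(frozen=True)
class SpectralSummary:
    freqs: np.ndarray          # Hz
    psd: np.ndarray            # a.u.²/Hz, PSD of the evoked (trial-averaged) LFP
    power_4040: float          # ∫ PSD over 38–42 Hz
    power_2040: float          # ∫ PSD over 18–22 Hz

    def __post_init__(self):
        if np.any(self.psd < 0):
            raise ValueError("PSD must be non-negative")
        if self.power_4040 < 0 or self.power_2040 < 0:
            raise ValueError("band powers must be non-negative")


@dataclass(frozen=True)
class ITCSummary:
    itc_40: float              # time-averaged ITC at 40 Hz, in [0, 1]
    itc_t: np.ndarray          # ITC(t) over the analysis window
    window: tuple[float, float]
    wavelet_cycles: float

    def __post_init__(self):
        if not (0.0 <= self.itc_40 <= 1.0 + 1e-9):
            raise ValueError(f"ITC must lie in [0, 1], got {self.itc_40}")


@dataclass(frozen=True)
class GroupEstimate:
    mean_difference: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    warning: Optional[str] = None

    def __post_init__(self):
        if not (self.ci_low <= self.mean_difference <= self.ci_high):
            raise ValueError("percentile CI must contain the point estimate")


def band_power(freqs: np.ndarray, psd: np.ndarray, center: float,
               half_width: float = BAND_HALF_WIDTH_HZ) -> float:
    """Integral of the PSD over [center − half_width, center + half_width]."""
    m = (freqs >= center - half_width) & (freqs <= center + half_width)
    return float(np.trapezoid(psd[m], freqs[m]))


def evoked_psd(
    trials: np.ndarray,
    fs: float = 1000.0,
    nperseg_ms: float = 500.0,
    detrend: str = "constant",
) -> SpectralSummary:
    """Evoked (phase-locked) power spectrum of a set of trials.

    ``trials`` is (n_trials, n_samples) LFP over the analysis window on a
    common time base.  Trials are averaged first — suppressing components
    whose phase varies across trials — then a Welch PSD (Hann window, 500 ms
    segments, 50 % overlap) is integrated over the 38–42 and 18–22 Hz bands.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] < 2:
        raise ValueError("evoked PSD needs at least 2 trials")
    n = trials.shape[1]
    if n / fs < 4 / 20.0:
        raise ValueError("analysis window shorter than 4 cycles of 20 Hz")
    evoked = trials.mean(axis=0)
    nperseg = min(int(round(nperseg_ms * fs / 1000.0)), n)
    freqs, psd = signal.welch(
        evoked, fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend=detrend,
    )
    return SpectralSummary(
        freqs=freqs, psd=psd,
        power_4040=band_power(freqs, psd, 40.0),
        power_2040=band_power(freqs, psd, 20.0),
    )


def _morlet_phase(x: np.ndarray, fs: float, freq: float, cycles: float) -> np.ndarray:
    """Instantaneous phase of ``x`` at ``freq`` from a complex Morlet wavelet."""
    sigma_t = cycles / (2 * np.pi * freq)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    wavelet = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    wavelet /= np.sqrt(np.sum(np.abs(wavelet) ** 2))
    conv = signal.fftconvolve(x - np.mean(x), wavelet, mode="same")
    return np.angle(conv)


def itc(
    trials: np.ndarray,
    fs: float = 1000.0,
    freq: float = 40.0,
    cycles: float = 7.0,
    window: tuple[float, float] | None = None,
) -> ITCSummary:
    """Inter-trial phase coherence at ``freq``.

    Per trial, the Morlet (``cycles``-cycle) phase time course is extracted;
    ITC(t) = |mean over trials of exp(iφ_k(t))|; the scalar ``itc_40`` is the
    time average, excluding one wavelet support at each edge.  ``window`` is
    (start, stop) in samples relative to the trial array.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    n_trials, n = trials.shape
    if n_trials < 2:
        raise ValueError("ITC needs at least 2 trials")
    phases = np.stack([_morlet_phase(x, fs, freq, cycles) for x in trials])
    itc_t = np.abs(np.mean(np.exp(1j * phases), axis=0))
    edge = int(np.ceil(cycles / freq * fs))
    lo, hi = (edge, n - edge) if window is None else window
    lo = max(int(lo), edge)
    hi = min(int(hi), n - edge)
    if hi <= lo:
        raise ValueError("analysis window too short for the wavelet support")
    return ITCSummary(
        itc_40=float(np.mean(itc_t[lo:hi])), itc_t=itc_t,
        window=(lo / fs * 1000.0, hi / fs * 1000.0), wavelet_cycles=cycles,
    )


def rayleigh_itc_null(n_trials: int) -> float:
    """Expected ITC of ``n_trials`` independent uniform phases: √π / (2√n)."""
    return float(np.sqrt(np.pi) / (2.0 * np.sqrt(n_trials)))


def mean_difference(
    condition_values: Sequence[float],
    control_values: Sequence[float],
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> GroupEstimate:
    """Bootstrap estimation statistics: mean(condition) − mean(control).

    Percentile bootstrap: both groups are resampled with replacement
    ``n_boot`` times; the CI is the (α/2, 1 − α/2) percentile interval of the
    resampled differences, widened if necessary to contain the point
    estimate (degenerate inputs).  Deterministic given ``seed``.
    """
    cond = np.asarray(condition_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if cond.size < 2 or ctrl.size < 2:
        raise ValueError("both groups need at least 2 subjects")
    warning = None
    if n_boot < 1000:
        warning = f"n_boot={n_boot} < 1000; interval may be unreliable"
    rng = np.random.default_rng(seed)
    point = float(cond.mean() - ctrl.mean())
    idx_c = rng.integers(0, cond.size, size=(n_boot, cond.size))
    idx_k = rng.integers(0, ctrl.size, size=(n_boot, ctrl.size))
    diffs = cond[idx_c].mean(axis=1) - ctrl[idx_k].mean(axis=1)
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    lo, hi = min(float(lo), point), max(float(hi), point)
    return GroupEstimate(
        mean_difference=point, ci_low=lo, ci_high=hi,
        n_boot=n_boot, seed=seed, warning=warning,
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation and two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of >= 3 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in an input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Cohort-level reporting
# ---------------------------------------------------------------------------

def subject_measures(cohort, cond: str, subject: int) -> dict:
    """4040/2040 evoked power and itc_40 for one (condition, subject)."""
    plan = cohort.plan
    lo = int(plan.analysis_start)
    hi = int(plan.analysis_stop)
    lfps = cohort.lfp_matrix(cond, subject)[:, lo:hi]
    spec = evoked_psd(lfps)
    coh = itc(lfps)
    return {
        "condition": cond, "subject": subject,
        "power_4040": spec.power_4040, "power_2040": spec.power_2040,
        "itc_40": coh.itc_40,
    }


def cohort_table(cohort, conditions: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-(condition, subject) measures for a cohort result."""
    conds = conditions or [c.label for c in cohort.plan.conditions]
    rows = [
        subject_measures(cohort, cond, s)
        for cond in conds
        for s in range(cohort.plan.n_subjects)
    ]
    return pd.DataFrame(rows)


def group_table(
    table: pd.DataFrame,
    control: str = "control",
    measure: str = "power_4040",
    n_boot: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Group-level estimation table: per condition, mean difference vs control.

    Missing conditions raise; the control row carries a zero difference with
    its own bootstrap CI (resampling control against itself).
    """
    if control not in set(table["condition"]):
        raise ValueError(f"control condition {control!r} missing from table")
    ctrl = table.loc[table.condition == control, measure].to_numpy()
    rows = []
    for i, cond in enumerate(pd.unique(table["condition"])):
        vals = table.loc[table.condition == cond, measure].to_numpy()
        est = mean_difference(vals, ctrl, n_boot=n_boot, seed=seed + i)
        rows.append({
            "condition": cond, "measure": measure, "n": vals.size,
            "mean": float(vals.mean()),
            "mean_difference": est.mean_difference,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
        })
    return pd.DataFrame(rows)
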