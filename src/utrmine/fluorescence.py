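"""Dual-fluorophore plate-reader normalization and growth-phase classification.

The measurement model: strains carry a genomic GFP whose expression tracks
biomass, plus a promoter-driven mCherry reporter. Raw signals are corrected
against a media-only control well,

    FI(fluorophore) = signal(fluorophore) - signal(media control),

then mCherry is normalized by GFP as a biomass proxy,

    RFU = FI(mCherry) / FI(GFP).

Growth phases are located on the Savitzky-Golay-smoothed OD600 curve: the
mid-exponential timepoint is where the slope is maximal, the stationary
timepoint is where the smoothed OD attains its maximum. The differential
activity is the ratio of RFU at mid-exponential over RFU at stationary;
ratios below 0.7 mark stationary-biased promoters, above 1.3
exponential-biased, and anything in between (bounds inclusive) unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PlateTimeSeries",
    "ActivityProfile",
    "QuadrantGate",
    "FIResult",
    "background_correct",
    "compute_rfu",
    "smooth_series",
    "find_growth_phases",
    "differential_activity",
    "classify_phase_bias",
    "detect_active",
    "gate_quadrant",
    "profile_strain",
]

PHASE_CLASSES = ("stationary_biased", "unbiased", "exponential_biased")


class PhaseDetectionError(ValueError):
    """OD series is flat or never grows; growth phases cannot be located."""


class NoUsableSignalError(ValueError):
    """Every timepoint is masked (GFP at or below the positivity floor)."""


@dataclass
class PlateTimeSeries:
    """Aligned plate-reader vectors for one strain plus its media controls."""

    time: np.ndarray  # hours, strictly increasing
    od600: np.ndarray
    mcherry_raw: np.ndarray
    gfp_raw: np.ndarray
    media_mcherry: np.ndarray
    media_gfp: np.ndarray
    media_od: np.ndarray | None = None
    strain: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        vecs = [self.od600, self.mcherry_raw, self.gfp_raw, self.media_mcherry, self.media_gfp]
        if self.media_od is not None:
            vecs.append(self.media_od)
        for name, v in zip(
            ("od600", "mcherry_raw", "gfp_raw", "media_mcherry", "media_gfp", "media_od"), vecs
        ):
            v = np.asarray(v, dtype=float)
            if v.shape != self.time.shape:
                raise ValueError(f"{name} length {v.size} != time length {self.time.size}")
        if self.time.size < 5:
            raise ValueError("time series needs at least 5 points")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class ActivityProfile:
    """Per-strain derived quantities: the end product of the analysis."""

    strain: str
    fi_mcherry: np.ndarray
    fi_gfp: np.ndarray
    rfu: np.ndarray
    t_midexp: float
    t_stat: float
    rfu_midexp: float
    rfu_stat: float
    differential_activity: float
    phase_class: str
    detectable: bool | None = None
    low_signal: bool = False


@dataclass(frozen=True)
class QuadrantGate:
    """Closed AU intervals defining the four flow-cytometry quadrants."""

    green_high: tuple[float, float] = (100_000.0, 500_000.0)
    green_low: tuple[float, float] = (25_000.0, 70_000.0)
    red_high: tuple[float, float] = (8_000.0, 90_000.0)
    red_low: tuple[float, float] = (3_500.0, 4_000.0)


@dataclass
class FIResult:
    """Background-corrected fluorescence with a negative-value audit mask.

    Negative FI (signal below the media control) is retained, not clamped —
    clamping would bias ratios for weak promoters — but flagged so downstream
    steps can report low-signal strains.
    """

    values: np.ndarray
    negative_mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def background_correct(signal, media_control) -> FIResult:
    """Elementwise media-background subtraction (fluorescence intensity, FI)."""
    sig = np.asarray(signal, dtype=float)
    ctrl = np.asarray(media_control, dtype=float)
    if sig.shape != ctrl.shape:
        raise ValueError(f"signal shape {sig.shape} != control shape {ctrl.shape}")
    fi = sig - ctrl
    return FIResult(values=fi, negative_mask=fi < 0)


def compute_rfu(fi_mcherry, fi_gfp, eps: float = 1e-9) -> np.ndarray:
    """Relative fluorescence units: FI(mCherry) / FI(GFP), elementwise.

    Timepoints where FI(GFP) <= ``eps`` are masked as NaN (no biomass proxy);
    if every point is masked a :class:`NoUsableSignalError` is raised.
    """
    mch = np.asarray(fi_mcherry, dtype=float)
    gfp = np.asarray(fi_gfp, dtype=float)
    if mch.shape != gfp.shape:
        raise ValueError("FI vectors must have equal length")
    rfu = np.full_like(mch, np.nan)
    ok = gfp > eps
    if not ok.any():
        raise NoUsableSignalError("GFP signal at or below the positivity floor everywhere")
    rfu[ok] = mch[ok] / gfp[ok]
    return rfu


def smooth_series(values, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    Preserves polynomials up to ``polyorder`` exactly; output length equals
    input length.
    """
    v = np.asarray(values, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if window > v.size:
        raise ValueError(f"window {window} exceeds series length {v.size}")
    return savgol_filter(v, window_length=window, polyorder=polyorder)


def find_growth_phases(od_series, time, onset_frac: float = 0.95) -> tuple[float, float]:
    """Locate the mid-exponential and stationary timepoints on a smoothed OD.

    t_midexp is the time of maximum central-difference slope; t_stat the
    earliest time attaining the maximum OD. Because mid-exponential growth by
    definition precedes the stationary plateau, the slope search is confined
    to times up to the stationary onset — the first attainment of
    ``onset_frac`` of the OD range — which keeps plateau measurement noise
    (largest in absolute terms when noise scales with signal) from producing
    spurious slope maxima. A curve whose maximum sits at the final timepoint
    never visibly plateaus, which is reported as a warning.
    """
    od = np.asarray(od_series, dtype=float)
    t = np.asarray(time, dtype=float)
    if od.size != t.size or od.size < 5:
        raise ValueError("need equal-length series of at least 5 points")
    if np.ptp(od) < 1e-12:
        raise PhaseDetectionError("flat OD series: no growth to phase")
    slope = np.gradient(od, t)
    if slope.max() <= 0:
        raise PhaseDetectionError("non-increasing OD series: no exponential phase")
    onset = int(np.argmax(od >= od.min() + onset_frac * np.ptp(od)))
    hi = max(onset, 2)
    if slope[: hi + 1].max() <= 0:  # all growth happens after the onset guess
        hi = od.size - 1
    t_midexp = float(t[int(np.argmax(slope[: hi + 1]))])
    i_stat = int(np.argmax(od))  # argmax returns the earliest maximum
    if i_stat == od.size - 1:
        warnings.warn(
            "OD maximum at the final timepoint; culture may not have reached "
            "stationary phase",
            stacklevel=2,
        )
    return t_midexp, float(t[i_stat])


def _window_mean(values: np.ndarray, time: np.ndarray, t_center: float, window: int) -> float:
    """NaN-aware mean of ``window`` samples centered on the sample nearest
    ``t_center``."""
    idx = int(np.argmin(np.abs(time - t_center)))
    half = window // 2
    lo = max(0, idx - half)
    hi = min(values.size, idx + half + 1)
    chunk = values[lo:hi]
    if np.all(np.isnan(chunk)):
        return float("nan")
    return float(np.nanmean(chunk))


def differential_activity(
    rfu, time, t_midexp: float, t_stat: float, window: int = 3
) -> float:
    """Ratio of RFU at the mid-exponential timepoint to RFU at stationary.

    Each phase value is the RFU averaged over a symmetric window of samples
    (``window=1`` gives a point estimate). A nonpositive stationary RFU makes
    the ratio undefined.
    """
    rfu = np.asarray(rfu, dtype=float)
    t = np.asarray(time, dtype=float)
    if not (t[0] <= t_midexp <= t[-1] and t[0] <= t_stat <= t[-1]):
        raise ValueError("phase timepoints must lie within the time range")
    r_mid = _window_mean(rfu, t, t_midexp, window)
    r_stat = _window_mean(rfu, t, t_stat, window)
    if not np.isfinite(r_stat) or r_stat <= 0:
        raise NoUsableSignalError(
            f"stationary-phase RFU {r_stat} is nonpositive; ratio undefined"
        )
    return r_mid / r_stat


def classify_phase_bias(ratio: float, low: float = 0.7, high: float = 1.3) -> str:
    """Three-way growth-phase bias from the differential-activity ratio.

    Strictly below ``low``: more active in stationary phase; strictly above
    ``high``: more active in exponential phase; the bounds themselves are
    unbiased.
    """
    if not np.isfinite(ratio) or ratio <= 0:
        raise ValueError(f"ratio must be positive and finite, got {ratio}")
    if ratio < low:
        return "stationary_biased"
    if ratio > high:
        return "exponential_biased"
    return "unbiased"


def detect_active(
    stationary_rfu: float, background_rfu_samples, k: float = 3.0
) -> bool:
    """Is a strain's stationary RFU above background noise?

    Detectable iff it exceeds the background strain's mean stationary RFU by
    more than ``k`` standard deviations.
    """
    bg = np.asarray(background_rfu_samples, dtype=float)
    bg = bg[np.isfinite(bg)]
    if bg.size == 0:
        raise ValueError("background profile is required for detection")
    return bool(stationary_rfu > bg.mean() + k * bg.std(ddof=1 if bg.size > 1 else 0))


def gate_quadrant(gfp_au: float, mcherry_au: float, gate: QuadrantGate = QuadrantGate()) -> str:
    """Assign a flow-cytometry event to a high/low green x red quadrant.

    Returns 'HH', 'HL', 'LH', 'LL' (first letter green, second red) or
    'ungated' for events outside every interval pair. Intervals are closed.
    """
    if gfp_au < 0 or mcherry_au < 0:
        raise ValueError("AU values must be nonnegative")

    def _in(x: float, iv: tuple[float, float]) -> bool:
        return iv[0] <= x <= iv[1]

    green = "H" if _in(gfp_au, gate.green_high) else "L" if _in(gfp_au, gate.green_low) else None
    red = "H" if _in(mcherry_au, gate.red_high) else "L" if _in(mcherry_au, gate.red_low) else None
    if green is None or red is None:
        return "ungated"
    return green + red


def profile_strain(
    ts: PlateTimeSeries,
    *,
    sg_window: int = 21,
    sg_polyorder: int = 3,
    ratio_window: int = 3,
    low: float = 0.7,
    high: float = 1.3,
    eps: float = 1e-9,
) -> ActivityProfile:
    """Run the full normalization chain for one strain.

    Background-correct both channels, form the RFU series, locate growth
    phases on the smoothed OD, and classify the differential-activity ratio.
    """
    fi_mch = background_correct(ts.mcherry_raw, ts.media_mcherry)
    fi_gfp = background_correct(ts.gfp_raw, ts.media_gfp)
    rfu = compute_rfu(fi_mch.values, fi_gfp.values, eps=eps)
    od_smooth = smooth_series(ts.od600, window=sg_window, polyorder=sg_polyorder)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_midexp, t_stat = find_growth_phases(od_smooth, ts.time)
    ratio = differential_activity(rfu, ts.time, t_midexp, t_stat, window=ratio_window)
    t = np.asarray(ts.time, dtype=float)
    return ActivityProfile(
        strain=ts.strain,
        fi_mcherry=fi_mch.values,
        fi_gfp=fi_gfp.values,
        rfu=rfu,
        t_midexp=t_midexp,
        t_stat=t_stat,
        rfu_midexp=_window_mean(rfu, t, t_midexp, ratio_window),
        rfu_stat=_window_mean(rfu, t, t_stat, ratio_window),
        differential_activity=ratio,
        phase_class=classify_phase_bias(ratio, low=low, high=high),
        low_signal=bool(fi_mch.negative_mask.any() or fi_gfp.negative_mask.any()),
    )
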