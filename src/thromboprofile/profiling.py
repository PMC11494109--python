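"""From per-channel intensity time courses to 7-dimension thrombus profiles.

The readout time point is 450 s after the onset of thrombus formation. The
profile's first dimension (size) is the platelet-channel intensity at that
time; each biomarker dimension is the (autofluorescence-corrected, where
applicable) biomarker intensity divided by the platelet intensity — its
*enrichment*. Platelet-channel growth is summarised by a three-parameter
logistic fit whose plateau-approach time (95% of plateau) is
t_half + 2.944 tau_g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .barcode import DIMENSIONS, N_DIMS

__all__ = [
    "TimeCourseSet",
    "ThrombusProfile",
    "GrowthFit",
    "OnsetNotDetected",
    "correct_autofluorescence",
    "detect_onset",
    "quantify_profile",
    "fit_growth",
    "residue_size",
    "READ_OFFSET_S",
]

READ_OFFSET_S = 450.0  # quantitation time point after onset


class OnsetNotDetected(ValueError):
    """The platelet signal never exceeded the baseline criterion."""


class FailedThrombusFormation(ValueError):
    """Zero platelet signal at the readout time: no thrombus formed."""


@dataclass(frozen=True)
class TimeCourseSet:
    """Shared time grid plus one intensity sequence per channel (AFU >= 0)."""

    times: np.ndarray
    channels: Mapping[str, np.ndarray]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        chans = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, v in chans.items():
            if v.size != t.size:
                raise ValueError(f"channel {name!r} length differs from time grid")
            if np.any(v < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
        object.__setattr__(self, "channels", chans)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **metadata) -> "TimeCourseSet":
        """Build from a tidy frame with columns time_s, channel, intensity."""
        wide = df.pivot_table(index="time_s", columns="channel", values="intensity")
        if wide.isna().any().any():
            raise ValueError("channels do not share a common time grid")
        return cls(
            times=wide.index.to_numpy(dtype=float),
            channels={c: wide[c].to_numpy(dtype=float) for c in wide.columns},
            metadata=metadata,
        )


@dataclass(frozen=True)
class ThrombusProfile:
    """The 7-dimension readout: size (AFU) + six platelet-normalised enrichments."""

    size: float
    fg: float
    vwf: float
    psel: float
    ps: float
    eplus: float
    act: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values):
            raise ValueError("profile values must be non-negative")

    @property
    def values(self) -> tuple[float, ...]:
        return (self.size, self.fg, self.vwf, self.psel, self.ps, self.eplus, self.act)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(DIMENSIONS, self.values))


@dataclass(frozen=True)
class GrowthFit:
    """Logistic growth fit A / (1 + exp(-(t - t_half)/tau_g)) of the platelet signal."""

    plateau: float
    t_half: float
    slope_scale: float  # tau_g
    onset: float
    rmse: float

    @property
    def plateau_time(self) -> float:
        """Time (from onset) at 95% of the plateau: t_half + 2.944 tau_g."""
        return self.t_half + 2.944 * self.slope_scale


def correct_autofluorescence(raw_391, platelet_channel, coeff: float) -> np.ndarray:
    """Subtract the platelet autofluorescence leak from the ~391-nm channel.

    corrected = max(raw - coeff * platelet, 0) elementwise.
    """
    raw = np.asarray(raw_391, dtype=float)
    plt = np.asarray(platelet_channel, dtype=float)
    if raw.size != plt.size:
        raise ValueError("raw and platelet channels must have equal length")
    if coeff < 0:
        raise ValueError("autofluorescence coefficient must be >= 0")
    return np.maximum(raw - coeff * plt, 0.0)


def detect_onset(
    platelet_channel,
    times,
    baseline_frames: int = 5,
    n_sd: float = 3.0,
    consecutive: int = 3,
) -> float:
    """First time the platelet signal exceeds baseline mean + 3 s.d. for 3 frames.

    The baseline is the first ``baseline_frames`` (pre-perfusion) frames; for
    a noiseless (zero-s.d.) baseline any strictly positive excursion counts.
    Raises OnsetNotDetected when the criterion is never met.
    """
    y = np.asarray(platelet_channel, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size != t.size:
        raise ValueError("signal and time grids differ in length")
    if y.size < baseline_frames + consecutive:
        raise ValueError("trace too short for onset detection")
    base = y[:baseline_frames]
    threshold = base.mean() + n_sd * base.std(ddof=0)
    above = y > threshold
    run = 0
    for i in range(y.size):
        run = run + 1 if above[i] else 0
        if run >= consecutive:
            return float(t[i - consecutive + 1])
    raise OnsetNotDetected("platelet signal never exceeded baseline + 3 s.d.")


def _read_value(y: np.ndarray, idx: int, half_window: int = 1) -> float:
    lo = max(idx - half_window, 0)
    hi = min(idx + half_window + 1, y.size)
    return float(y[lo:hi].mean())


def quantify_profile(
    tc: TimeCourseSet,
    read_offset: float = READ_OFFSET_S,
    autofluorescence_coeff: float = 0.0,
    autofluorescence_channel: str = "fg",
    onset: float | None = None,
) -> ThrombusProfile:
    """Quantify the 7-dimension profile at onset + ``read_offset`` seconds.

    The readout is a 3-frame local average around the readout time for
    robustness to single-frame noise. ``autofluorescence_coeff`` > 0 applies
    the 391-nm leak subtraction to ``autofluorescence_channel`` first.
    """
    missing = [d for d in ("platelet", *DIMENSIONS[1:]) if d not in tc.channels]
    if missing:
        raise ValueError(f"missing channels: {missing}")
    platelet = tc.channels["platelet"]
    if onset is None:
        onset = detect_onset(platelet, tc.times)
    t_read = onset + read_offset
    if t_read > tc.times[-1]:
        raise ValueError(
            f"readout time {t_read:.0f} s beyond trace end {tc.times[-1]:.0f} s"
        )
    idx = int(np.argmin(np.abs(tc.times - t_read)))
    size = _read_value(platelet, idx)
    if size <= 0:
        raise FailedThrombusFormation(
            "zero platelet signal at readout: thrombus failed to form"
        )
    values = [size]
    for dim in DIMENSIONS[1:]:
        y = tc.channels[dim]
        if dim == autofluorescence_channel and autofluorescence_coeff > 0:
            y = correct_autofluorescence(y, platelet, autofluorescence_coeff)
        values.append(_read_value(y, idx) / size)
    return ThrombusProfile(*values)


def fit_growth(platelet_channel, times, onset: float | None = None) -> GrowthFit:
    """Least-squares logistic fit of the post-onset platelet growth curve.

    Fits A / (1 + exp(-(t - t_half)/tau_g)) to the signal after onset (time
    measured from onset). Degenerate (constant) traces and non-convergent
    fits raise rather than returning silently wrong parameters.
    """
    y = np.asarray(platelet_channel, dtype=float)
    t = np.asarray(times, dtype=float)
    if onset is None:
        onset = detect_onset(y, t)
    m = t >= onset
    ty = t[m] - onset
    yy = y[m]
    if np.ptp(yy) <= 0:
        raise ValueError("constant trace: logistic fit is degenerate")

    def logistic(x, a, t_half, tau):
        return a / (1.0 + np.exp(-(x - t_half) / tau))

    a0 = float(yy.max())
    t0 = float(ty[np.argmin(np.abs(yy - a0 / 2.0))])
    try:
        popt, _ = curve_fit(
            logistic,
            ty,
            yy,
            p0=[a0, t0, max(ty.max() / 10.0, 1.0)],
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"logistic growth fit did not converge: {exc}") from exc
    resid = yy - logistic(ty, *popt)
    return GrowthFit(
        plateau=float(popt[0]),
        t_half=float(popt[1]),
        slope_scale=float(popt[2]),
        onset=float(onset),
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


def residue_size(treated_size: float, control_size: float) -> float:
    """Residue size: 100 x treated / control (%)."""
    if control_size <= 0:
        raise ValueError("control size must be strictly positive")
    if treated_size < 0:
        raise ValueError("treated size must be non-negative")
    return 100.0 * treated_size / control_size
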