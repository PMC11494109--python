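"""Seeded synthetic-data generator for every pipeline input.

Emulates the study's data-generating structure so the whole analysis chain is
testable without blood samples: four cohorts (healthy young n=33, healthy
older n=14, hypertensive young n=9, hypertensive older n=13) with
multiplicative disease/aging effects on selected profile dimensions and
log-normal between-subject variation; per-channel fluorescence time courses
(logistic platelet growth, biomarker channels proportional to the platelet
channel, autofluorescence leak into the ~391-nm channel); Hill-type inhibitor
dose responses; Bernoulli BFP touch sequences; two-pathway catch-slip bond
lifetimes; and Fura-2 calcium traces whose pulse amplitude mirrors the mean
bond lifetime at the clamping force.

Everything is deterministic under (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode import DIMENSIONS, N_DIMS, Barcode
from .doseresponse import predict_residue_params

__all__ = [
    "StudyDesign",
    "InhibitorSpec",
    "AcquisitionSpec",
    "CatchSlipParams",
    "BfpScenario",
    "COHORTS",
    "HEALTHY_GROWTH",
    "HYPERTENSIVE_GROWTH",
    "HEALTHY_INTEGRIN_PARAMS",
    "HYPERTENSIVE_INTEGRIN_PARAMS",
    "generate_study",
    "simulate_timecourses",
    "apply_inhibitor",
    "simulate_adhesion",
    "simulate_lifetimes",
    "simulate_calcium",
]

COHORTS = ("healthy_young", "healthy_older", "htn_young", "htn_older")

# (t_half s, tau_g s): plateau-approach time t_half + 2.944 tau_g of ~400 s
# for healthy and ~500 s for hypertensive subjects
HEALTHY_GROWTH = (200.0, 68.0)
HYPERTENSIVE_GROWTH = (250.0, 85.0)


@dataclass(frozen=True)
class StudyDesign:
    """Cohort structure and effect sizes of the synthetic study.

    Dimensions are ordered [size, fg, vwf, psel, ps, eplus, act]. Baseline
    means are healthy-young population values (size in AFU, the rest
    platelet-normalised enrichments). Hypertension and aging act as
    multiplicative effects on [size, Fg, E+, Act], yielding the effect
    barcode [+ + 0 0 0 + +] at the study's sample sizes.
    """

    cohort_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "healthy_young": 33,
            "healthy_older": 14,
            "htn_young": 9,
            "htn_older": 13,
        }
    )
    baseline_profile: tuple[float, ...] = (1000.0, 0.5, 0.3, 0.4, 0.2, 0.3, 0.2)
    baseline_cv: tuple[float, ...] = (0.25, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2)
    effect_multipliers: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "hypertension": (1.8, 1.3, 1.0, 1.0, 1.0, 1.6, 1.5),
            "aging": (1.8, 1.3, 1.0, 1.0, 1.0, 1.6, 1.5),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for k in self.cohort_sizes:
            if k not in COHORTS:
                raise ValueError(f"unknown cohort {k!r}; expected one of {COHORTS}")
        if any(n < 0 for n in self.cohort_sizes.values()):
            raise ValueError("cohort sizes must be non-negative")
        if len(self.baseline_profile) != N_DIMS or len(self.baseline_cv) != N_DIMS:
            raise ValueError(f"baseline profile/CV must have {N_DIMS} entries")
        for mult in self.effect_multipliers.values():
            if len(mult) != N_DIMS or any(m <= 0 for m in mult):
                raise ValueError("effect multipliers must be 7 positive values")

    @property
    def n_subjects(self) -> int:
        return sum(self.cohort_sizes.values())


@dataclass(frozen=True)
class InhibitorSpec:
    """A dose-responsive inhibitor with a directional effect barcode.

    ``effect_barcode`` marks which profile dimensions the inhibitor suppresses
    ('-') or raises ('+'); dimension 0 (size) is governed by the residue-size
    Hill curve (ic50, hill_slope, floor_R) rather than the trit factor.
    """

    name: str
    ic50: float  # µg/mL (or the assay's concentration unit)
    hill_slope: float = 1.0
    floor_R: float = 0.0  # residue size (%) at saturating dose
    effect_barcode: Barcode = field(
        default_factory=lambda: Barcode.from_string("-000000")
    )

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be strictly positive")
        if not 0.0 <= self.floor_R <= 100.0:
            raise ValueError("floor_R must lie in [0, 100]")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Imaging acquisition settings for simulated time courses.

    ``autofluorescence_coeff`` is the fraction of the platelet signal leaking
    into the ~391-nm channel (the Fg channel by default);
    ``baseline_noise_sd`` is a small additive camera noise floor (AFU) that
    makes onset detection on the pre-perfusion baseline meaningful.
    """

    frame_interval: float = 5.0  # s
    duration: float = 600.0  # s
    autofluorescence_coeff: float = 0.1
    noise_cv: float = 0.05
    onset_delay: float = 30.0  # s
    autofluorescence_channel: str = "fg"
    baseline_noise_sd: float = 0.5  # AFU

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.duration < 450.0 + self.onset_delay:
            raise ValueError(
                "duration must cover onset_delay + the 450-s readout window"
            )


@dataclass(frozen=True)
class CatchSlipParams:
    """Two-pathway dissociation rate k(F) = k_c0 e^(-F/f_c) + k_s0 e^(F/f_s).

    k_c0 = 0 encodes a pure slip bond. The catch-slip lifetime curve 1/k(F)
    peaks where k is minimal, at F* = ln(k_c0 f_s / (k_s0 f_c)) / (1/f_c + 1/f_s)
    when that is positive.
    """

    k_c0: float  # 1/s
    f_c: float  # pN
    k_s0: float  # 1/s
    f_s: float  # pN

    def __post_init__(self) -> None:
        if self.k_c0 < 0 or self.k_s0 <= 0 or self.f_c <= 0 or self.f_s <= 0:
            raise ValueError("rates/force scales must be positive (k_c0 may be 0)")

    def rate(self, force) -> np.ndarray | float:
        f = np.asarray(force, dtype=float)
        k = self.k_c0 * np.exp(-f / self.f_c) + self.k_s0 * np.exp(f / self.f_s)
        return float(k) if np.isscalar(force) else k

    def mean_lifetime(self, force) -> np.ndarray | float:
        k = self.rate(force)
        return 1.0 / k

    def peak_force(self) -> float:
        """Force minimising k(F); 0 for pure slip bonds."""
        if self.k_c0 == 0:
            return 0.0
        f_star = np.log(self.k_c0 * self.f_s / (self.k_s0 * self.f_c)) / (
            1.0 / self.f_c + 1.0 / self.f_s
        )
        return float(max(f_star, 0.0))

    def peak_lifetime(self) -> float:
        return float(1.0 / self.rate(self.peak_force()))


# Calibrated integrin aIIbb3-Fg kinetics: analytic peaks at 15 pN / 5.0 s
# (healthy) and 35 pN / 10.0 s (hypertensive), matching the reported
# phenotype shift. Rate constants are calibration, not measurements.
HEALTHY_INTEGRIN_PARAMS = CatchSlipParams(k_c0=0.8033, f_c=5.0, k_s0=0.07558, f_s=20.0)
HYPERTENSIVE_INTEGRIN_PARAMS = CatchSlipParams(
    k_c0=0.52770, f_c=12.0, k_s0=0.022237, f_s=30.0
)


@dataclass(frozen=True)
class BfpScenario:
    """One BFP experimental series."""

    p_a: float = 0.2
    n_cycles: int = 30
    m_r: float = 50.0  # sites/µm²
    m_l: float = 100.0  # sites/µm²
    forces: tuple[float, ...] = (5.0, 15.0, 25.0, 35.0, 45.0, 55.0)
    lifetimes_per_force: int = 100
    params: CatchSlipParams = HEALTHY_INTEGRIN_PARAMS

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_a < 1.0:
            raise ValueError("p_a must lie in [0, 1)")
        if self.n_cycles < 1 or self.lifetimes_per_force < 1:
            raise ValueError("counts must be >= 1")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _lognormal_factor(rng: np.random.Generator, cv: np.ndarray, size) -> np.ndarray:
    """Unit-mean log-normal multiplicative noise with the given CVs."""
    cv = np.asarray(cv, dtype=float)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _cohort_multiplier(design: StudyDesign, cohort: str) -> np.ndarray:
    mult = np.ones(N_DIMS)
    if cohort.startswith("htn"):
        mult = mult * np.asarray(design.effect_multipliers["hypertension"])
    if cohort.endswith("older"):
        mult = mult * np.asarray(design.effect_multipliers["aging"])
    return mult


def generate_study(design: StudyDesign, seed: int | None = None) -> pd.DataFrame:
    """Draw the subject table: cohorts, ages, true profiles, cytometry MFIs.

    True per-subject profiles are baseline x cohort multipliers x unit-mean
    log-normal subject noise. Flow-cytometry MFIs for total / E+ / Act.
    aIIbb3 and P-selectin mirror the reported pattern: only the E+ level is
    elevated in hypertensive cohorts.
    """
    rng = _rng(design.seed if seed is None else seed)
    base = np.asarray(design.baseline_profile)
    cv = np.asarray(design.baseline_cv)
    rows = []
    sid = 0
    for cohort in COHORTS:
        n = design.cohort_sizes.get(cohort, 0)
        mult = _cohort_multiplier(design, cohort)
        lo, hi = (50, 75) if cohort.endswith("older") else (20, 49)
        for _ in range(n):
            age = int(rng.integers(lo, hi + 1))
            profile = base * mult
            if np.any(cv > 0):
                profile = profile * _lognormal_factor(rng, cv, N_DIMS)
            is_htn = cohort.startswith("htn")
            mfi_noise = _lognormal_factor(rng, np.full(4, 0.15), 4)
            mfi = {
                "mfi_total_aiibb3": 1000.0 * mfi_noise[0],
                "mfi_eplus_aiibb3": (300.0 if is_htn else 150.0) * mfi_noise[1],
                "mfi_act_aiibb3": 80.0 * mfi_noise[2],
                "mfi_psel": 120.0 * mfi_noise[3],
            }
            rows.append(
                {
                    "subject_id": f"S{sid:03d}",
                    "cohort": cohort,
                    "age": age,
                    **dict(zip(DIMENSIONS, profile)),
                    **mfi,
                }
            )
            sid += 1
    return pd.DataFrame(rows)


def simulate_timecourses(
    subject_profile,
    acquisition: AcquisitionSpec = AcquisitionSpec(),
    seed: int = 0,
    t_half: float = HEALTHY_GROWTH[0],
    tau_g: float = HEALTHY_GROWTH[1],
) -> pd.DataFrame:
    """Per-channel fluorescence time course for one subject/condition.

    The platelet channel follows A / (1 + exp(-(t - onset - t_half)/tau_g))
    after the perfusion onset delay (A = the subject's true size). Each
    biomarker channel is enrichment x platelet x multiplicative noise; the
    autofluorescence channel additionally receives
    ``autofluorescence_coeff`` x platelet. Tidy long format: time_s, channel,
    intensity.
    """
    prof = _profile_vector(subject_profile)
    rng = _rng(seed)
    acq = acquisition
    times = np.arange(0.0, acq.duration + 0.5 * acq.frame_interval, acq.frame_interval)
    size = prof[0]
    shifted = times - acq.onset_delay
    platelet = np.where(
        shifted >= 0, size / (1.0 + np.exp(-(shifted - t_half) / tau_g)), 0.0
    )

    def noisy(x: np.ndarray) -> np.ndarray:
        y = x.copy()
        if acq.noise_cv > 0:
            y = y * _lognormal_factor(rng, np.full(y.size, acq.noise_cv), y.size)
        if acq.baseline_noise_sd > 0:
            y = y + rng.normal(0.0, acq.baseline_noise_sd, y.size)
        return np.maximum(y, 0.0)

    frames = {"platelet": noisy(platelet)}
    for i, dim in enumerate(DIMENSIONS[1:], start=1):
        channel = prof[i] * platelet
        if dim == acq.autofluorescence_channel:
            channel = channel + acq.autofluorescence_coeff * platelet
        frames[dim] = noisy(channel)
    out = []
    for channel, intensity in frames.items():
        out.append(
            pd.DataFrame(
                {"time_s": times, "channel": channel, "intensity": intensity}
            )
        )
    return pd.concat(out, ignore_index=True)


def _profile_vector(subject_profile) -> np.ndarray:
    if isinstance(subject_profile, pd.Series):
        return subject_profile.loc[list(DIMENSIONS)].to_numpy(dtype=float)
    if isinstance(subject_profile, Mapping):
        return np.array([float(subject_profile[d]) for d in DIMENSIONS])
    arr = np.asarray(subject_profile, dtype=float)
    if arr.shape != (N_DIMS,):
        raise ValueError(f"profile must have {N_DIMS} values")
    return arr


def apply_inhibitor(
    true_profile,
    spec: InhibitorSpec,
    concentration: float,
    trit_factor: float = 0.5,
) -> np.ndarray:
    """Modify a true profile by an inhibitor at the given concentration.

    Size is multiplied by the Hill residue-size fraction. Each non-size
    dimension carrying a '-' ('+') trit in the inhibitor's effect barcode is
    scaled by ``trit_factor`` (1/``trit_factor``) raised to twice the Hill
    receptor occupancy, so the scale equals ``trit_factor`` exactly at the
    IC50 and saturates at ``trit_factor``² at high dose; '0' trits are
    untouched. Monotone in concentration.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if not 0 < trit_factor <= 1:
        raise ValueError("trit_factor must lie in (0, 1]")
    prof = _profile_vector(true_profile).copy()
    residue = predict_residue_params(
        concentration, spec.ic50, spec.hill_slope, spec.floor_R
    )
    prof[0] *= residue / 100.0
    if concentration > 0:
        occupancy = 1.0 / (1.0 + (spec.ic50 / concentration) ** spec.hill_slope)
    else:
        occupancy = 0.0
    for i in range(1, N_DIMS):
        trit = spec.effect_barcode.trits[i]
        if trit == -1:
            prof[i] *= trit_factor ** (2.0 * occupancy)
        elif trit == 1:
            prof[i] *= (1.0 / trit_factor) ** (2.0 * occupancy)
    return prof


def simulate_adhesion(scenario: BfpScenario, seed: int = 0) -> np.ndarray:
    """Bernoulli(p_a) outcomes over the touch cycles of one series."""
    rng = _rng(seed)
    return (rng.random(scenario.n_cycles) < scenario.p_a).astype(int)


def simulate_lifetimes(scenario: BfpScenario, seed: int = 0) -> pd.DataFrame:
    """Exponential bond lifetimes at each clamping force.

    At clamp force F lifetimes are exponential with rate k(F) from the
    scenario's catch-slip parameters (mean lifetime 1/k(F)). Returns a tidy
    frame with columns force_pN, lifetime_s.
    """
    rng = _rng(seed)
    frames = []
    for f in scenario.forces:
        k = scenario.params.rate(float(f))
        life = rng.exponential(1.0 / k, scenario.lifetimes_per_force)
        frames.append(pd.DataFrame({"force_pN": f, "lifetime_s": life}))
    return pd.concat(frames, ignore_index=True)


def simulate_calcium(
    force_schedule: Sequence[float],
    lifetime_model: CatchSlipParams,
    seed: int = 0,
    frame_interval: float = 0.5,
    frames_per_pulse: int = 41,  # odd so the pulse grid hits the exact peak
    amplitude_per_second: float = 0.05,
    noise_sd: float = 0.0,
    i380_level: float = 500.0,
) -> tuple[pd.DataFrame, list[float]]:
    """Fura-2 340/380 trace for a sequence of force-clamp pulses.

    The normalised ratio is 1 + amplitude(F) x pulse shape (+ noise), with
    amplitude = ``amplitude_per_second`` x mean bond lifetime at F — encoding
    the observation that the calcium response mirrors the lifetime's
    catch-slip trend. The first 10 frames are pre-stimulus baseline. Returns
    (trace frame with time_s/i340/i380, true pulse amplitudes).
    """
    rng = _rng(seed)
    segments = [np.ones(10)]  # baseline
    amplitudes = []
    for f in force_schedule:
        amp = amplitude_per_second * float(lifetime_model.mean_lifetime(float(f)))
        amplitudes.append(amp)
        phase = np.linspace(0.0, np.pi, frames_per_pulse)
        segments.append(1.0 + amp * np.sin(phase) ** 2)
    ratio = np.concatenate(segments)
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, ratio.size)
    times = np.arange(ratio.size) * frame_interval
    i380 = np.full(ratio.size, i380_level)
    trace = pd.DataFrame({"time_s": times, "i340": ratio * i380, "i380": i380})
    return trace, amplitudes
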