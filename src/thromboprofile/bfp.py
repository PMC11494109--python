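"""Single-molecule adhesion kinetics and force-clamp lifetime analysis.

Biomembrane-force-probe (BFP) touch cycles give a steady-state adhesion
frequency P_a. Under the standard Poisson bond-number model the expected bond
count per touch is lambda = -ln(1 - P_a) = m_r m_l A_c K_a, where m_r and m_l
are receptor and ligand surface densities; the effective avidity is
A_c K_a m_r = lambda / m_l and the effective 2D affinity A_c K_a =
lambda / (m_r m_l). Keeping P_a near 20% makes ~90% of adhesion events
single-bonded, P(N=1 | N>=1) = lambda e^-lambda / (1 - e^-lambda).

Force-clamp lifetimes are binned over clamping force to give mean-lifetime-vs-
force curves, whose shape classifies the bond phenotype (slip, catch-slip,
triphasic slip-catch-slip, flat). Fura-2 ratiometric calcium traces are
normalised by the mean of the first 10 frames and summarised by the peak
increase delta_I_max.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "AdhesionKinetics",
    "LifetimeCurve",
    "CalciumTrace",
    "BondPhenotype",
    "adhesion_frequency",
    "avidity_affinity",
    "single_bond_probability",
    "bin_lifetimes",
    "classify_force_dependence",
    "normalize_calcium",
]

MIN_REPORTABLE_EVENTS = 50  # per-bin event count below which a bin is flagged


@dataclass(frozen=True)
class AdhesionKinetics:
    """Adhesion frequency with derived avidity/affinity (Poisson bond model)."""

    p_a: float
    n_cycles: int
    m_r: float | None = None  # receptor sites / µm²
    m_l: float | None = None  # ligand sites / µm²

    @property
    def standard_error(self) -> float:
        return float(np.sqrt(self.p_a * (1.0 - self.p_a) / self.n_cycles))

    @property
    def mean_bonds(self) -> float:
        """lambda = -ln(1 - P_a), expected bonds per touch."""
        return float(-np.log1p(-self.p_a))

    @property
    def effective_avidity(self) -> float:
        """A_c K_a m_r = lambda / m_l (µm² per unit ligand density)."""
        if self.m_l is None:
            raise ValueError("ligand density m_l required for avidity")
        return self.mean_bonds / self.m_l

    @property
    def effective_affinity(self) -> float:
        """A_c K_a = lambda / (m_r m_l) (µm⁴/site)."""
        if self.m_r is None or self.m_l is None:
            raise ValueError("both densities required for affinity")
        return self.mean_bonds / (self.m_r * self.m_l)


def adhesion_frequency(outcomes: Sequence[int]) -> tuple[float, float]:
    """P_a and its binomial standard error from a 0/1 touch-outcome sequence."""
    arr = np.asarray(outcomes)
    if arr.size == 0:
        raise ValueError("empty outcome sequence")
    if not np.all(np.isin(arr, (0, 1))):
        raise ValueError("outcomes must be 0 (no adhesion) or 1 (adhesion)")
    n = arr.size
    p = float(arr.mean())
    return p, float(np.sqrt(p * (1.0 - p) / n))


def avidity_affinity(p_a: float, m_r: float, m_l: float) -> tuple[float, float]:
    """Effective avidity and 2D affinity from P_a and surface densities.

    Inverts P_a = 1 - exp(-m_r m_l A_c K_a): lambda = -ln(1 - P_a),
    avidity = lambda / m_l, affinity = lambda / (m_r m_l).
    """
    if not 0.0 <= p_a < 1.0:
        raise ValueError("p_a must lie in [0, 1); p_a = 1 implies infinite affinity")
    if m_r <= 0 or m_l <= 0:
        raise ValueError("surface densities must be strictly positive")
    lam = -np.log1p(-p_a)
    return float(lam / m_l), float(lam / (m_r * m_l))


def single_bond_probability(p_a: float) -> float:
    """P(exactly one bond | adhesion) under Poisson bond numbers.

    With lambda = -ln(1 - p_a): lambda e^-lambda / (1 - e^-lambda). At the
    working point p_a = 0.2 this is ~0.893, the basis for running force-clamp
    assays at ~20% adhesion frequency.
    """
    if not 0.0 < p_a < 1.0:
        raise ValueError("p_a must lie strictly in (0, 1)")
    lam = -np.log1p(-p_a)
    return float(lam * np.exp(-lam) / (1.0 - np.exp(-lam)))


@dataclass(frozen=True)
class LifetimeCurve:
    """Mean bond lifetime vs clamping force, binned."""

    bin_edges: np.ndarray  # pN, len = n_bins + 1
    bin_mean_force: np.ndarray  # pN, observed mean force per bin
    mean_lifetime: np.ndarray  # s
    sem: np.ndarray  # s
    count: np.ndarray  # events per bin
    reportable: np.ndarray  # count >= MIN_REPORTABLE_EVENTS

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def peak(self) -> tuple[float, float]:
        """(force, lifetime) at the maximum mean lifetime."""
        i = int(np.argmax(self.mean_lifetime))
        return float(self.bin_mean_force[i]), float(self.mean_lifetime[i])


def bin_lifetimes(
    records, bin_edges: Sequence[float] | None = None, bin_width: float = 10.0
) -> LifetimeCurve:
    """Bin (force, lifetime) records over successive force ranges.

    ``records`` is an (n, 2) array-like of (clamp force pN, lifetime s) or a
    DataFrame with columns force_pN / lifetime_s. Default bins are
    ``bin_width``-pN wide from 0. Empty bins are dropped; bins with fewer than
    50 events are kept but flagged not reportable.
    """
    arr = _as_force_lifetime(records)
    if arr.shape[0] == 0:
        raise ValueError("empty lifetime record set")
    force, life = arr[:, 0], arr[:, 1]
    if bin_edges is None:
        top = np.ceil(force.max() / bin_width) * bin_width
        bin_edges = np.arange(0.0, max(top, bin_width) + 0.5 * bin_width, bin_width)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    idx = np.digitize(force, edges) - 1
    keep = (idx >= 0) & (idx < edges.size - 1)
    idx, force, life = idx[keep], force[keep], life[keep]
    mean_f, mean_t, sem, count, lo_edges = [], [], [], [], []
    for b in range(edges.size - 1):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            continue
        mean_f.append(force[m].mean())
        mean_t.append(life[m].mean())
        sem.append(life[m].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0)
        count.append(n)
        lo_edges.append(b)
    used = np.asarray(lo_edges, dtype=int)
    # edges restricted to occupied bins (contiguity not required)
    kept_edges = np.unique(np.concatenate([edges[used], edges[used + 1]]))
    count_arr = np.asarray(count)
    return LifetimeCurve(
        bin_edges=kept_edges,
        bin_mean_force=np.asarray(mean_f),
        mean_lifetime=np.asarray(mean_t),
        sem=np.asarray(sem),
        count=count_arr,
        reportable=count_arr >= MIN_REPORTABLE_EVENTS,
    )


def _as_force_lifetime(records) -> np.ndarray:
    import pandas as pd

    if isinstance(records, pd.DataFrame):
        return records.loc[:, ["force_pN", "lifetime_s"]].to_numpy(dtype=float)
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("records must be (n, 2): force_pN, lifetime_s")
    return arr


class BondPhenotype(str, Enum):
    SLIP = "slip"
    CATCH_SLIP = "catch-slip"
    TRIPHASIC = "triphasic"
    FLAT = "flat"


@dataclass(frozen=True)
class PhenotypeCall:
    phenotype: BondPhenotype
    peak_force: float | None = None  # pN, for catch-slip / triphasic
    peak_lifetime: float | None = None  # s

    def __eq__(self, other):  # allow comparison against the bare enum
        if isinstance(other, (BondPhenotype, str)):
            return self.phenotype == BondPhenotype(other)
        return super().__eq__(other)


def classify_force_dependence(
    curve: LifetimeCurve, noise_margin_sem: float = 1.0
) -> PhenotypeCall:
    """Classify the bond phenotype from the binned lifetime-vs-force curve.

    Successive bin-to-bin changes count only when they exceed the noise margin
    (default 1 pooled s.e.m.). Sign patterns: all down = slip; up then down
    (interior peak) = catch-slip, with the peak bin reported; down-up-down =
    triphasic; no significant change = flat.
    """
    t = curve.mean_lifetime
    if t.size < 2:
        return PhenotypeCall(BondPhenotype.FLAT)
    signs: list[int] = []
    for i in range(t.size - 1):
        margin = noise_margin_sem * float(
            np.sqrt(curve.sem[i] ** 2 + curve.sem[i + 1] ** 2)
        )
        d = t[i + 1] - t[i]
        if d > margin:
            s = 1
        elif d < -margin:
            s = -1
        else:
            s = 0
        if s != 0 and (not signs or signs[-1] != s):
            signs.append(s)
    if not signs:
        return PhenotypeCall(BondPhenotype.FLAT)
    if signs == [-1]:
        return PhenotypeCall(BondPhenotype.SLIP)
    if signs in ([1, -1], [1]):
        i = int(np.argmax(t))
        return PhenotypeCall(
            BondPhenotype.CATCH_SLIP,
            peak_force=float(curve.bin_mean_force[i]),
            peak_lifetime=float(t[i]),
        )
    if signs == [-1, 1, -1]:
        # interior peak of the catch phase
        interior = slice(1, t.size)
        i = 1 + int(np.argmax(t[1:]))
        return PhenotypeCall(
            BondPhenotype.TRIPHASIC,
            peak_force=float(curve.bin_mean_force[i]),
            peak_lifetime=float(t[i]),
        )
    # anything more oscillatory: fall back on the dominant interior-peak test
    i = int(np.argmax(t))
    if 0 < i < t.size - 1:
        return PhenotypeCall(
            BondPhenotype.CATCH_SLIP,
            peak_force=float(curve.bin_mean_force[i]),
            peak_lifetime=float(t[i]),
        )
    return PhenotypeCall(BondPhenotype.SLIP if signs[0] == -1 else BondPhenotype.FLAT)


@dataclass(frozen=True)
class CalciumTrace:
    """Fura-2 ratiometric trace with baseline-normalised ratio."""

    times: np.ndarray
    i340: np.ndarray
    i380: np.ndarray
    normalized: np.ndarray
    delta_i_max: float


def normalize_calcium(
    times, i340, i380, baseline_frames: int = 10
) -> CalciumTrace:
    """340/380 ratio normalised by the mean of the first ``baseline_frames``.

    delta_I_max is the peak increase of the normalised ratio above 1 over the
    post-baseline (stimulation) window.
    """
    times = np.asarray(times, dtype=float)
    i340 = np.asarray(i340, dtype=float)
    i380 = np.asarray(i380, dtype=float)
    if not (times.size == i340.size == i380.size):
        raise ValueError("times, i340, i380 must have equal length")
    if times.size < baseline_frames:
        raise ValueError(f"need at least {baseline_frames} frames")
    if np.any(i380 <= 0):
        raise ValueError("i380 must be strictly positive")
    ratio = i340 / i380
    baseline = ratio[:baseline_frames].mean()
    if baseline <= 0:
        raise ValueError("non-positive baseline ratio")
    norm = ratio / baseline
    post = norm[baseline_frames:]
    delta = float(max(post.max() - 1.0, 0.0)) if post.size else 0.0
    return CalciumTrace(
        times=times, i340=i340, i380=i380, normalized=norm, delta_i_max=delta
    )
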