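"""Effect barcodes, personal barcodes, reference ranges, and the addition rule.

A thrombus profile has seven ordered dimensions
[size, Fg, VWF, P-selectin, PS, E+ aIIbb3, Act. aIIbb3]. A factor (drug,
disease, age) is summarised as an *effect barcode*: one trit per dimension,
+1 / 0 / -1 for a significant increase / no significant change / significant
decrease. Subjects are summarised as *personal barcodes*: each profile value
classified as abnormally high (+1), normal (0), or abnormally low (-1)
against healthy reference ranges (mean ± 2 s.d., ~95% coverage for a
Gaussian dimension). Barcodes add elementwise with sign saturation: the
combined effect of two factors is sign(a + b) per dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

DIMENSIONS: tuple[str, ...] = ("size", "fg", "vwf", "psel", "ps", "eplus", "act")
N_DIMS = len(DIMENSIONS)

_TRIT_TO_CHAR = {-1: "-", 0: "0", 1: "+"}
_CHAR_TO_TRIT = {v: k for k, v in _TRIT_TO_CHAR.items()}

__all__ = [
    "DIMENSIONS",
    "Barcode",
    "EffectBarcode",
    "PersonalBarcode",
    "ReferenceRanges",
    "derive_effect_barcode",
    "add_barcodes",
    "build_reference_ranges",
    "personal_barcode",
    "census",
]


@dataclass(frozen=True)
class Barcode:
    """Ordered 7-trit code over {-1, 0, +1}; canonical string uses '-', '0', '+'."""

    trits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.trits) != N_DIMS:
            raise ValueError(f"barcode must have {N_DIMS} trits, got {len(self.trits)}")
        if any(t not in (-1, 0, 1) for t in self.trits):
            raise ValueError("trits must be -1, 0, or +1")

    @classmethod
    def from_string(cls, s: str) -> "Barcode":
        """Parse '+-0' strings, with or without spaces/brackets: '- 0 - - 0 - -'."""
        chars = [c for c in s if c in _CHAR_TO_TRIT]
        if len(chars) != N_DIMS:
            raise ValueError(f"cannot parse {s!r} as a {N_DIMS}-trit barcode")
        return cls(tuple(_CHAR_TO_TRIT[c] for c in chars))

    def __str__(self) -> str:
        return "".join(_TRIT_TO_CHAR[t] for t in self.trits)

    def __add__(self, other: "Barcode") -> "Barcode":
        return add_barcodes(self, other)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(DIMENSIONS, self.trits))


@dataclass(frozen=True)
class EffectBarcode(Barcode):
    """Effect barcode, optionally with per-dimension test provenance."""

    p_values: tuple[float, ...] | None = None
    mean_differences: tuple[float, ...] | None = None


class PersonalBarcode(Barcode):
    """Per-subject low/normal/high classification against reference ranges."""


@dataclass(frozen=True)
class ReferenceRanges:
    """Per-dimension Gaussian reference ranges: mean ± 2 s.d."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if len(self.mean) != N_DIMS or len(self.sd) != N_DIMS:
            raise ValueError(f"need {N_DIMS} means and s.d.s")
        if np.any(np.asarray(self.sd) <= 0):
            raise ValueError("reference s.d. must be strictly positive")

    @property
    def low(self) -> np.ndarray:
        return self.mean - 2.0 * self.sd

    @property
    def high(self) -> np.ndarray:
        return self.mean + 2.0 * self.sd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "sd": self.sd, "low": self.low, "high": self.high},
            index=list(DIMENSIONS),
        )


def _as_profile_matrix(profiles) -> np.ndarray:
    """Accept an (n, 7) array or a DataFrame with the 7 dimension columns."""
    if isinstance(profiles, pd.DataFrame):
        arr = profiles.loc[:, list(DIMENSIONS)].to_numpy(dtype=float)
    else:
        arr = np.asarray(profiles, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != N_DIMS:
        raise ValueError(f"profiles must be (n, {N_DIMS})")
    return arr


def derive_effect_barcode(
    profiles_without,
    profiles_with,
    paired: bool = False,
    alpha: float = 0.05,
    correction: str = "holm-sidak",
) -> EffectBarcode:
    """Per-dimension significance test of a factor's effect on the profile.

    Each dimension is tested two-sided: paired t-test when ``paired`` (rows of
    the two matrices are matched subjects), Welch's unpaired t-test otherwise.
    A trit is the sign of the mean difference (with minus without) wherever the
    (multiplicity-adjusted) p-value falls below ``alpha``, else 0.

    ``correction``: 'holm-sidak' (default) or 'none' across the 7 dimensions.
    """
    a = _as_profile_matrix(profiles_without)
    b = _as_profile_matrix(profiles_with)
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least 3 subjects per arm")
    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired mode requires equal, matched subject counts")
        res = _st.ttest_rel(b, a, axis=0)
    else:
        res = _st.ttest_ind(b, a, axis=0, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    # p exactly 1 (identical arms) would hit log1p(-1) inside Holm-Šidák
    pvals = np.clip(np.where(np.isnan(pvals), 1.0, pvals), 0.0, 1.0 - 1e-15)
    if correction == "holm-sidak":
        adjusted = multipletests(pvals, alpha=alpha, method="holm-sidak")[1]
    elif correction == "none":
        adjusted = pvals
    else:
        raise ValueError(f"unknown correction {correction!r}")
    diff = b.mean(axis=0) - a.mean(axis=0)
    trits = tuple(
        int(np.sign(d)) if p < alpha and d != 0 else 0 for d, p in zip(diff, adjusted)
    )
    return EffectBarcode(
        trits, p_values=tuple(adjusted), mean_differences=tuple(diff)
    )


def add_barcodes(a: Barcode, b: Barcode) -> EffectBarcode:
    """The addition rule: elementwise sum with sign saturation.

    sign(a_i + b_i) per dimension, so -1 + -1 -> -1 and +1 + -1 -> 0. The
    operation is commutative; it is *not* associative in general once clamping
    has occurred (e.g. (+ + -) groupings can differ).
    """
    trits = tuple(int(np.sign(x + y)) for x, y in zip(a.trits, b.trits))
    return EffectBarcode(trits)


def build_reference_ranges(healthy_profiles) -> ReferenceRanges:
    """Fit per-dimension Gaussian reference ranges from healthy-young profiles."""
    arr = _as_profile_matrix(healthy_profiles)
    if arr.shape[0] < 10:
        raise ValueError("need at least 10 healthy profiles for reference ranges")
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("degenerate reference data: zero s.d. in some dimension")
    return ReferenceRanges(mean=arr.mean(axis=0), sd=sd)


def personal_barcode(profile, ranges: ReferenceRanges) -> PersonalBarcode:
    """Classify one profile against the reference ranges.

    Values strictly below mean - 2 s.d. are abnormally low (-1), strictly above
    mean + 2 s.d. abnormally high (+1); the closed interval in between,
    including the bounds, is normal (0).
    """
    if isinstance(profile, Mapping):
        vals = np.array([float(profile[d]) for d in DIMENSIONS])
    elif isinstance(profile, pd.Series):
        vals = profile.loc[list(DIMENSIONS)].to_numpy(dtype=float)
    else:
        vals = np.asarray(profile, dtype=float)
    if vals.shape != (N_DIMS,):
        raise ValueError(f"profile must have {N_DIMS} values")
    trits = tuple(
        -1 if v < lo else (1 if v > hi else 0)
        for v, lo, hi in zip(vals, ranges.low, ranges.high)
    )
    return PersonalBarcode(trits)


@dataclass(frozen=True)
class BarcodeCensus:
    n_distinct: int
    frequencies: pd.Series  # canonical string -> count
    abnormal_fractions: pd.DataFrame  # rows: low/normal/high; columns: dimensions


def census(barcodes: Iterable[Barcode]) -> BarcodeCensus:
    """Count distinct barcodes and per-dimension low/normal/high fractions."""
    codes = list(barcodes)
    if not codes:
        raise ValueError("empty barcode collection")
    strings = [str(c) for c in codes]
    freq = pd.Series(strings).value_counts()
    mat = np.array([c.trits for c in codes])
    frac = pd.DataFrame(
        {
            d: [
                float(np.mean(mat[:, i] == -1)),
                float(np.mean(mat[:, i] == 0)),
                float(np.mean(mat[:, i] == 1)),
            ]
            for i, d in enumerate(DIMENSIONS)
        },
        index=["low", "normal", "high"],
    )
    return BarcodeCensus(
        n_distinct=int(freq.size), frequencies=freq, abnormal_fractions=frac
    )
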