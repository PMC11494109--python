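"""Hill dose-response fitting of thrombus residue size and IC50 extraction.

Residue size (% of the untreated thrombus size) as a function of inhibitor
concentration C follows

    Residue(C) = R + (100 - R) / (1 + (IC50 / C)^HillSlope),

where R is the residue plateau at saturating dose. Fitting is nonlinear
least squares with bounds 0 <= R <= 100, IC50 > 0, and a log-spaced
multistart over the observed concentration range for the IC50 initial guess.
Monotonically non-decreasing data are flagged "no inhibition" rather than
fitted. Biphasic dose dependencies (e.g. charged-nanoparticle inhibition)
are not Hill-shaped; for those, the concentration achieving ~50% size
reduction is estimated by monotone interpolation on the descending branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseData",
    "HillFit",
    "predict_residue",
    "predict_residue_params",
    "fit_hill",
    "half_effect_concentration",
    "NoInhibitionError",
]


class NoInhibitionError(ValueError):
    """Raised when the data show no dose-dependent decrease to fit."""


@dataclass(frozen=True)
class DoseResponseData:
    """Concentration (>= 0) vs residue size (%) observations."""

    concentrations: np.ndarray
    residues: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.residues, dtype=float)
        if c.size != r.size:
            raise ValueError("concentrations and residues must have equal length")
        if np.any(c < 0) or not np.all(np.isfinite(r)):
            raise ValueError("concentrations must be >= 0 and residues finite")
        if np.unique(c).size < 4:
            raise ValueError("need at least 4 distinct concentrations")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "residues", r)


@dataclass(frozen=True)
class HillFit:
    ic50: float
    hill_slope: float
    floor_R: float
    rss: float
    converged: bool
    covariance: np.ndarray | None = None

    def predict(self, concentration) -> np.ndarray | float:
        return predict_residue(self, concentration)


def predict_residue_params(
    concentration, ic50: float, hill_slope: float, floor_R: float
):
    """Evaluate the residue-size Hill curve; C = 0 returns 100 (no drug).

    The descending form R + (100 - R)/(1 + (C/IC50)^h) is used, with h > 0
    the magnitude of the descending Hill slope (equivalently the textbook
    (IC50/C)^h form with a negative slope). Residue is 100% at C = 0,
    (100 + R)/2 at C = IC50, and R at saturating dose.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = floor_R + (100.0 - floor_R) / (1.0 + np.power(c / ic50, hill_slope))
    return float(out) if np.isscalar(concentration) else out


def predict_residue(fit: HillFit, concentration):
    return predict_residue_params(concentration, fit.ic50, fit.hill_slope, fit.floor_R)


def _residuals(params: np.ndarray, c: np.ndarray, r: np.ndarray) -> np.ndarray:
    log_ic50, slope, floor = params
    return predict_residue_params(c, np.exp(log_ic50), slope, floor) - r


def fit_hill(data: DoseResponseData, n_starts: int = 7) -> HillFit:
    """Bounded nonlinear least-squares fit of the residue-size Hill curve.

    IC50 is fit on the log scale with a log-spaced multistart spanning the
    positive observed concentrations (extended one decade each way). Raises
    NoInhibitionError when the residues do not decrease with dose.
    """
    c, r = data.concentrations, data.residues
    order = np.argsort(c)
    c_s, r_s = c[order], r[order]
    # no inhibition: non-decreasing trend or essentially flat at 100
    if r_s[-1] >= r_s[0] or np.all(r >= 99.5):
        raise NoInhibitionError("residue size does not decrease with concentration")
    pos = c[c > 0]
    lo, hi = np.log(pos.min() / 10.0), np.log(pos.max() * 10.0)
    best = None
    for log_ic50_0 in np.linspace(lo, hi, n_starts):
        try:
            res = least_squares(
                _residuals,
                x0=[log_ic50_0, 1.0, max(float(r.min()), 0.0)],
                bounds=([lo - 5.0, 0.05, 0.0], [hi + 5.0, 20.0, 100.0]),
                args=(c, r),
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return HillFit(np.nan, np.nan, np.nan, np.inf, converged=False)
    log_ic50, slope, floor = best.x
    # Gauss-Newton covariance estimate (on the internal parameterisation)
    dof = max(c.size - 3, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * 2.0 * best.cost / dof
    except np.linalg.LinAlgError:
        cov = None
    return HillFit(
        ic50=float(np.exp(log_ic50)),
        hill_slope=float(slope),
        floor_R=float(floor),
        rss=float(2.0 * best.cost),
        converged=True,
        covariance=cov,
    )


def half_effect_concentration(concentrations, residues) -> float:
    """Concentration achieving ~50% size reduction on the descending branch.

    For biphasic dose dependencies the Hill form does not apply; this walks
    the descending branch (from the maximum residue down to the minimum) and
    interpolates monotonically to residue = 50%.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(residues, dtype=float)
    order = np.argsort(c)
    c, r = c[order], r[order]
    start = int(np.argmax(r))
    stop = start + int(np.argmin(r[start:]))
    branch_c, branch_r = c[start : stop + 1], r[start : stop + 1]
    if branch_r.size < 2 or branch_r.min() > 50.0:
        raise ValueError("descending branch never reaches 50% residue size")
    # enforce monotone decrease for interpolation
    branch_r = np.minimum.accumulate(branch_r)
    return float(np.interp(-50.0, -branch_r, branch_c))
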