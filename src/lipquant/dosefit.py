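"""Four-parameter logistic (4PL) dose-response fitting per peptide.

The model is f(x) = lower + (upper - lower) / (1 + (x / ec50)^slope); with a
positive slope the vehicle (x = 0) sits at the upper asymptote and the signal
decreases with dose, a negative slope gives an increasing curve. Fits are
least squares over all replicate points of the vehicle-normalised relative
intensities, both slope signs are attempted, and R^2 against the pooled mean
is the raw feature behind score component I.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .quantio import Experiment

#: EC50 sanity window relative to the dosed range; outside -> non-converged
EC50_WINDOW_FACTOR = 100.0


@dataclasses.dataclass(frozen=True)
class DoseResponseFit:
    """4PL parameters, fit quality and EC50 for one peptide."""

    peptide: str
    lower: float
    upper: float
    slope: float
    ec50: float
    r2: float
    converged: bool
    direction: str  # "up" (signal rises with dose) or "down"

    @classmethod
    def failed(cls, peptide: str) -> "DoseResponseFit":
        return cls(peptide, np.nan, np.nan, np.nan, np.nan, 0.0, False, "down")


def four_pl(x: np.ndarray, lower: float, upper: float, ec50: float,
            slope: float) -> np.ndarray:
    """Evaluate the 4PL curve; x = 0 maps to the no-drug asymptote."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    zero = x == 0
    with np.errstate(over="ignore"):
        out[~zero] = lower + (upper - lower) / (1.0 + (x[~zero] / ec50) ** slope)
    out[zero] = upper if slope > 0 else lower
    return out


def normalize_relative_intensity(exp: Experiment, peptide: str) -> pd.DataFrame:
    """Per-sample intensities of one peptide divided by its mean vehicle intensity.

    Returns a frame with columns sample, dose_molar, replicate, relative.
    The vehicle mean maps to 1.0. A vehicle mean of zero or all-missing vehicle
    makes the peptide unfittable (ValueError).
    """
    sub = exp.quant.data[exp.quant.data["peptide"] == peptide]
    if sub.empty:
        raise KeyError(peptide)
    merged = sub.merge(
        exp.design.data[["sample", "dose_molar", "replicate"]], on="sample"
    )
    veh = merged.loc[merged["dose_molar"] == 0, "intensity"].dropna()
    if veh.empty or veh.mean() == 0:
        raise ValueError(f"peptide {peptide}: vehicle mean missing or zero")
    merged = merged.assign(relative=merged["intensity"] / veh.mean())
    return merged[["sample", "dose_molar", "replicate", "relative"]]


def _fit_one_direction(
    x: np.ndarray, y: np.ndarray, slope_sign: float
) -> tuple[np.ndarray, float] | None:
    """Least-squares 4PL fit with the slope constrained to one sign.

    Parameters are (lower, upper, log10_ec50, slope); returns (params, ssres)
    or None on optimizer failure.
    """
    pos = x > 0
    lo_dose_mean = y[x == x.min()].mean()
    hi_dose_mean = y[x == x.max()].mean()
    # positive slope: vehicle at upper asymptote (decreasing curve)
    if slope_sign > 0:
        upper0, lower0 = lo_dose_mean, hi_dose_mean
    else:
        upper0, lower0 = hi_dose_mean, lo_dose_mean
    half = 0.5 * (lower0 + upper0)
    pos_doses = np.unique(x[pos])
    # initial EC50: dose whose mean response is nearest the half-range crossing
    means = np.array([y[x == d].mean() for d in pos_doses])
    ec50_0 = pos_doses[np.argmin(np.abs(means - half))]
    log_lo = np.log10(pos_doses.min()) - np.log10(EC50_WINDOW_FACTOR)
    log_hi = np.log10(pos_doses.max()) + np.log10(EC50_WINDOW_FACTOR)

    def resid(theta):
        lower, upper, log_ec50, slope = theta
        return four_pl(x, lower, upper, 10.0 ** log_ec50, slope) - y

    if slope_sign > 0:
        slope_bounds = (1e-3, 20.0)
    else:
        slope_bounds = (-20.0, -1e-3)
    theta0 = np.array([lower0, upper0, np.log10(ec50_0), slope_sign])
    lb = np.array([-np.inf, -np.inf, log_lo, slope_bounds[0]])
    ub = np.array([np.inf, np.inf, log_hi, slope_bounds[1]])
    theta0 = np.clip(theta0, lb, ub)
    try:
        res = least_squares(resid, theta0, bounds=(lb, ub), method="trf",
                            max_nfev=2000)
    except Exception:
        return None
    if not res.success and not np.isfinite(res.cost):
        return None
    return res.x, float(2.0 * res.cost)


def fit_4pl(doses: np.ndarray, responses: np.ndarray,
            peptide: str = "") -> DoseResponseFit:
    """Fit the 4PL model to all replicate points of one peptide.

    ``doses`` includes the vehicle (0); both slope signs are attempted and the
    fit with the smaller residual sum of squares is kept. R^2 is computed
    against the pooled mean of the responses and clamped to [0, 1]. An EC50
    outside [min positive dose / 100, max dose x 100] flags the fit as
    non-converged with r2 = 0.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    x, y = x[keep], y[keep]
    if np.unique(x).size < 5:
        return DoseResponseFit.failed(peptide)
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0.0:  # identical responses everywhere: no dose response
        return DoseResponseFit.failed(peptide)
    best = None
    for sign in (+1.0, -1.0):
        out = _fit_one_direction(x, y, sign)
        if out is not None and (best is None or out[1] < best[1]):
            best = out
    if best is None:
        return DoseResponseFit.failed(peptide)
    (lower, upper, log_ec50, slope), ssres = best
    ec50 = float(10.0 ** log_ec50)
    pos = x[x > 0]
    lo_ok = pos.min() / EC50_WINDOW_FACTOR
    hi_ok = pos.max() * EC50_WINDOW_FACTOR
    # bounded optimisation can park ec50 on the window edge; treat edge as outside
    if not (lo_ok * 1.0000001 <= ec50 <= hi_ok * 0.9999999):
        return DoseResponseFit.failed(peptide)
    r2 = 1.0 - ssres / sstot
    r2 = float(min(1.0, max(0.0, r2)))
    # the 4PL is invariant under (lower<->upper, slope->-slope), so direction
    # comes from the asymptote values: vehicle asymptote vs infinite-dose one
    v0 = upper if slope > 0 else lower
    v_inf = lower if slope > 0 else upper
    direction = "down" if v_inf < v0 else "up"
    return DoseResponseFit(
        peptide=peptide,
        lower=float(lower),
        upper=float(upper),
        slope=float(slope),
        ec50=ec50,
        r2=r2,
        converged=True,
        direction=direction,
    )


def fit_peptide(exp: Experiment, peptide: str) -> DoseResponseFit:
    """Vehicle-normalise one peptide and fit the 4PL over all replicate points."""
    try:
        rel = normalize_relative_intensity(exp, peptide)
    except ValueError:
        return DoseResponseFit.failed(peptide)
    rel = rel.dropna(subset=["relative"])
    return fit_4pl(rel["dose_molar"].to_numpy(), rel["relative"].to_numpy(),
                   peptide=peptide)


def fit_experiment(exp: Experiment, peptides) -> dict[str, DoseResponseFit]:
    """Fit every requested peptide; failures are recorded, not raised."""
    return {pep: fit_peptide(exp, pep) for pep in peptides}


def protein_ec50(fits) -> float:
    """Protein-level EC50: median of the converged peptide EC50s.

    Even counts use the midpoint convention; with no converged fit the protein
    EC50 is undefined (NaN).
    """
    ec50s = [f.ec50 for f in fits if f.converged]
    if not ec50s:
        return float("nan")
    return float(np.median(ec50s))


def write_fits(fits: dict[str, DoseResponseFit], protein_of, path) -> None:
    rows = [
        {
            "peptide": f.peptide,
            "protein": protein_of(f.peptide),
            "lower": f.lower,
            "upper": f.upper,
            "slope": f.slope,
            "ec50_molar": f.ec50,
            "r2": f.r2,
            "converged": f.converged,
            "direction": f.direction,
        }
        for f in fits.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
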