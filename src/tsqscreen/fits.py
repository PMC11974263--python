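"""Empirical models linking aromaticity to photostability and energetics.

Three model families recur in the screening analysis:

* a 4-parameter logistic (sigmoid) of radical-addition reaction energy vs
  the T1-state MCI — the photostability proxy: strongly Baird-aromatic T1
  states resist methyl/hydroxyl radical addition, so the reaction energy
  saturates towards a mild asymptote at high MCI;
* ordinary linear fits with R^2 (reorganization energy vs planarity change,
  ln k_ISC vs triplet energy);
* a power fit y = a |x|^b for triplet energy vs normalized-MCI change in
  compound subsets.

All fitters are deterministic: the multi-start grid for the sigmoid is
fixed, and R^2 is always reported on the original y scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import DomainError, FitError


class Radical(str, Enum):
    METHYL = "methyl"
    HYDROXYL = "hydroxyl"


@dataclass(frozen=True)
class RadicalAdditionPoint:
    """One (MCI_T1, reaction energy) observation for radical addition."""

    mci_t1: float
    de_rxn: float  # kJ/mol
    radical: Radical = Radical.METHYL

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mci_t1) and np.isfinite(self.de_rxn)):
            raise DomainError("non-finite radical-addition point")


@dataclass(frozen=True)
class SigmoidModel:
    """4-parameter logistic y = y_lo + (y_hi - y_lo) / (1 + exp(-(x-x0)/w)).

    y_lo/y_hi are the low-/high-MCI asymptotes (kJ/mol), x0 the midpoint
    MCI and w > 0 the transition width.
    """

    y_lo: float
    y_hi: float
    x0: float
    w: float

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise DomainError("sigmoid width w must be positive")

    def __call__(self, x):
        return predict_sigmoid(self, x)


@dataclass(frozen=True)
class FitResult:
    """Converged parameters plus goodness-of-fit on the original y scale."""

    model_type: str
    params: dict
    r2: float
    residuals: np.ndarray
    n_points: int
    degenerate: bool = False
    model: object = field(default=None, repr=False)

    def to_json_dict(self) -> dict:
        return {
            "model_type": self.model_type,
            "params": {k: float(v) for k, v in self.params.items()},
            "r2": float(self.r2),
            "n": int(self.n_points),
        }


def _r_squared(y: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        raise FitError("constant y: R^2 undefined")
    return 1.0 - ss_res / ss_tot


def predict_sigmoid(model: SigmoidModel, x):
    """Evaluate the logistic; monotone in x, asymptotes y_lo/y_hi."""
    x = np.asarray(x, dtype=float)
    out = model.y_lo + (model.y_hi - model.y_lo) * special.expit((x - model.x0) / model.w)
    return float(out) if out.ndim == 0 else out


def fit_sigmoid(points: Sequence[RadicalAdditionPoint]) -> FitResult:
    """Least-squares 4-parameter logistic fit with multi-start initialization.

    Asymptote guesses come from the extreme y-deciles, x0 from the median
    crossing; a fixed 5x5 grid over (x0, w) makes the optimization robust
    to the plateau structure of reaction-energy data.  Deterministic.
    """
    if len(points) < 5:
        raise FitError(f"sigmoid fit needs >= 5 points, got {len(points)}")
    x = np.array([p.mci_t1 for p in points], dtype=float)
    y = np.array([p.de_rxn for p in points], dtype=float)
    span = np.ptp(x)
    if span == 0:
        raise FitError("zero x-spread; sigmoid midpoint unidentifiable")

    lo0 = float(np.mean(y[y <= np.quantile(y, 0.1)]))
    hi0 = float(np.mean(y[y >= np.quantile(y, 0.9)]))
    # orient asymptotes with the x-trend so increasing data fit increasing curves
    if np.corrcoef(x, y)[0, 1] < 0:
        lo0, hi0 = hi0, lo0
    mid = 0.5 * (lo0 + hi0)
    x0_med = float(x[np.argmin(np.abs(y - mid))])

    x0_grid = np.concatenate(([x0_med], np.linspace(x.min(), x.max(), 5)))
    w_grid = span * np.array([0.02, 0.05, 0.1, 0.2, 0.5])

    def model_f(xx, y_lo, y_hi, x0, w):
        return y_lo + (y_hi - y_lo) * special.expit((xx - x0) / np.abs(w))

    best = None
    for x0_init in x0_grid:
        for w_init in w_grid:
            try:
                with warnings.catch_warnings():
                    # some grid starts sit on plateaus where the covariance
                    # is singular; only the best SSE solution is kept
                    warnings.simplefilter("ignore", optimize.OptimizeWarning)
                    popt, _ = optimize.curve_fit(
                        model_f, x, y, p0=[lo0, hi0, x0_init, w_init], maxfev=5000
                    )
            except RuntimeError:
                continue
            resid = y - model_f(x, *popt)
            sse = float(resid @ resid)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, popt, resid)
    if best is None:
        raise FitError(
            "sigmoid fit failed to converge from all "
            f"{len(x0_grid) * len(w_grid)} starts (n={len(x)}, x-span={span:.3g})"
        )
    _, popt, resid = best
    model = SigmoidModel(y_lo=popt[0], y_hi=popt[1], x0=popt[2], w=abs(popt[3]))
    return FitResult(
        model_type="sigmoid",
        params={"y_lo": model.y_lo, "y_hi": model.y_hi, "x0": model.x0, "w": model.w},
        r2=_r_squared(y, predict_sigmoid(model, x)),
        residuals=resid,
        n_points=len(x),
        model=model,
    )


def fit_linear_r2(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Ordinary least squares y = slope*x + intercept with R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise FitError("linear fit needs >= 3 points")
    if np.ptp(x) == 0:
        raise FitError("constant x; slope unidentifiable")
    res = stats.linregress(x, y)
    y_pred = res.slope * x + res.intercept
    return FitResult(
        model_type="linear",
        params={"slope": res.slope, "intercept": res.intercept},
        r2=_r_squared(y, y_pred),
        residuals=y - y_pred,
        n_points=x.size,
    )


def fit_power(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Power fit y = a |x|^b via log-log least squares.

    |x| is used because normalized-MCI changes can be negative (e.g. the
    thiepine series); requires all x nonzero and all y of one sign.
    R^2 is reported on the original scale.  A fitted |b| below 1e-8 is
    flagged degenerate (constant model).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise FitError("power fit needs >= 3 points")
    if np.any(x == 0):
        raise DomainError("power fit undefined at x = 0")
    if np.any(y <= 0):
        sign = -1.0
        if np.any(y >= 0):
            raise DomainError("power fit needs y of a single sign")
    else:
        sign = 1.0
    lx = np.log(np.abs(x))
    ly = np.log(sign * y)
    if np.ptp(lx) == 0:
        raise FitError("constant |x|; exponent unidentifiable")
    if np.ptp(ly) == 0:
        # exactly constant data: the fit is the constant itself (b = 0);
        # R^2 has no variance to explain, flagged degenerate
        return FitResult(
            model_type="power",
            params={"a": float(y[0]), "b": 0.0},
            r2=1.0,
            residuals=np.zeros_like(y),
            n_points=x.size,
            degenerate=True,
        )
    b, log_a = np.polyfit(lx, ly, 1)
    a = sign * float(np.exp(log_a))
    y_pred = a * np.abs(x) ** b
    return FitResult(
        model_type="power",
        params={"a": a, "b": float(b)},
        r2=_r_squared(y, y_pred),
        residuals=y - y_pred,
        n_points=x.size,
        degenerate=abs(b) < 1e-8,
    )
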