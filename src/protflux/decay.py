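"""Per-cell first-order decay model for optical pulse labeling traces.

The photoconverted (red) Dendra2 pool of a single cell is assumed to decay
as ``I(t) = I0 * exp(-k t)``; the half-life is ``t_half = ln(2) / k``.  The
model is fitted by nonlinear least squares, initialised from the log-linear
regression of ``log(max(I, eps))`` on ``t``.  There is no additive plateau
term: the background is removed upstream and a free plateau is not
identifiable from seven timepoints.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

__all__ = ["ExponentialDecay", "ExponentialDecayResults"]

_EPS = 1e-12


class ExponentialDecay:
    """Model ``I(t) = I0 * exp(-k t)`` for one intensity trace.

    Parameters
    ----------
    time : array-like
        Sample times (hours, by convention).
    intensity : array-like
        Observed intensities; same length as ``time``.

    Examples
    --------
    >>> t = np.arange(0, 13, 2)
    >>> y = 100 * 2 ** (-t / 20)
    >>> res = ExponentialDecay(t, y).fit()
    >>> round(res.t_half, 6)
    20.0
    """

    def __init__(self, time, intensity):
        self.time = np.asarray(time, dtype=float)
        self.intensity = np.asarray(intensity, dtype=float)
        if self.time.shape != self.intensity.shape or self.time.ndim != 1:
            raise ValueError("time and intensity must be 1-D and the same length")
        if self.time.size < 3:
            raise ValueError("need at least 3 points for a 2-parameter fit")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.intensity))):
            raise ValueError("time and intensity must be finite")

    def _initial_guess(self) -> tuple[float, float]:
        y = np.maximum(self.intensity, _EPS)
        slope, intercept = np.polyfit(self.time, np.log(y), 1)
        return float(np.exp(intercept)), float(-slope)

    def fit(self, maxfev: int = 2000) -> "ExponentialDecayResults":
        i0_init, k_init = self._initial_guess()
        converged = True
        try:
            popt, pcov = optimize.curve_fit(
                lambda t, i0, k: i0 * np.exp(-k * t),
                self.time,
                self.intensity,
                p0=(i0_init, k_init),
                maxfev=maxfev,
                xtol=1e-12,
                ftol=1e-12,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            popt, pcov = (i0_init, k_init), np.full((2, 2), np.nan)
            converged = False
        i0, k = float(popt[0]), float(popt[1])
        fitted = i0 * np.exp(-k * self.time)
        ss_res = float(np.sum((self.intensity - fitted) ** 2))
        ss_tot = float(np.sum((self.intensity - self.intensity.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
        bse = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array(
            [np.nan, np.nan]
        )
        return ExponentialDecayResults(
            model=self, i0=i0, k=k, r2=r2, converged=converged,
            bse_i0=float(bse[0]), bse_k=float(bse[1]),
        )


@dataclass
class ExponentialDecayResults:
    """Fit results: decay rate, half-life and goodness of fit."""

    model: ExponentialDecay
    i0: float
    k: float
    r2: float
    converged: bool
    bse_i0: float = np.nan
    bse_k: float = np.nan

    @property
    def t_half(self) -> float:
        """Half-life in the time units of the input; inf for k <= 0."""
        return np.log(2) / self.k if self.k > 0 else np.inf

    @property
    def bse_t_half(self) -> float:
        # delta method: d(t_half)/dk = -ln2 / k^2
        if self.k > 0 and np.isfinite(self.bse_k):
            return np.log(2) / self.k**2 * self.bse_k
        return np.nan

    def predict(self, time) -> np.ndarray:
        return self.i0 * np.exp(-self.k * np.asarray(time, dtype=float))

    def qc(self, min_r2: float = 0.5, min_timepoints: int = 5) -> tuple[bool, str]:
        """QC verdict and reason code for downstream population statistics."""
        if self.model.time.size < min_timepoints:
            return False, "too_few_points"
        if not self.converged:
            return False, "no_converge"
        # unit-invariant: negligible decline over the observed span is flat
        span = float(self.model.time.max() - self.model.time.min())
        if self.k <= 0 or -np.expm1(-self.k * span) < 1e-6:
            return False, "non_decaying"
        if self.r2 < min_r2:
            return False, "poor_fit"
        return True, "ok"

    def summary(self) -> str:
        lines = [
            "First-order decay fit",
            "=" * 40,
            f"n points    : {self.model.time.size}",
            f"I0          : {self.i0:.4g} (se {self.bse_i0:.3g})",
            f"k [1/unit]  : {self.k:.4g} (se {self.bse_k:.3g})",
            f"t_half      : {self.t_half:.4g} (se {self.bse_t_half:.3g})",
            f"R^2         : {self.r2:.4f}",
            f"converged   : {self.converged}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot data and the fitted curve; returns the matplotlib axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.time
        ax.plot(t, self.model.intensity, "o", label="trace")
        tt = np.linspace(t.min(), t.max(), 200)
        ax.plot(tt, self.predict(tt), "-",
                label=f"fit: t1/2 = {self.t_half:.1f}")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("red intensity")
        ax.legend()
        return ax
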