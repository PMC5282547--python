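"""LD50 estimation from survival counts via the four-parameter logistic.

Survival (motor-neuron counts per coverslip, or XTT absorbance) as a
function of concentration is modelled as

    y(x) = bottom + (top - bottom) / (1 + (x / ld50)^hill),

fitted by least squares.  Vehicle records (x = 0) inform the top asymptote
only, since zero cannot sit on a log-concentration axis.  ``bottom`` is
constrained nonnegative; the Hill slope is unconstrained in sign so that
toxicity (decreasing) and protection fits share code.  For count data the
model can iteratively reweight by the Poisson mean-variance relation.
Confidence intervals for the LD50 come from a bootstrap: case-resampling
within concentration (expanded percentile) for generic responses, or a
parametric Poisson bootstrap for count data.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .datatypes import SurvivalRecord
from .simulate import four_pl

__all__ = ["FourParamLogistic", "DoseResponseResults", "NotIdentifiableError"]


class NotIdentifiableError(ValueError):
    """Raised when the data show no decline across the tested range."""


class FourParamLogistic:
    """4PL dose-response model for survival measurements.

    Parameters
    ----------
    concentration, response : array-like
        Replicate-level observations; concentration 0 denotes vehicle.
        Counts should already be averaged per coverslip.
    """

    def __init__(self, concentration, response, variance: str = "constant"):
        self.concentration = np.asarray(concentration, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if variance not in ("constant", "poisson"):
            raise ValueError("variance must be 'constant' or 'poisson'")
        self.variance = variance
        self._weights = np.ones_like(self.response)
        if self.concentration.shape != self.response.shape:
            raise ValueError("concentration and response must match in length")
        if np.any(self.concentration < 0) or np.any(self.response < 0):
            raise ValueError("concentrations and responses must be >= 0")
        nonzero = np.unique(self.concentration[self.concentration > 0])
        if nonzero.size < 2:
            raise ValueError(">=2 distinct nonzero concentrations required")

    @classmethod
    def from_records(
        cls, records: Sequence[SurvivalRecord], variance: str = "constant"
    ) -> "FourParamLogistic":
        conc = [r.concentration for r in records]
        resp = [r.count_or_signal for r in records]
        return cls(conc, resp, variance=variance)

    # -- internal -----------------------------------------------------------

    def _dose_means(self) -> tuple[np.ndarray, np.ndarray]:
        doses = np.unique(self.concentration)
        means = np.array(
            [self.response[self.concentration == d].mean() for d in doses]
        )
        return doses, means

    def _initial_guess(self) -> np.ndarray:
        doses, means = self._dose_means()
        top = means[doses == 0].mean() if np.any(doses == 0) else means.max()
        bottom = max(means.min(), 0.0)
        mid = (top + bottom) / 2
        pos = doses[doses > 0]
        pos_means = means[doses > 0]
        k = int(np.argmin(np.abs(pos_means - mid)))
        return np.array([top, bottom, np.log10(pos[k]), 1.0])

    @staticmethod
    def _predict(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        top, bottom, log_ld50, hill = theta
        return four_pl(x, top, bottom, 10.0**log_ld50, hill)

    def _least_squares(self, x, y, theta0, tol: float = 1e-12, weights=None):
        pos = x > 0
        log_x = np.where(pos, np.log10(np.where(pos, x, 1.0)), 0.0)
        ln10 = np.log(10.0)
        sw = np.ones_like(y) if weights is None else np.sqrt(weights)

        def resid(theta):
            return (self._predict(theta, x) - y) * sw

        def jac(theta):
            top, bottom, log_ld50, hill = theta
            u = np.where(pos, 10.0 ** np.clip(hill * (log_x - log_ld50), -30, 30), 0.0)
            d = 1.0 + u
            j = np.empty((x.size, 4))
            j[:, 0] = np.where(pos, 1.0 / d, 1.0)
            j[:, 1] = np.where(pos, 1.0 - 1.0 / d, 0.0)
            j[:, 2] = np.where(pos, (top - bottom) * hill * ln10 * u / d**2, 0.0)
            j[:, 3] = np.where(
                pos, -(top - bottom) * ln10 * (log_x - log_ld50) * u / d**2, 0.0
            )
            return j * sw[:, None]

        lo = np.array([0.0, 0.0, -np.inf, -np.inf])
        hi = np.array([np.inf, np.inf, np.inf, np.inf])
        return optimize.least_squares(
            resid, theta0, jac=jac, bounds=(lo, hi), xtol=tol, ftol=tol,
            max_nfev=2000,
        )

    def _batched_lm(
        self, xmat: np.ndarray, ymat: np.ndarray, theta0: np.ndarray,
        n_iter: int = 80, wmat: np.ndarray | None = None,
    ) -> np.ndarray:
        """Levenberg-Marquardt on many small 4PL problems at once.

        ``xmat``/``ymat`` have one bootstrap resample per row; all rows are
        iterated simultaneously, which is what makes case-resampling
        bootstrap intervals cheap.  The nonnegativity bounds on top and
        bottom are enforced by projection after each accepted step.
        """
        B, n = xmat.shape
        pos = xmat > 0
        logx = np.where(pos, np.log10(np.where(pos, xmat, 1.0)), 0.0)
        ln10 = np.log(10.0)
        eye = np.eye(4)
        sw = np.ones_like(ymat) if wmat is None else np.sqrt(wmat)

        def model_parts(theta):
            top, bottom, L, hill = (theta[:, i:i + 1] for i in range(4))
            expo = np.clip(hill * (logx - L), -30.0, 30.0)
            u = np.where(pos, 10.0**expo, 0.0)
            dd = 1.0 + u
            f = np.where(pos, bottom + (top - bottom) / dd, top)
            return f, u, dd

        def cost_of(theta):
            f, _, _ = model_parts(theta)
            rr = (f - ymat) * sw
            return np.einsum("bn,bn->b", rr, rr)

        theta = np.tile(np.asarray(theta0, dtype=float), (B, 1))
        f, u, dd = model_parts(theta)
        r = (f - ymat) * sw
        cost = np.einsum("bn,bn->b", r, r)
        lam = np.full(B, 1e-4)
        grad_norm = np.full(B, np.inf)

        for _ in range(n_iter):
            top, bottom, L, hill = (theta[:, i:i + 1] for i in range(4))
            J = np.empty((B, n, 4))
            J[:, :, 0] = np.where(pos, 1.0 / dd, 1.0)
            J[:, :, 1] = np.where(pos, 1.0 - 1.0 / dd, 0.0)
            J[:, :, 2] = np.where(pos, (top - bottom) * hill * ln10 * u / dd**2, 0.0)
            J[:, :, 3] = np.where(
                pos, -(top - bottom) * ln10 * (logx - L) * u / dd**2, 0.0
            )
            J *= sw[:, :, None]
            g = np.einsum("bnp,bn->bp", J, r)
            H = np.einsum("bnp,bnq->bpq", J, J)
            diag = np.maximum(np.diagonal(H, axis1=1, axis2=2), 1e-12)
            Haug = H + (lam[:, None] * diag)[:, :, None] * eye
            try:
                delta = -np.linalg.solve(Haug, g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                delta = -np.einsum(
                    "bpq,bq->bp", np.linalg.pinv(Haug), g
                )
            trial = theta + delta
            trial[:, 0] = np.maximum(trial[:, 0], 0.0)
            trial[:, 1] = np.maximum(trial[:, 1], 0.0)
            trial_cost = cost_of(trial)
            accept = trial_cost <= cost
            theta = np.where(accept[:, None], trial, theta)
            cost = np.where(accept, trial_cost, cost)
            lam = np.where(accept, lam * 0.2, lam * 3.0)
            lam = np.clip(lam, 1e-12, 1e8)
            grad_norm = np.abs(g).max(axis=1)
            f, u, dd = model_parts(theta)
            r = (f - ymat) * sw
            if np.abs(delta).max() < 1e-11:
                break

        # polish the rare rows whose gradient has not flattened out
        scale = np.maximum(cost, 1.0)
        rough = np.flatnonzero(grad_norm > 1e-6 * scale)
        for b in rough:
            sol = self._least_squares(
                xmat[b], ymat[b], theta[b], tol=1e-10,
                weights=None if wmat is None else wmat[b],
            )
            if sol.cost * 2 <= cost[b]:  # least_squares cost is 0.5*sum(r^2)
                theta[b] = sol.x
        return theta

    def _check_identifiable(self, min_decline_fraction: float) -> None:
        doses, means = self._dose_means()
        top_ref = means[doses == 0].mean() if np.any(doses == 0) else means.max()
        if top_ref <= 0:
            raise NotIdentifiableError("no signal at vehicle; cannot anchor top")
        decline = 1.0 - means[doses > 0].min() / top_ref
        if decline < min_decline_fraction:
            raise NotIdentifiableError(
                "ld50 not identifiable within range: survival declines by "
                f"{100 * decline:.1f}% at most across the tested concentrations"
            )

    # -- public -------------------------------------------------------------

    def fit(self, min_decline_fraction: float = 0.2) -> "DoseResponseResults":
        """Fit the 4PL; raises :class:`NotIdentifiableError` on flat data.

        With ``variance="poisson"`` the fit iteratively reweights by the
        reciprocal predicted response (the Poisson mean-variance relation
        of count data), starting from the unweighted solution.
        """
        self._check_identifiable(min_decline_fraction)
        theta0 = self._initial_guess()
        sol = self._least_squares(self.concentration, self.response, theta0)
        if self.variance == "poisson":
            for _ in range(2):
                w = 1.0 / np.maximum(self._predict(sol.x, self.concentration), 0.5)
                sol = self._least_squares(
                    self.concentration, self.response, sol.x, weights=w
                )
            self._weights = w
        top, bottom, log_ld50, hill = sol.x
        fitted = self._predict(sol.x, self.concentration)
        ss_res = float(np.sum((self.response - fitted) ** 2))
        ss_tot = float(np.sum((self.response - self.response.mean()) ** 2))
        r2 = 1 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)

        # parameter covariance from the jacobian, when the fit has residual dof
        bse = np.full(4, np.nan)
        dof = self.response.size - 4
        if dof > 0 and sol.jac is not None:
            s2 = ss_res / dof
            try:
                cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
                bse = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                pass

        ld50 = float(10.0**log_ld50)
        doses, means = self._dose_means()
        return DoseResponseResults(
            model=self, top=float(top), bottom=float(bottom), ld50=ld50,
            hill=float(hill), r2=r2, converged=bool(sol.success),
            bse=dict(zip(("top", "bottom", "log10_ld50", "hill"), bse)),
            dose_means=dict(zip(doses.tolist(), means.tolist())),
        )


@dataclass
class DoseResponseResults:
    """Fitted 4PL parameters with bootstrap LD50 interval support."""

    model: FourParamLogistic
    top: float
    bottom: float
    ld50: float
    hill: float
    r2: float
    converged: bool
    bse: dict
    dose_means: dict
    ci_ld50: Optional[tuple[float, float]] = None

    def predict(self, concentration) -> np.ndarray:
        return four_pl(concentration, self.top, self.bottom, self.ld50, self.hill)

    def bootstrap_ld50(
        self,
        n_boot: int = 300,
        seed: Optional[int] = None,
        alpha: float = 0.05,
        method: str = "auto",
        expand: bool = True,
        count_scale: float = 1.0,
    ) -> tuple[float, float]:
        """Bootstrap CI for the LD50, stored on the results object.

        ``method="case"`` resamples cases with replacement *within* each
        concentration and refits every resample (all at once, via the
        batched solver).  With only a few replicates per dose the plain
        percentile interval is systematically narrow, so quantile
        deviations from the point estimate are widened by sqrt(n/(n-1))
        on the log10(LD50) scale (the expanded percentile interval;
        ``expand=False`` disables this).

        ``method="parametric"`` (the default when the model was built with
        ``variance="poisson"``) resamples responses from the fitted curve
        under Poisson counting noise: ``y* = Poisson(count_scale * mu) /
        count_scale``, where ``count_scale`` is the number of raw counts
        behind each recorded response (e.g. fields averaged per
        coverslip).  This sidesteps the small-sample narrowness of
        resampling 3 cases per dose entirely and is the appropriate choice
        when the counting-noise model is part of the design.

        ``method="auto"`` picks parametric for Poisson-variance models and
        case-resampling otherwise.
        """
        if method == "auto":
            method = "parametric" if self.model.variance == "poisson" else "case"
        if method not in ("case", "parametric"):
            raise ValueError("method must be 'auto', 'case' or 'parametric'")
        rng = np.random.default_rng(seed)
        x, y = self.model.concentration, self.model.response
        theta0 = np.array([self.top, self.bottom, np.log10(self.ld50), self.hill])

        if method == "parametric":
            if count_scale <= 0:
                raise ValueError("count_scale must be positive")
            mu = np.maximum(self.predict(x), 1e-9)
            ystar = rng.poisson(np.tile(count_scale * mu, (n_boot, 1))) / count_scale
            xmat = np.tile(x, (n_boot, 1))
            wmat = None
            if self.model.variance == "poisson":
                wmat = np.tile(1.0 / np.maximum(mu, 0.5), (n_boot, 1))
            theta = self.model._batched_lm(xmat, ystar, theta0, wmat=wmat)
            q_lo, q_hi = np.percentile(
                theta[:, 2], [100 * alpha / 2, 100 * (1 - alpha / 2)]
            )
        else:
            doses = np.unique(x)
            idx_by_dose = [np.flatnonzero(x == d) for d in doses]
            take = np.concatenate(
                [
                    idx[rng.integers(0, idx.size, size=(n_boot, idx.size))]
                    for idx in idx_by_dose
                ],
                axis=1,
            )
            wmat = None
            if self.model.variance == "poisson":
                wmat = self.model._weights[take]
            theta = self.model._batched_lm(x[take], y[take], theta0, wmat=wmat)
            q_lo, q_hi = np.percentile(
                theta[:, 2], [100 * alpha / 2, 100 * (1 - alpha / 2)]
            )
            if expand:
                n_bar = np.mean([idx.size for idx in idx_by_dose])
                c = np.sqrt(n_bar / max(n_bar - 1.0, 1.0))
                centre = np.log10(self.ld50)
                q_lo = centre + c * (q_lo - centre)
                q_hi = centre + c * (q_hi - centre)
        self.ci_ld50 = (float(10.0**q_lo), float(10.0**q_hi))
        return self.ci_ld50

    def summary(self) -> str:
        lines = [
            "Four-parameter logistic dose-response fit",
            "=" * 48,
            f"top      : {self.top:.4g} (se {self.bse.get('top', float('nan')):.3g})",
            f"bottom   : {self.bottom:.4g} (se {self.bse.get('bottom', float('nan')):.3g})",
            f"LD50     : {self.ld50:.4g} (log10 se {self.bse.get('log10_ld50', float('nan')):.3g})",
            f"hill     : {self.hill:.4g} (se {self.bse.get('hill', float('nan')):.3g})",
            f"R^2      : {self.r2:.4f}   converged: {self.converged}",
        ]
        if self.ci_ld50 is not None:
            lines.append(f"LD50 95% CI : [{self.ci_ld50[0]:.4g}, {self.ci_ld50[1]:.4g}]")
        lines.append("per-dose means: " + ", ".join(
            f"{d:.3g}->{m:.3g}" for d, m in self.dose_means.items()
        ))
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "top": self.top, "bottom": self.bottom, "ld50": self.ld50,
            "hill": self.hill, "r2": self.r2, "converged": self.converged,
            "ci_ld50": self.ci_ld50, "bse": self.bse,
            "dose_means": self.dose_means,
        }

    def plot(self, ax=None):
        """Dose-response curve over the replicate data (log-x)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model.concentration, self.model.response
        pos = x > 0
        ax.semilogx(x[pos], y[pos], "o", alpha=0.6, label="replicates")
        grid = np.logspace(
            np.log10(x[pos].min()) - 0.5, np.log10(x[pos].max()) + 0.5, 200
        )
        ax.semilogx(grid, self.predict(grid), "-",
                    label=f"4PL fit: LD50 = {self.ld50:.3g}")
        ax.axvline(self.ld50, ls="--", color="0.5")
        ax.set_xlabel("concentration (M)")
        ax.set_ylabel("survival")
        ax.legend()
        return ax
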