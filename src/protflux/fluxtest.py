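"""Restricted permutation test for ubiquitin flux through the proteasome.

The flux assay compares total-ubiquitin blot intensities in a 2x2 design:
(control vs treated) x (with vs without a 4-hour proteasome block).  The
test statistic is the difference of +block/-block ratios of group means,

    T = mean(treated, +MG132) / mean(treated, -MG132)
      - mean(control, +MG132) / mean(control, -MG132),

and the null distribution is built by permuting values between the control
and treated arms *within* each MG132 stratum only: moving a value across
the MG132 boundary is disallowed, because the proteasome block itself has
an uninteresting, guaranteed effect on ubiquitin levels.

Two permutation schemes are provided.  ``full_relabel`` (default) redraws
the control/treated partition uniformly within each stratum, which samples
the exchangeable null directly; ``transposition`` swaps one random
control/treated pair per stratum per iteration, the literal single-swap
scheme.  The p-value is the plain proportion of permuted statistics at
least as large in magnitude as the observed one (ties count toward the
null; a strict-inequality variant and a (b+1)/(B+1) correction are
available by flag).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import LaneRecord

__all__ = [
    "FluxDesign",
    "FluxTestResult",
    "normalize_lanes",
    "flux_statistic",
    "restricted_permutation_test",
    "exhaustive_null",
]

# absolute+relative slack when counting |T_perm| >= |T_obs|, so that exact
# ties are not lost to non-associative float summation
_TIE_EPS = 1e-12


@dataclass
class FluxDesign:
    """Normalized intensities of the four (condition x MG132) groups."""

    treated_plus: np.ndarray
    treated_minus: np.ndarray
    control_plus: np.ndarray
    control_minus: np.ndarray

    def __post_init__(self) -> None:
        for name in ("treated_plus", "treated_minus", "control_plus", "control_minus"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size == 0:
                raise ValueError(f"group {name} is empty")
            if np.any(arr <= 0):
                raise ValueError(f"group {name} has nonpositive normalized values")
            setattr(self, name, arr)

    @property
    def group_sizes(self) -> dict:
        return {
            "treated_plus": self.treated_plus.size,
            "treated_minus": self.treated_minus.size,
            "control_plus": self.control_plus.size,
            "control_minus": self.control_minus.size,
        }

    def swapped_labels(self) -> "FluxDesign":
        """Exchange the treated/control arm labels."""
        return FluxDesign(
            treated_plus=self.control_plus,
            treated_minus=self.control_minus,
            control_plus=self.treated_plus,
            control_minus=self.treated_minus,
        )


def normalize_lanes(
    records: list[LaneRecord],
    control_label: str = "control",
    batch_rescale: bool = False,
) -> FluxDesign:
    """Normalize lane intensities to loading controls and group them.

    Each lane's value is ``target_intensity / loading_intensity``.  Any
    condition label other than ``control_label`` is treated as the treated
    arm.  With ``batch_rescale`` and multiple blot ids, each blot's values
    are divided by that blot's (control, -MG132) group mean so that global
    exposure differences between blots cancel.
    """
    if not records:
        raise ValueError("no lane records")
    values: dict[tuple[str, str, bool], list[float]] = {}
    for rec in records:
        arm = "control" if rec.condition == control_label else "treated"
        values.setdefault((rec.blot_id, arm, rec.mg132), []).append(rec.normalized)

    blot_ids = sorted({b for b, _, _ in values})
    scale = {b: 1.0 for b in blot_ids}
    if batch_rescale and len(blot_ids) > 1:
        for b in blot_ids:
            ref = values.get((b, "control", False))
            if not ref:
                raise ValueError(
                    f"blot {b!r} lacks a (control, -MG132) group for batch rescaling"
                )
            scale[b] = float(np.mean(ref))

    groups: dict[tuple[str, bool], list[float]] = {}
    for (b, arm, mg), vals in values.items():
        groups.setdefault((arm, mg), []).extend(v / scale[b] for v in vals)

    missing = [g for g in (("treated", True), ("treated", False),
                           ("control", True), ("control", False)) if g not in groups]
    if missing:
        raise ValueError(f"design incomplete; missing groups: {missing}")
    return FluxDesign(
        treated_plus=np.array(groups[("treated", True)]),
        treated_minus=np.array(groups[("treated", False)]),
        control_plus=np.array(groups[("control", True)]),
        control_minus=np.array(groups[("control", False)]),
    )


def flux_statistic(design: FluxDesign) -> float:
    """Difference of +MG132/-MG132 ratios of group means."""
    tm = design.treated_minus.mean()
    cm = design.control_minus.mean()
    if tm == 0 or cm == 0:
        raise ZeroDivisionError("a -MG132 group mean is zero")
    return float(design.treated_plus.mean() / tm - design.control_plus.mean() / cm)


@dataclass
class FluxTestResult:
    """Observed statistic, Monte-Carlo null sample and p-value."""

    T_obs: float
    null_sample: np.ndarray
    p: float
    B: int
    mode: str
    seed: Optional[int]
    group_means: dict = field(default_factory=dict)
    group_sizes: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Restricted permutation flux test",
            "=" * 40,
            f"T observed  : {self.T_obs:.6g}",
            f"p (two-sided, magnitude) : {self.p:.4g}",
            f"iterations  : {self.B}  mode: {self.mode}  seed: {self.seed}",
            "group means : "
            + ", ".join(f"{k}={v:.4g}" for k, v in self.group_means.items()),
            "group sizes : "
            + ", ".join(f"{k}={v}" for k, v in self.group_sizes.items()),
        ]
        return "\n".join(lines)

    def plot_null(self, ax=None):
        """Histogram of the permutation null with the observed statistic."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null_sample, bins=50, color="0.7")
        ax.axvline(self.T_obs, color="crimson", label=f"T_obs = {self.T_obs:.3g}")
        ax.set_xlabel("difference of ratios under permutation")
        ax.set_ylabel("count")
        ax.legend()
        return ax

    def as_dict(self) -> dict:
        return {
            "T_obs": self.T_obs, "p": self.p, "B": self.B, "mode": self.mode,
            "seed": self.seed, "group_means": self.group_means,
            "group_sizes": self.group_sizes,
        }


def _count_extreme(null_abs: np.ndarray, t_abs: float, strict: bool) -> int:
    threshold = t_abs - _TIE_EPS * max(1.0, t_abs)
    if strict:
        threshold = t_abs + _TIE_EPS * max(1.0, t_abs)
        return int(np.sum(null_abs > threshold))
    return int(np.sum(null_abs >= threshold))


def restricted_permutation_test(
    design: FluxDesign,
    B: int = 50_000,
    mode: str = "full_relabel",
    seed: Optional[int] = None,
    strict_ties: bool = False,
    plus_one: bool = False,
) -> FluxTestResult:
    """Monte-Carlo restricted permutation test of the flux statistic.

    Values are exchanged between the treated and control arms only within
    the same MG132 stratum.  See the module docstring for the two modes and
    the tie convention.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if mode not in ("full_relabel", "transposition"):
        raise ValueError("mode must be 'full_relabel' or 'transposition'")
    if design.treated_plus.size + design.control_plus.size < 2:
        raise ValueError("+MG132 stratum has fewer than 2 values")
    if design.treated_minus.size + design.control_minus.size < 2:
        raise ValueError("-MG132 stratum has fewer than 2 values")

    rng = np.random.default_rng(seed)
    T_obs = flux_statistic(design)

    def stratum_means(treated: np.ndarray, control: np.ndarray) -> tuple:
        """B permuted (treated_mean, control_mean) pairs for one stratum."""
        nt = treated.size
        pool = np.concatenate([treated, control])
        n = pool.size
        if mode == "full_relabel":
            idx = np.tile(np.arange(n), (B, 1))
            idx = rng.permuted(idx, axis=1)
            perm = pool[idx]
            t_mean = perm[:, :nt].mean(axis=1)
            c_mean = perm[:, nt:].mean(axis=1)
        else:  # transposition: swap one random treated/control pair
            i = rng.integers(0, nt, size=B)
            j = rng.integers(0, control.size, size=B)
            t_sum = treated.sum()
            c_sum = control.sum()
            diff = control[j] - treated[i]
            t_mean = (t_sum + diff) / nt
            c_mean = (c_sum - diff) / control.size
        return t_mean, c_mean

    tp, cp = stratum_means(design.treated_plus, design.control_plus)
    tm, cm = stratum_means(design.treated_minus, design.control_minus)
    null = tp / tm - cp / cm

    count = _count_extreme(np.abs(null), abs(T_obs), strict_ties)
    p = (count + 1) / (B + 1) if plus_one else count / B

    return FluxTestResult(
        T_obs=T_obs,
        null_sample=null,
        p=float(p),
        B=B,
        mode=mode,
        seed=seed,
        group_means={
            "treated_plus": float(design.treated_plus.mean()),
            "treated_minus": float(design.treated_minus.mean()),
            "control_plus": float(design.control_plus.mean()),
            "control_minus": float(design.control_minus.mean()),
        },
        group_sizes=design.group_sizes,
    )


def exhaustive_null(
    design: FluxDesign, strict_ties: bool = False, max_relabelings: int = 10**6
) -> dict:
    """Exact p by enumerating every allowed within-stratum relabeling.

    Serves as the oracle for the Monte-Carlo test.  The identity
    relabeling is included, so the exact p is always >= 1/#relabelings.
    """
    from math import comb

    T_obs = flux_statistic(design)

    def stratum_all_means(treated: np.ndarray, control: np.ndarray):
        pool = np.concatenate([treated, control])
        nt, n = treated.size, pool.size
        total = pool.sum()
        t_means, c_means = [], []
        for combo in itertools.combinations(range(n), nt):
            s = pool[list(combo)].sum()
            t_means.append(s / nt)
            c_means.append((total - s) / (n - nt))
        return np.array(t_means), np.array(c_means)

    n_plus = comb(
        design.treated_plus.size + design.control_plus.size, design.treated_plus.size
    )
    n_minus = comb(
        design.treated_minus.size + design.control_minus.size,
        design.treated_minus.size,
    )
    if n_plus * n_minus > max_relabelings:
        raise ValueError(
            f"{n_plus * n_minus} relabelings exceed the limit {max_relabelings}"
        )

    tp, cp = stratum_all_means(design.treated_plus, design.control_plus)
    tm, cm = stratum_all_means(design.treated_minus, design.control_minus)
    # broadcast over the cartesian product of the two strata's relabelings
    T_all = tp[:, None] / tm[None, :] - cp[:, None] / cm[None, :]
    count = _count_extreme(np.abs(T_all).ravel(), abs(T_obs), strict_ties)
    n_total = T_all.size
    return {
        "p": count / n_total,
        "T_obs": T_obs,
        "n_relabelings": int(n_total),
    }
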