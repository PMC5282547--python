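"""Synthetic data with known ground truth for every assay class.

Each generator emulates the statistical structure the downstream analysis
assumes:

* optical pulse labeling: per-cell first-order red-channel decay with
  lognormal between-cell half-life heterogeneity, Gaussian read noise and
  a constant green channel,
* flux blots: four groups (treatment x MG132) with multiplicative
  lognormal densitometry noise,
* dose-response: four-parameter-logistic expected survival with Poisson
  counting noise,
* in vitro degradation: first-order loss slowed by an inhibition factor,
  with lognormal band noise.

All generators are pure functions of their parameters and seed: replaying
a seed reproduces the output exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import DegradationRecord, ImageStack, LaneRecord, SurvivalRecord

__all__ = [
    "OPLSimParams",
    "FluxSimParams",
    "DoseSimParams",
    "DegradationSimParams",
    "gen_opl_stack",
    "gen_flux_table",
    "gen_dose_response",
    "gen_degradation",
]


def _lognormal_mean1(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Optical pulse labeling
# ---------------------------------------------------------------------------

@dataclass
class OPLSimParams:
    """Ground-truth parameters of a simulated photoconversion time lapse.

    Half-lives are drawn per cell from a lognormal with median
    ``halflife_median_h`` and log-sd ``halflife_sigma_log``; initial red
    intensities from a lognormal with median ``initial_red_median``.  Cells
    are rendered as 2-D Gaussian blobs of sd ``cell_radius_px`` that may
    drift a fixed number of pixels per frame in a random direction.
    """

    n_cells: int = 200
    halflife_median_h: float = 20.0
    halflife_sigma_log: float = 0.35
    initial_red_median: float = 2000.0
    initial_red_sigma_log: float = 0.3
    background_level: float = 100.0
    background_sd: float = 5.0
    cell_radius_px: float = 4.0
    cell_radius_sd: float = 0.5
    timestamps_h: Sequence[float] = field(
        default_factory=lambda: tuple(float(t) for t in range(0, 13, 2))
    )
    drift_px_per_frame: float = 0.3
    field_shape: tuple[int, int] = (512, 512)
    green_level: float = 1500.0
    bleach_rate_per_h: float = 0.0  # optional confound for robustness studies
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.halflife_median_h <= 0:
            raise ValueError("halflife_median_h must be > 0")
        if self.halflife_sigma_log < 0 or self.initial_red_sigma_log < 0:
            raise ValueError("lognormal sigmas must be >= 0")
        ts = np.asarray(self.timestamps_h, dtype=float)
        if ts.size < 2 or np.any(np.diff(ts) <= 0) or ts[0] != 0:
            raise ValueError("timestamps_h must be strictly increasing from 0")
        if self.background_level < 0 or self.background_sd < 0:
            raise ValueError("background parameters must be >= 0")
        if self.cell_radius_px <= 0:
            raise ValueError("cell_radius_px must be > 0")
        if self.bleach_rate_per_h < 0:
            raise ValueError("bleach_rate_per_h must be >= 0")


def _place_cells(
    rng: np.random.Generator, params: OPLSimParams, radii: np.ndarray
) -> np.ndarray:
    """Rejection-sample non-overlapping blob centres; error when too dense."""
    h, w = params.field_shape
    margin = 4.0 * params.cell_radius_px
    centres: list[tuple[float, float]] = []
    min_sep = 6.0 * params.cell_radius_px  # blobs ~vanish beyond 3 sigma
    max_tries = 200 * max(params.n_cells, 1)
    tries = 0
    while len(centres) < params.n_cells:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {params.n_cells} non-overlapping cells in a "
                f"{h}x{w} field; use a larger field_shape or fewer cells"
            )
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centres):
            centres.append((r, c))
    return np.asarray(centres).reshape(params.n_cells, 2)


def gen_opl_stack(params: OPLSimParams) -> tuple[ImageStack, pd.DataFrame]:
    """Render a synthetic photoconversion time lapse with known ground truth.

    The red intensity of cell *i* at time *t* is
    ``I0_i * 2**(-t / thalf_i)`` on top of a Gaussian-noise background; the
    green channel is constant per cell.  Photobleaching is not simulated by
    default (red loss is read as degradation, as in the assay); a nonzero
    ``bleach_rate_per_h`` adds an extra ``exp(-bleach t)`` factor to every
    red trace so the bleaching confound can be studied explicitly — the
    truth table still records the degradation half-life only.

    Returns
    -------
    stack : ImageStack
    truth : DataFrame
        Long format: one row per (cell, frame) with columns ``cell_id``,
        ``frame``, ``time_h``, ``row``, ``col``, ``t_half_h``, ``i0_red``,
        ``radius_px``.
    """
    rng = np.random.default_rng(params.seed)
    ts = np.asarray(params.timestamps_h, dtype=float)
    n_frames = ts.size
    h, w = params.field_shape

    radii = np.clip(
        rng.normal(params.cell_radius_px, params.cell_radius_sd, params.n_cells),
        0.5 * params.cell_radius_px,
        2.0 * params.cell_radius_px,
    )
    t_half = rng.lognormal(
        np.log(params.halflife_median_h), params.halflife_sigma_log, params.n_cells
    )
    i0 = rng.lognormal(
        np.log(params.initial_red_median), params.initial_red_sigma_log, params.n_cells
    )
    centres = _place_cells(rng, params, radii)
    theta = rng.uniform(0, 2 * np.pi, params.n_cells)
    drift = params.drift_px_per_frame * np.stack([np.sin(theta), np.cos(theta)], axis=1)

    green = np.empty((n_frames, h, w), dtype=np.float32)
    red = np.empty_like(green)
    rows = []
    for f in range(n_frames):
        gf = rng.normal(params.background_level, params.background_sd, (h, w))
        rf = rng.normal(params.background_level, params.background_sd, (h, w))
        for i in range(params.n_cells):
            r0, c0 = centres[i] + f * drift[i]
            sigma = radii[i]
            amp_red = i0[i] * 2.0 ** (-ts[f] / t_half[i]) * np.exp(
                -params.bleach_rate_per_h * ts[f]
            )
            half = int(np.ceil(4 * sigma))
            rr = np.arange(
                max(0, int(r0) - half), min(h, int(r0) + half + 1)
            )
            cc = np.arange(
                max(0, int(c0) - half), min(w, int(c0) + half + 1)
            )
            if rr.size == 0 or cc.size == 0:
                continue
            blob = np.exp(
                -(((rr[:, None] - r0) ** 2) + ((cc[None, :] - c0) ** 2))
                / (2 * sigma**2)
            )
            gf[np.ix_(rr, cc)] += params.green_level * blob
            rf[np.ix_(rr, cc)] += amp_red * blob
            rows.append(
                dict(
                    cell_id=i, frame=f, time_h=ts[f], row=r0, col=c0,
                    t_half_h=t_half[i], i0_red=i0[i], radius_px=sigma,
                )
            )
        green[f] = np.clip(gf, 0, None)
        red[f] = np.clip(rf, 0, None)

    truth = pd.DataFrame(
        rows,
        columns=["cell_id", "frame", "time_h", "row", "col", "t_half_h",
                 "i0_red", "radius_px"],
    )
    stack = ImageStack(green=green, red=red, timestamps_h=ts)
    return stack, truth


# ---------------------------------------------------------------------------
# Flux blots
# ---------------------------------------------------------------------------

@dataclass
class FluxSimParams:
    """Four-group (treatment x MG132) blot design with lognormal noise.

    ``flux_fold`` is the +MG132/-MG132 ratio of group means in the control
    arm; ``effect_delta`` is the additive change of that ratio under
    treatment, so the true difference-of-ratios statistic equals
    ``effect_delta``.
    """

    n_per_group: int = 6
    baseline_mean: float = 1.0
    flux_fold: float = 3.0
    effect_delta: float = 0.0
    noise_cv: float = 0.2
    loading_mean: float = 1.0
    loading_cv: Optional[float] = None  # defaults to noise_cv
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.flux_fold < 1:
            raise ValueError("flux_fold must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.flux_fold + self.effect_delta <= 0:
            raise ValueError("flux_fold + effect_delta must stay positive")


def gen_flux_table(params: FluxSimParams) -> list[LaneRecord]:
    """Simulate lane records for the +/-MG132 flux design.

    Lane normalized values (target/loading) have group means
    ``baseline`` (-MG132, both arms), ``baseline*flux_fold`` (control
    +MG132) and ``baseline*(flux_fold+effect_delta)`` (treated +MG132).
    """
    rng = np.random.default_rng(params.seed)
    loading_cv = params.noise_cv if params.loading_cv is None else params.loading_cv
    group_means = {
        ("control", False): params.baseline_mean,
        ("control", True): params.baseline_mean * params.flux_fold,
        ("treated", False): params.baseline_mean,
        ("treated", True): params.baseline_mean * (params.flux_fold + params.effect_delta),
    }
    records = []
    for (condition, mg132), mean in group_means.items():
        normalized = mean * _lognormal_mean1(rng, params.noise_cv, params.n_per_group)
        loading = params.loading_mean * _lognormal_mean1(
            rng, loading_cv, params.n_per_group
        )
        for k in range(params.n_per_group):
            records.append(
                LaneRecord(
                    blot_id="sim",
                    condition=condition,
                    mg132=mg132,
                    target_intensity=float(normalized[k] * loading[k]),
                    loading_intensity=float(loading[k]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseSimParams:
    """Poisson survival counts along a 4PL dose-response curve.

    Default concentrations follow the coarse screening design: roughly
    10-fold increments from 2 nM to 35 uM, plus vehicle (0).
    """

    concentrations: Sequence[float] = (
        0.0, 2e-9, 2e-8, 2e-7, 2e-6, 2e-5, 3.5e-5
    )
    true_ld50: float = 2e-6
    hill_slope: float = 1.0
    top_count: float = 30.0
    floor_fraction: float = 0.0
    n_replicates: int = 3
    fields_per_replicate: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_ld50 <= 0:
            raise ValueError("true_ld50 must be > 0")
        if self.top_count <= 0:
            raise ValueError("top_count must be > 0")
        if not 0 <= self.floor_fraction < 1:
            raise ValueError("floor_fraction must be in [0, 1)")
        if self.n_replicates < 1 or self.fields_per_replicate < 1:
            raise ValueError("replicate and field counts must be >= 1")
        nonzero = {c for c in self.concentrations if c > 0}
        if len(nonzero) < 2:
            raise ValueError(">=2 distinct nonzero concentrations required")


def four_pl(x, top, bottom, ld50, hill):
    """Four-parameter logistic; x = 0 maps to the top asymptote."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, x / ld50, 0.0)
        val = bottom + (top - bottom) / (1.0 + ratio**hill)
    return np.where(x > 0, val, top)


def gen_dose_response(params: DoseSimParams) -> list[SurvivalRecord]:
    """Simulate survival counts: expectation 4PL, realisation Poisson.

    Each replicate (coverslip) records the average of
    ``fields_per_replicate`` Poisson field counts, mirroring counting
    motor neurons in several nonoverlapping fields and averaging per
    coverslip.
    """
    rng = np.random.default_rng(params.seed)
    bottom = params.floor_fraction * params.top_count
    records = []
    for conc in params.concentrations:
        mu = float(four_pl(conc, params.top_count, bottom, params.true_ld50,
                           params.hill_slope))
        counts = rng.poisson(mu, (params.n_replicates, params.fields_per_replicate))
        for k in range(params.n_replicates):
            records.append(
                SurvivalRecord(
                    concentration=float(conc),
                    replicate_id=f"rep{k}",
                    count_or_signal=float(counts[k].mean()),
                )
            )
    return records


# ---------------------------------------------------------------------------
# In vitro degradation
# ---------------------------------------------------------------------------

@dataclass
class DegradationSimParams:
    """First-order in vitro degradation, slowed per molar-ratio condition.

    ``inhibition_factors`` multiplies the uninhibited rate for each
    proteasome:peptide molar-ratio condition; 1.0 means uninhibited.
    """

    timepoints_min: Sequence[float] = (0.0, 5.0, 15.0)
    deg_rate_per_min: float = 0.15
    inhibition_factors: dict = field(
        default_factory=lambda: {"1:0": 1.0, "1:10": 0.5, "1:100": 0.3}
    )
    noise_cv: float = 0.05
    loading_cv: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deg_rate_per_min < 0:
            raise ValueError("deg_rate_per_min must be >= 0")
        for label, f in self.inhibition_factors.items():
            if not 0 < f <= 1:
                raise ValueError(f"inhibition_factor for {label!r} must be in (0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def gen_degradation(params: DegradationSimParams) -> list[DegradationRecord]:
    """Simulate degradation band tables.

    The normalized signal at time *t* under a condition with inhibition
    factor *f* is ``exp(-rate * f * t)`` times lognormal noise; the loading
    control is constant in expectation.
    """
    rng = np.random.default_rng(params.seed)
    records = []
    for condition, factor in params.inhibition_factors.items():
        for k in range(params.n_replicates):
            for t in params.timepoints_min:
                signal = np.exp(-params.deg_rate_per_min * factor * t)
                signal *= float(_lognormal_mean1(rng, params.noise_cv, ()))
                loading = float(_lognormal_mean1(rng, params.loading_cv, ()))
                records.append(
                    DegradationRecord(
                        condition=condition,
                        replicate_id=f"rep{k}",
                        time_min=float(t),
                        target_intensity=float(signal * loading),
                        loading_intensity=loading,
                    )
                )
    return records
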