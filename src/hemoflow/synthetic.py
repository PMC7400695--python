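"""Seeded generators for everything the study measured but did not publish.

Three generators stand in for the unpublished raw data of a paired
hemodilution cohort:

* :func:`generate_cohort` — before/after viscometer curves for n
  participants.  Condition-mean Casson parameters are inverted exactly
  from the published group-mean viscosities (about 33.6/28.4 cP at
  1 1/s and 5.0/4.5 cP at 300 1/s), so the saline effect appears as it
  did in the study: a strong reduction of the low-shear viscosity
  (yield-stress dominated) and a milder reduction at high shear.
  Between-subject variation is a shared lognormal factor per
  participant (pairing), measurement noise is per-point lognormal.
* :func:`generate_waveform` — a carotid-like pulsatile mean-velocity
  waveform built from a few harmonics, rescaled to a chosen
  systolic-peak-to-mean ratio with its cycle mean preserved exactly.
* :func:`generate_geometry_cohort` — per-participant-side jitter of the
  parametric bifurcation.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

from hemoflow.geometry import BifurcationGeometry, GeometryError
from hemoflow.rheology import (
    CP_PER_PA_S,
    CassonParams,
    ViscosityCurve,
    apparent_viscosity,
    casson_from_two_viscosities,
)


class GenerationError(ValueError):
    """A spec that cannot produce valid synthetic data."""


#: Published group-mean whole-blood viscosities used as calibration anchors
#: (cP at 1 and 300 1/s, before/after saline infusion).
VISCOSITY_ANCHORS = {
    "before": ((1.0, 33.64), (300.0, 5.02)),
    "after": ((1.0, 28.40), (300.0, 4.51)),
}


def condition_mean_params(condition: str) -> CassonParams:
    """Casson parameters whose apparent viscosity passes exactly through
    the published group-mean anchors of the given condition."""
    (g1, m1), (g2, m2) = VISCOSITY_ANCHORS[condition]
    return casson_from_two_viscosities(m1, g1, m2, g2)


def default_shear_grid(n: int = 17) -> np.ndarray:
    """Log-spaced viscometer grid covering 1-1000 1/s."""
    return np.logspace(0.0, 3.0, n)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the synthetic cohort."""

    n_participants: int = 8
    seed: int = 0
    before_params_mean: CassonParams = field(
        default_factory=lambda: condition_mean_params("before"))
    after_params_mean: CassonParams = field(
        default_factory=lambda: condition_mean_params("after"))
    between_subject_cv: float = 0.10
    measurement_noise_cv: float = 0.02
    shear_rate_grid: np.ndarray = field(default_factory=default_shear_grid)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise GenerationError("need n_participants >= 2")
        for cv in (self.between_subject_cv, self.measurement_noise_cv):
            if not (0.0 <= cv <= 0.5):
                raise GenerationError("CVs must lie in [0, 0.5]")
        grid = np.asarray(self.shear_rate_grid, float)
        if np.any(grid < 1.0) or np.any(grid > 1000.0) or np.any(np.diff(grid) <= 0):
            raise GenerationError("shear grid must be increasing within [1, 1000]")
        object.__setattr__(self, "shear_rate_grid", grid)


def _lognormal_factor(rng_z: np.ndarray, cv: float) -> np.ndarray:
    """Unit-mean multiplicative lognormal factors from standard normals."""
    if cv == 0.0:
        return np.ones_like(rng_z)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(sigma * rng_z - 0.5 * sigma ** 2)


def generate_cohort(spec: CohortSpec) -> List[Tuple[ViscosityCurve, ViscosityCurve]]:
    """Paired (before, after) viscosity curves per participant.

    Each participant draws one shared lognormal factor per Casson
    parameter, applied to both condition means — the within-subject
    design: the saline effect is the deterministic mean shift, subject
    identity is the shared factor.  Per-point multiplicative noise
    emulates viscometer error.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.shear_rate_grid
    out = []
    for i in range(spec.n_participants):
        pid = f"P{i + 1:02d}"
        z = rng.standard_normal(2)
        f_tau, f_k = _lognormal_factor(z, spec.between_subject_cv)
        curves = {}
        for cond, mean in (("before", spec.before_params_mean),
                           ("after", spec.after_params_mean)):
            params = CassonParams(tau_y=mean.tau_y * f_tau, k=mean.k * f_k)
            mu_cp = np.asarray(apparent_viscosity(params, grid)) * CP_PER_PA_S
            noise = _lognormal_factor(rng.standard_normal(len(grid)),
                                      spec.measurement_noise_cv)
            vals = mu_cp * noise
            if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
                raise GenerationError("generated non-positive viscosity")
            curves[cond] = ViscosityCurve(pid, cond, grid.copy(), vals)
        out.append((curves["before"], curves["after"]))
    return out


@dataclass(frozen=True)
class WaveformSpec:
    """Pulsatile mean-inlet-velocity waveform specification.

    ``harmonic_amplitudes`` are (relative amplitude, phase) pairs of the
    first harmonics of the cycle; the shape is rescaled so that
    peak/mean equals ``systolic_peak_factor`` while the cycle average
    stays exactly ``mean_velocity``.
    """

    period: float = 1.0            # [s]
    mean_velocity: float = 0.3     # [m/s], typical healthy CCA cycle mean
    systolic_peak_factor: float = 2.5
    harmonic_amplitudes: Tuple[Tuple[float, float], ...] = (
        (1.0, -2.0 * np.pi * 0.15),
        (0.5, -4.0 * np.pi * 0.15),
        (0.25, -6.0 * np.pi * 0.15),
    )

    def __post_init__(self) -> None:
        if self.period <= 0 or self.mean_velocity <= 0:
            raise GenerationError("period and mean_velocity must be positive")
        if self.systolic_peak_factor < 1.0:
            raise GenerationError("systolic_peak_factor must be >= 1")


def _waveform_shape(spec: WaveformSpec, t: np.ndarray) -> np.ndarray:
    s = np.zeros_like(t)
    for i, (a, phi) in enumerate(spec.harmonic_amplitudes, start=1):
        s += a * np.cos(2.0 * np.pi * i * t / spec.period + phi)
    return s


def generate_waveform(spec: WaveformSpec, n_samples: int = 128
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Sample one period of v(t); returns (times, velocities).

    v(t) = mean * (1 + c * shape(t)) with c chosen so peak/mean matches
    the spec.  Harmonics integrate to zero over the cycle, so the cycle
    average equals ``mean_velocity`` exactly (also discretely, for
    uniform sampling finer than the harmonic content).  A shape whose
    rescaling would drive v nonpositive is rejected.
    """
    if n_samples < 16:
        raise GenerationError("need n_samples >= 16")
    t = np.linspace(0.0, spec.period, n_samples, endpoint=False)
    if not spec.harmonic_amplitudes or spec.systolic_peak_factor == 1.0:
        return t, np.full(n_samples, spec.mean_velocity)
    fine = np.linspace(0.0, spec.period, 4096, endpoint=False)
    shape_fine = _waveform_shape(spec, fine)
    smax = shape_fine.max()
    if smax <= 0:
        raise GenerationError("waveform shape has no positive peak")
    c = (spec.systolic_peak_factor - 1.0) / smax
    if 1.0 + c * shape_fine.min() <= 0.0:
        raise GenerationError("waveform would be nonpositive; reduce "
                              "systolic_peak_factor or harmonic content")
    v = spec.mean_velocity * (1.0 + c * _waveform_shape(spec, t))
    return t, v


def generate_geometry_cohort(n: int, seed: int, base: BifurcationGeometry,
                             cv: float, max_retries: int = 100
                             ) -> List[BifurcationGeometry]:
    """n independent lognormal jitters of the base bifurcation.

    Branch diameters and the bulb widening are jittered (the bulb via
    its excess over 1.0, keeping ``bulb_factor >= 1``); draws violating
    the geometry invariants are resampled a bounded number of times.
    """
    if cv > 0.15:
        raise GenerationError("geometry cv > 0.15 risks invalid lumens")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        for _attempt in range(max_retries):
            z = rng.standard_normal(4)
            f = _lognormal_factor(z[:3], cv)
            fb = _lognormal_factor(z[3:], cv)[0]
            try:
                geom = replace(base,
                               d_cca=base.d_cca * f[0],
                               d_ica=base.d_ica * f[1],
                               d_eca=base.d_eca * f[2],
                               bulb_factor=1.0 + (base.bulb_factor - 1.0) * fb)
            except GeometryError:
                continue
            out.append(geom)
            break
        else:
            raise GenerationError(f"no valid geometry in {max_retries} draws")
    return out


def curves_flat(cohort: Sequence[Tuple[ViscosityCurve, ViscosityCurve]]
                ) -> List[ViscosityCurve]:
    """Flatten paired cohort output for CSV writing / group summaries."""
    flat: List[ViscosityCurve] = []
    for before, after in cohort:
        flat.extend((before, after))
    return flat
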