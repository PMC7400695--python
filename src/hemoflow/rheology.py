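"""Casson blood rheology: constitutive law, fitting and group summaries.

Whole blood behaves as a yield-stress, shear-thinning fluid.  The Casson
law models this with two parameters, a yield stress ``tau_y`` [Pa] below
which the material does not deform, and a Casson constant ``k`` [Pa s]
that sets the high-shear limiting viscosity:

    sqrt(tau) = sqrt(tau_y) + sqrt(k * gamma_dot)        (gamma_dot >= 0)

so the apparent viscosity ``mu = tau / gamma_dot`` is

    mu(gamma_dot) = k + tau_y/gamma_dot + 2*sqrt(k*tau_y/gamma_dot),

which diverges as ``gamma_dot -> 0`` (the unyielded plug).  Flow solvers
therefore evaluate the law through a regularization that floors the shear
rate and caps the viscosity; the measured range of a scanning capillary
viscometer (1-1000 1/s) is untouched by the defaults.

Units: viscometer I/O is in centipoise (cP) and 1/s, matching laboratory
convention; everything internal is SI (Pa, Pa s).  1 cP = 1e-3 Pa s.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CP_PER_PA_S = 1.0e3
PA_S_PER_CP = 1.0e-3

VALID_CONDITIONS = ("before", "after")


class RheologyError(ValueError):
    """Domain error in a rheology computation."""


@dataclass(frozen=True)
class CassonParams:
    """Casson constitutive parameters.

    Attributes
    ----------
    tau_y : float
        Yield stress [Pa], >= 0.
    k : float
        Casson constant (high-shear limiting viscosity) [Pa s], > 0.
    """

    tau_y: float
    k: float

    def __post_init__(self) -> None:
        if not (self.tau_y >= 0.0):
            raise RheologyError(f"yield stress must be >= 0, got {self.tau_y}")
        if not (self.k > 0.0):
            raise RheologyError(f"Casson constant must be > 0, got {self.k}")


@dataclass(frozen=True)
class RegularizationConfig:
    """Regularization of the Casson apparent viscosity near zero shear.

    ``gamma_min`` floors the shear rate at which the law is evaluated
    (clamped evaluation) and ``mu_max`` caps the resulting viscosity, so
    the unyielded plug behaves as a very viscous — not rigid — fluid.
    """

    gamma_min: float = 1.0e-3  # [1/s]
    mu_max: float = 10.0  # [Pa s]

    def __post_init__(self) -> None:
        if not (self.gamma_min > 0.0):
            raise RheologyError("gamma_min must be > 0")
        if not (self.mu_max > 0.0):
            raise RheologyError("mu_max must be > 0")


@dataclass(frozen=True)
class ViscosityCurve:
    """One participant/condition apparent-viscosity curve.

    ``shear_rates`` [1/s] strictly increasing within [1, 1000];
    ``viscosities_cp`` [cP] positive, same length.
    """

    participant_id: str
    condition: str
    shear_rates: np.ndarray
    viscosities_cp: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "shear_rates", np.asarray(self.shear_rates, float))
        object.__setattr__(self, "viscosities_cp", np.asarray(self.viscosities_cp, float))
        if self.condition not in VALID_CONDITIONS:
            raise RheologyError(f"condition must be one of {VALID_CONDITIONS}")
        g, v = self.shear_rates, self.viscosities_cp
        if g.ndim != 1 or g.shape != v.shape:
            raise RheologyError("shear_rates and viscosities must be 1-D, same length")
        if not np.all(np.diff(g) > 0):
            raise RheologyError("shear_rates must be strictly increasing")
        if g.size and (g[0] < 1.0 - 1e-12 or g[-1] > 1000.0 + 1e-9):
            raise RheologyError("shear rates must lie in [1, 1000] 1/s")
        if not np.all(v > 0):
            raise RheologyError("viscosities must be positive")

    @property
    def viscosities_pa_s(self) -> np.ndarray:
        return self.viscosities_cp * PA_S_PER_CP


@dataclass(frozen=True)
class CassonFit:
    """Result of a Casson fit: parameters plus the residual norm in the
    square-root coordinates the fit is performed in."""

    params: CassonParams
    residual_norm: float
    clipped: bool = False


def casson_shear_stress(params: CassonParams, gamma_dot) -> np.ndarray | float:
    """Shear stress tau(gamma_dot) [Pa] of the Casson law.

    tau = (sqrt(tau_y) + sqrt(k*gamma_dot))**2; equals tau_y at rest and
    is monotone nondecreasing in the shear rate.
    """
    g = np.asarray(gamma_dot, float)
    if np.any(g < 0):
        raise RheologyError("shear rate must be >= 0")
    tau = (np.sqrt(params.tau_y) + np.sqrt(params.k * g)) ** 2
    return tau if tau.ndim else float(tau)


def apparent_viscosity(
    params: CassonParams,
    gamma_dot,
    reg: RegularizationConfig = RegularizationConfig(),
) -> np.ndarray | float:
    """Regularized apparent viscosity mu(gamma_dot) [Pa s].

    For ``gamma_dot >= reg.gamma_min`` returns ``min(tau/gamma_dot,
    reg.mu_max)``; below the floor the value at the floor is returned
    (clamped evaluation).  Nonincreasing in the shear rate.
    """
    g = np.asarray(gamma_dot, float)
    if np.any(g < 0):
        raise RheologyError("shear rate must be >= 0")
    gc = np.maximum(g, reg.gamma_min)
    mu = params.k + params.tau_y / gc + 2.0 * np.sqrt(params.k * params.tau_y / gc)
    mu = np.minimum(mu, reg.mu_max)
    return mu if mu.ndim else float(mu)


def fit_casson(curve: ViscosityCurve) -> CassonFit:
    """Least-squares Casson fit of a measured viscosity curve.

    The law is linear in square-root coordinates: with x = sqrt(gamma_dot)
    and y = sqrt(mu * gamma_dot) = sqrt(tau) (mu in Pa s),

        y = sqrt(tau_y) + sqrt(k) * x,

    so linear least squares gives intercept**2 = tau_y, slope**2 = k.
    The fit is weighted by 1/y: viscometer error is multiplicative in mu,
    hence a uniform *relative* error in y, and equal relative weighting
    keeps the low-shear points (which carry the yield-stress signal)
    from being swamped by the large high-shear y values.  A negative
    intercept (super-Newtonian data) is clipped to zero and the slope
    refit through the origin.
    """
    g = curve.shear_rates
    if g.size < 3 or np.unique(g).size < 3:
        raise RheologyError("need at least 3 distinct shear rates to fit")
    mu = curve.viscosities_pa_s
    if np.any(mu <= 0):
        raise RheologyError("viscosities must be positive")
    x = np.sqrt(g)
    y = np.sqrt(mu * g)
    w = 1.0 / y
    A = np.column_stack([w, w * x])
    (b0, b1), *_ = np.linalg.lstsq(A, np.ones_like(y), rcond=None)
    clipped = False
    if b0 < 0.0:
        clipped = True
        b0 = 0.0
        b1 = float((w * x) @ (w * y) / ((w * x) @ (w * x)))
    if b1 <= 0.0:
        raise RheologyError("fit produced non-positive Casson constant")
    resid = float(np.linalg.norm(y - (b0 + b1 * x)))
    return CassonFit(CassonParams(tau_y=float(b0) ** 2, k=float(b1) ** 2),
                     residual_norm=resid, clipped=clipped)


def interpolate_viscosity(curve: ViscosityCurve, shear_rate: float) -> float:
    """Apparent viscosity [cP] at an arbitrary shear rate, log-linear in
    (log gamma_dot, log mu).  Raises outside the measured range."""
    g = curve.shear_rates
    if shear_rate < g[0] - 1e-12 or shear_rate > g[-1] + 1e-9:
        raise RheologyError(
            f"shear rate {shear_rate} outside measured range [{g[0]}, {g[-1]}]"
        )
    return float(np.exp(np.interp(np.log(shear_rate), np.log(g),
                                  np.log(curve.viscosities_cp))))


def group_viscosity_summary(
    cohort: Iterable[ViscosityCurve],
    at_shear_rates: Sequence[float],
) -> pd.DataFrame:
    """Mean and sample SD [cP] of cohort viscosity per condition per shear rate.

    Mirrors the study-style viscosity table: per condition, the arithmetic
    mean and (n-1)-denominator SD of the curves interpolated at each
    requested shear rate.  SD is reported as 0.0 when n == 1 (flagged via
    the ``n`` column).
    """
    curves = list(cohort)
    if not curves:
        raise RheologyError("cohort must be non-empty")
    rows = []
    for cond in VALID_CONDITIONS:
        sel = [c for c in curves if c.condition == cond]
        if not sel:
            continue
        for sr in at_shear_rates:
            vals = np.array([interpolate_viscosity(c, sr) for c in sel])
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            rows.append({"condition": cond, "shear_rate": float(sr),
                         "mean_cP": float(vals.mean()), "sd_cP": sd,
                         "n": vals.size})
    return pd.DataFrame(rows)


def percent_difference(before_value: float, after_value: float) -> float:
    """Relative difference (before - after) / after * 100 [%].

    The denominator-after convention matches every percentage the study
    style prints, e.g. (33.64, 28.40) -> 18.45 and (0.52, 0.48) -> 8.33.
    """
    if after_value <= 0:
        raise RheologyError("after_value must be > 0")
    return (before_value - after_value) / after_value * 100.0


def percent_difference_truncated(before_value: float, after_value: float) -> int:
    """Integer rendering of :func:`percent_difference`, truncated toward zero
    (18.45 -> 18, matching the printed integer percentages)."""
    return int(percent_difference(before_value, after_value))


def casson_from_two_viscosities(mu1_cp: float, g1: float,
                                mu2_cp: float, g2: float) -> CassonParams:
    """Exact Casson parameters through two (shear rate, viscosity) anchors.

    The Casson apparent viscosity factors as
    sqrt(mu) = sqrt(k) + sqrt(tau_y / gamma_dot), linear in
    1/sqrt(gamma_dot), so two anchor points determine (tau_y, k) in
    closed form.  Requires the low-shear anchor to be the more viscous
    one (shear thinning).
    """
    if g1 <= 0 or g2 <= 0 or g1 == g2:
        raise RheologyError("need two distinct positive shear rates")
    if mu1_cp <= 0 or mu2_cp <= 0:
        raise RheologyError("viscosities must be positive")
    x1, x2 = 1.0 / np.sqrt(g1), 1.0 / np.sqrt(g2)
    y1, y2 = np.sqrt(mu1_cp * PA_S_PER_CP), np.sqrt(mu2_cp * PA_S_PER_CP)
    b = (y1 - y2) / (x1 - x2)       # sqrt(tau_y)
    a = y1 - b * x1                 # sqrt(k)
    if b < 0 or a <= 0:
        raise RheologyError("anchors are not shear-thinning Casson-compatible")
    return CassonParams(tau_y=float(b * b), k=float(a * a))


# ---------------------------------------------------------------- CSV I/O

VISCOSITY_COLUMNS = ["participant_id", "condition", "shear_rate_s-1", "viscosity_cP"]


def write_viscosity_csv(curves: Iterable[ViscosityCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for g, v in zip(c.shear_rates, c.viscosities_cp):
            rows.append((c.participant_id, c.condition, g, v))
    pd.DataFrame(rows, columns=VISCOSITY_COLUMNS).to_csv(path, index=False)


def read_viscosity_csv(path: str | Path) -> list[ViscosityCurve]:
    df = pd.read_csv(path)
    missing = set(VISCOSITY_COLUMNS) - set(df.columns)
    if missing:
        raise RheologyError(f"viscosity CSV missing columns: {sorted(missing)}")
    curves = []
    for (pid, cond), grp in df.groupby(["participant_id", "condition"], sort=True):
        grp = grp.sort_values("shear_rate_s-1")
        curves.append(ViscosityCurve(str(pid), str(cond),
                                     grp["shear_rate_s-1"].to_numpy(),
                                     grp["viscosity_cP"].to_numpy()))
    return curves


def write_fit_csv(fits: dict[tuple[str, str], CassonFit], path: str | Path) -> None:
    """Fitted parameters, one row per (participant, condition)."""
    rows = [
        {"participant_id": pid, "condition": cond,
         "tau_y_Pa": f.params.tau_y, "k_Pa_s": f.params.k,
         "residual_norm": f.residual_norm}
        for (pid, cond), f in sorted(fits.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
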