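"""Transition-state-theory rates and the two-state activity–pH model.

A rate-controlling free-energy barrier ΔG‡ (kcal·mol⁻¹) converts to an
intrinsic rate via the Eyring expression k = κ·(k_B T/h)·exp(−ΔG‡/RT),
reported in min⁻¹. Observed activity follows the noncooperative two-state
model

    k_obs(pH) = k_int / (1 + 10^(pKa_B − pH) + 10^(pH − pKa_A)
                           + 10^(pKa_B − pKa_A)),

whose denominator enumerates the protonation states of the general acid
(A, active when protonated) and of a functionally required base-like site
(B, active when deprotonated). The bell-shaped profile peaks at
pH = (pKa_A + pKa_B)/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, H_J, KB_J, LN10, R_KCAL


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and transmission coefficient for rate conversion."""

    temperature: float = DEFAULT_TEMPERATURE
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (0.0 < self.kappa <= 1.0):
            raise ValueError("transmission coefficient must be in (0, 1]")

    @property
    def prefactor_per_min(self) -> float:
        """κ·k_B·T/h converted to min⁻¹."""
        return self.kappa * KB_J * self.temperature / H_J * 60.0


def tst_rate(barrier: float, ctx: ThermoContext | None = None) -> float:
    """Eyring rate (min⁻¹) for an activation free energy in kcal·mol⁻¹.

    Large barriers underflow gracefully to 0.0.
    """
    if ctx is None:
        ctx = ThermoContext()
    if not math.isfinite(barrier):
        raise ValueError("barrier must be finite")
    exponent = -barrier / (R_KCAL * ctx.temperature)
    try:
        boltz = math.exp(exponent)
    except OverflowError:
        return math.inf
    return ctx.prefactor_per_min * boltz


def barrier_from_rate(rate_per_min: float, ctx: ThermoContext | None = None) -> float:
    """Inverse of :func:`tst_rate`: ΔG‡ implied by a rate in min⁻¹."""
    if ctx is None:
        ctx = ThermoContext()
    if rate_per_min <= 0:
        raise ValueError("rate must be positive")
    return -R_KCAL * ctx.temperature * math.log(rate_per_min / ctx.prefactor_per_min)


@dataclass(frozen=True)
class PhRateModel:
    """Two-state activity–pH model: intrinsic rate and two apparent pKa values."""

    k_int: float  # min⁻¹
    pka_a: float  # acid: must stay protonated (activity lost above)
    pka_b: float  # base-like site: must stay deprotonated (activity lost below)

    def __post_init__(self) -> None:
        if self.k_int < 0:
            raise ValueError("k_int must be >= 0")

    def fraction(self, ph):
        return ph_fraction(self, ph)

    def rate(self, ph):
        return self.k_int * ph_fraction(self, ph)

    @property
    def ph_optimum(self) -> float:
        return 0.5 * (self.pka_a + self.pka_b)

    def to_dict(self) -> dict:
        return {"k_int": self.k_int, "pka_a": self.pka_a, "pka_b": self.pka_b}


def ph_fraction(model: PhRateModel, ph):
    """Active-state fraction f_obs(pH) ∈ (0, 1), overflow-safe at extreme pH."""
    ph = np.asarray(ph, dtype=float)
    # f = exp(-logsumexp over the four denominator terms in log10 units)
    terms = np.stack(
        [
            np.zeros_like(ph),
            (model.pka_b - ph) * LN10,
            (ph - model.pka_a) * LN10,
            np.full_like(ph, (model.pka_b - model.pka_a) * LN10),
        ]
    )
    out = np.exp(-logsumexp(terms, axis=0))
    return float(out) if out.ndim == 0 else out


def predict_ph_profile(model: PhRateModel, ph_grid) -> pd.DataFrame:
    """Tabulate k_obs(pH) = k_int·f_obs(pH) over a pH grid."""
    ph = np.asarray(ph_grid, dtype=float)
    if ph.size == 0:
        raise ValueError("empty pH grid")
    return pd.DataFrame({"ph": ph, "k_obs": model.rate(ph)})


@dataclass
class PhFitResult:
    """Fitted two-state model with standard errors from the local quadratic."""

    model: PhRateModel
    se: dict[str, float]
    cov: np.ndarray
    residual_norm: float

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "se": dict(self.se),
            "residual_norm": self.residual_norm,
        }


def fit_ph_profile(
    data: pd.DataFrame,
    init: PhRateModel | None = None,
    pka_bounds: tuple[float, float] = (0.0, 14.0),
) -> PhFitResult:
    """Weighted nonlinear least squares of the two-state model to (pH, k_obs).

    Weights are 1/se when an ``se`` column is present, else uniform. The
    ordering pKa_B < pKa_A is enforced by parameterizing
    pKa_B = pKa_A − exp(s), which also makes the fit invariant to swapped
    initial guesses. Data lying on a single limb of the bell (observed
    maximum at the boundary of the pH range) is rejected as unidentifiable.
    """
    for col in ("ph", "k_obs"):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    df = data.sort_values("ph").reset_index(drop=True)
    ph = df["ph"].to_numpy(dtype=float)
    k = df["k_obs"].to_numpy(dtype=float)
    if ph.size < 4:
        raise ValueError("need at least 4 data points spanning both limbs")
    imax = int(np.argmax(k))
    if imax in (0, ph.size - 1):
        raise ValueError(
            "data lie on a single limb of the bell curve; "
            "pKa values are unidentifiable"
        )
    w = 1.0 / df["se"].to_numpy(dtype=float) if "se" in df.columns else np.ones_like(k)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("standard errors must be finite and positive")
    if k.max() <= 0:
        raise ValueError("all rates are zero; nothing to fit")

    if init is None:
        init = PhRateModel(
            k_int=float(k.max() * 1.5),
            pka_a=float(ph[imax] + 0.6),
            pka_b=float(ph[imax] - 0.6),
        )
    pa0 = max(init.pka_a, init.pka_b)
    pb0 = min(init.pka_a, init.pka_b)
    theta0 = np.array(
        [math.log(max(init.k_int, 1e-12)), pa0, math.log(max(pa0 - pb0, 1e-3))]
    )

    def unpack(theta):
        return PhRateModel(math.exp(theta[0]), theta[1], theta[1] - math.exp(theta[2]))

    def resid(theta):
        return w * (unpack(theta).rate(ph) - k)

    lo = [-np.inf, pka_bounds[0], -np.inf]
    hi = [np.inf, pka_bounds[1], np.inf]
    sol = least_squares(resid, theta0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    model = unpack(sol.x)

    # covariance in θ-space from the Gauss–Newton quadratic, scaled by the
    # residual variance when no per-point SEs were supplied
    jac = sol.jac
    dof = max(ph.size - 3, 1)
    s2 = 2 * sol.cost / dof if "se" not in df.columns else 1.0
    try:
        cov_theta = s2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        cov_theta = np.full((3, 3), np.nan)
    # delta method to (k_int, pKa_A, pKa_B)
    gap = math.exp(sol.x[2])
    jac_tf = np.array(
        [
            [model.k_int, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 1.0, -gap],
        ]
    )
    cov = jac_tf @ cov_theta @ jac_tf.T
    se = {
        name: float(np.sqrt(cov[i, i])) if np.isfinite(cov[i, i]) and cov[i, i] >= 0 else float("nan")
        for i, name in enumerate(("k_int", "pka_a", "pka_b"))
    }
    return PhFitResult(model=model, se=se, cov=cov, residual_norm=float(np.sqrt(2 * sol.cost)))
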