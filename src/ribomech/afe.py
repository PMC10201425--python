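"""Alchemical free-energy estimation and pKa shifts.

Deprotonation free energies are estimated from per-λ samples of ∂U/∂λ by
thermodynamic integration (TI) or from neighbor-exchange work samples by the
Bennett acceptance ratio (BAR). The shift of a site's pKa caused by the
ribozyme environment is

    ΔpKa = [ΔG_RNA(AH⁺→A) − ΔG_aq(AH⁺→A)] / (RT ln 10)

and the apparent pKa is the experimental solution pKa plus that shift.
Solution reference values (cytosine 4.2, adenine 3.5) are inputs, never
constants of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.special import expit

from .constants import DEFAULT_TEMPERATURE, beta, rt_ln10


class OverlapError(RuntimeError):
    """Forward/reverse work distributions do not overlap; BAR is undefined."""


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A ΔG in kcal·mol⁻¹ with its standard error."""

    value: float
    se: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


@dataclass(eq=False)
class LambdaSeries:
    """Per-λ alchemical samples for one transformation leg.

    ``dudl[i]`` holds the ∂U/∂λ samples at ``lambdas[i]``;
    ``work_fwd[i]``/``work_rev[i]`` (optional) hold work samples for the
    i→i+1 exchange in the forward and reverse direction respectively.
    """

    lambdas: np.ndarray
    dudl: list[np.ndarray]
    work_fwd: list[np.ndarray] | None = None
    work_rev: list[np.ndarray] | None = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.dudl = [np.asarray(d, dtype=float) for d in self.dudl]
        if self.lambdas.ndim != 1 or self.lambdas.size < 2:
            raise ValueError("need at least two lambda values")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambda values must be strictly increasing")
        if not (math.isclose(self.lambdas[0], 0.0) and math.isclose(self.lambdas[-1], 1.0)):
            raise ValueError("lambda endpoints must be 0 and 1")
        if len(self.dudl) != self.lambdas.size:
            raise ValueError("one dudl sample array per lambda required")
        if any(d.size < 2 for d in self.dudl):
            raise ValueError("need >= 2 samples per lambda for a standard error")
        for name in ("work_fwd", "work_rev"):
            w = getattr(self, name)
            if w is not None:
                w = [np.asarray(x, dtype=float) for x in w]
                if len(w) != self.lambdas.size - 1:
                    raise ValueError(f"{name} needs one array per neighbor pair")
                setattr(self, name, w)

    @property
    def n_lambda(self) -> int:
        return self.lambdas.size

    def means(self) -> np.ndarray:
        return np.array([d.mean() for d in self.dudl])

    def sems(self) -> np.ndarray:
        return np.array([d.std(ddof=1) / math.sqrt(d.size) for d in self.dudl])


def _trapezoid_weights(lam: np.ndarray) -> np.ndarray:
    w = np.zeros_like(lam)
    d = np.diff(lam)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def ti_integrate(series: LambdaSeries, rule: str = "trapezoid") -> FreeEnergyEstimate:
    """ΔG = ∫₀¹ ⟨∂U/∂λ⟩ dλ with SE propagated through the quadrature weights.

    ``rule`` is ``"trapezoid"`` (exact for piecewise-linear mean curves) or
    ``"cubic_spline"`` (natural cubic spline through the per-λ means). Both
    estimators are linear in the per-λ means, so the SE is
    √(Σ wᵢ² seᵢ²) with wᵢ the effective quadrature weights.
    """
    lam = series.lambdas
    if lam.size < 2:
        raise ValueError("TI needs at least two lambda points")
    m = series.means()
    se = series.sems()
    if rule == "trapezoid":
        w = _trapezoid_weights(lam)
        value = float(w @ m)
    elif rule == "cubic_spline":
        value = float(CubicSpline(lam, m).integrate(0.0, 1.0))
        # effective weights: the spline integral is linear in the means
        w = np.array(
            [CubicSpline(lam, np.eye(lam.size)[i]).integrate(0.0, 1.0) for i in range(lam.size)]
        )
    else:
        raise ValueError(f"unknown TI rule {rule!r}")
    return FreeEnergyEstimate(value, float(np.sqrt(np.sum(w**2 * se**2))))


def bar_estimate(
    work_forward: np.ndarray,
    work_reverse: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    tol: float = 1e-12,
) -> FreeEnergyEstimate:
    """Bennett acceptance ratio for one pair of states.

    ``work_forward`` are work values (kcal·mol⁻¹) for 0→1 switches,
    ``work_reverse`` for 1→0 switches. Solves the self-consistent Bennett
    equation for ΔG and reports the standard asymptotic variance estimate.

    Raises :class:`OverlapError` when the Fermi acceptance weights are
    degenerate (no overlap between the work distributions).
    """
    wf = np.asarray(work_forward, dtype=float)
    wr = np.asarray(work_reverse, dtype=float)
    if wf.size == 0 or wr.size == 0:
        raise ValueError("both work sets must be nonempty")
    b = beta(temperature)
    n_f, n_r = wf.size, wr.size
    m = math.log(n_f / n_r) / b  # Bennett constant, kcal/mol

    def imbalance(dg: float) -> float:
        # Σ_F fermi(β(W_F − dG + M)) − Σ_R fermi(β(W_R + dG − M))
        a = expit(-b * (wf - dg + m)).sum()
        c = expit(-b * (wr + dg - m)).sum()
        return a - c

    lo = min(wf.min(), -wr.max()) - 10.0 / b
    hi = max(wf.max(), -wr.min()) + 10.0 / b
    f_lo, f_hi = imbalance(lo), imbalance(hi)
    if f_lo == 0.0 and f_hi == 0.0:
        raise OverlapError("acceptance weights are degenerate; no overlap")
    if f_lo * f_hi > 0:
        raise OverlapError(
            "Bennett equation has no root in the work range; overlap failure"
        )
    dg = brentq(imbalance, lo, hi, xtol=tol)

    # asymptotic variance (Bennett): per-set relative fluctuation of the
    # Fermi weights
    ff = expit(-b * (wf - dg + m))
    fr = expit(-b * (wr + dg - m))
    if ff.sum() < 1e-8 or fr.sum() < 1e-8:
        raise OverlapError("acceptance weights are degenerate; no overlap")
    var = (1.0 / b**2) * (
        (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / n_f
        + (np.mean(fr**2) / np.mean(fr) ** 2 - 1.0) / n_r
    )
    return FreeEnergyEstimate(float(dg), float(np.sqrt(max(var, 0.0))))


def bar_series(series: LambdaSeries, tol: float = 1e-12) -> FreeEnergyEstimate:
    """Sum of per-neighbor BAR estimates over a λ series; SE by quadrature."""
    if series.work_fwd is None or series.work_rev is None:
        raise ValueError("series carries no forward/reverse work samples")
    total, var = 0.0, 0.0
    for wf, wr in zip(series.work_fwd, series.work_rev):
        est = bar_estimate(wf, wr, temperature=series.temperature, tol=tol)
        total += est.value
        var += est.se**2
    return FreeEnergyEstimate(total, math.sqrt(var))


@dataclass(frozen=True)
class AfeDeprotonationPair:
    """Deprotonation ΔG (AH⁺→A) in the ribozyme and in water, same T."""

    dg_rna: FreeEnergyEstimate
    dg_aq: FreeEnergyEstimate
    temperature: float = DEFAULT_TEMPERATURE
    temperature_aq: float | None = None  # defaults to `temperature`

    def __post_init__(self) -> None:
        t_aq = self.temperature if self.temperature_aq is None else self.temperature_aq
        if not math.isclose(self.temperature, t_aq, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                f"temperature mismatch between legs: {self.temperature} vs {t_aq}"
            )


@dataclass(frozen=True)
class PkaShift:
    """An environment-induced pKa shift with standard error."""

    value: float
    se: float


@dataclass(frozen=True)
class PkaResult:
    """Solution pKa + environment shift = apparent pKa (exact sum)."""

    solution_pka: float
    delta_pka: float
    delta_pka_se: float = 0.0

    @property
    def apparent_pka(self) -> float:
        return self.solution_pka + self.delta_pka

    @property
    def apparent_pka_se(self) -> float:
        return self.delta_pka_se

    def to_dict(self) -> dict:
        return {
            "solution_pka": self.solution_pka,
            "delta_pka": self.delta_pka,
            "delta_pka_se": self.delta_pka_se,
            "apparent_pka": self.apparent_pka,
            "apparent_pka_se": self.apparent_pka_se,
        }


def delta_pka(pair: AfeDeprotonationPair) -> PkaShift:
    """pKa shift (ΔG_RNA − ΔG_aq)/(RT ln 10); SE combined in quadrature."""
    denom = rt_ln10(pair.temperature)
    value = (pair.dg_rna.value - pair.dg_aq.value) / denom
    se = math.sqrt(pair.dg_rna.se**2 + pair.dg_aq.se**2) / denom
    return PkaShift(value, se)


def apparent_pka(solution_pka: float, shift: PkaShift | float) -> PkaResult:
    """Apparent pKa in the ribozyme environment: solution value plus shift."""
    if isinstance(shift, (int, float)):
        shift = PkaShift(float(shift), 0.0)
    if not (math.isfinite(solution_pka) and math.isfinite(shift.value)):
        raise ValueError("pKa inputs must be finite")
    return PkaResult(float(solution_pka), shift.value, shift.se)
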