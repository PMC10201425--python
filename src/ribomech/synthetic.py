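"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the *statistical structure* of simulation outputs —
Boltzmann-distributed umbrella samples under analytic potentials plus
harmonic biases, λ-series with a known exact free-energy difference and
Crooks-consistent Gaussian work samples, active-site trajectories with
prescribed distance/angle distributions, and multi-model toy structures
with per-residue Gaussian disorder — not the physics that produced them.
Every generator is bit-deterministic for identical inputs and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .afe import LambdaSeries
from .constants import DEFAULT_TEMPERATURE, beta
from .fes import UmbrellaWindow, UmbrellaWindowSet
from .geometry import sigma_to_bvalue
from .trajectory import Frame, Topology, Trajectory

logger = logging.getLogger(__name__)

POTENTIAL_KINDS = ("flat", "harmonic", "double_well_1d", "two_channel_2d")


@dataclass(frozen=True)
class AnalyticPotential:
    """A named analytic energy function in kcal·mol⁻¹ over Å coordinates.

    Kinds
    -----
    flat
        U = 0 (``ndim`` parameter, default 2).
    harmonic
        U = ½·Σ κ_d x_d²; ``kappa`` scalar or per-dimension sequence.
    double_well_1d
        U = a·(x² − 1)²; the barrier between the ±1 minima equals ``a``
        exactly.
    two_channel_2d
        U = a·[(x²−1)² + (y²−1)²] + c·(y − x). Four corner basins at
        (±1, ±1); the tilt ``c`` > 0 lowers the channel through the
        (x=+1, y=−1) corner, i.e. the x-coordinate ("proton transfer")
        advances first along the low channel.
    """

    kind: str
    params: tuple[tuple[str, float], ...] = ()

    @classmethod
    def make(cls, kind: str, **params: float) -> "AnalyticPotential":
        if kind not in POTENTIAL_KINDS:
            raise ValueError(f"unknown potential kind {kind!r}")
        defaults: dict[str, float]
        if kind == "flat":
            defaults = {"ndim": 2}
        elif kind == "harmonic":
            defaults = {"kappa": 1.0, "ndim": 1}
        elif kind == "double_well_1d":
            defaults = {"a": 5.0}
        else:
            defaults = {"a": 2.0, "c": 0.6}
        defaults.update(params)
        return cls(kind, tuple(sorted(defaults.items())))

    @property
    def p(self) -> dict[str, float]:
        return dict(self.params)

    @property
    def ndim(self) -> int:
        if self.kind == "double_well_1d":
            return 1
        if self.kind == "two_channel_2d":
            return 2
        if self.kind == "harmonic":
            kappa = self.p["kappa"]
            return int(self.p.get("ndim", 1)) if np.isscalar(kappa) else len(kappa)
        return int(self.p.get("ndim", 2))

    def energy(self, x: np.ndarray) -> np.ndarray:
        """U evaluated at points of shape (..., ndim) or (...,) for 1D."""
        x = np.asarray(x, dtype=float)
        if x.ndim >= 1 and x.shape[-1] == self.ndim and (x.ndim > 1 or self.ndim > 1):
            pts = x
        else:
            pts = x[..., None]
        if self.kind == "flat":
            return np.zeros(pts.shape[:-1])
        if self.kind == "harmonic":
            kappa = np.broadcast_to(np.atleast_1d(self.p["kappa"]), (pts.shape[-1],))
            return 0.5 * np.sum(kappa * pts**2, axis=-1)
        if self.kind == "double_well_1d":
            a = self.p["a"]
            return a * (pts[..., 0] ** 2 - 1.0) ** 2
        a, c = self.p["a"], self.p["c"]
        xx, yy = pts[..., 0], pts[..., 1]
        return a * ((xx**2 - 1.0) ** 2 + (yy**2 - 1.0) ** 2) + c * (yy - xx)


def dense_grid_extrema(
    potential: AnalyticPotential,
    lims: Sequence[tuple[float, float]] = ((-1.6, 1.6), (-1.6, 1.6)),
    n: int = 201,
    anchors: tuple[tuple[float, float], tuple[float, float]] = ((-1.0, -1.0), (1.0, 1.0)),
) -> dict:
    """Brute-force basin minima and connecting saddle of a 2D potential.

    Evaluates the potential on a dense grid, snaps each anchor (reactant and
    product guesses) to its nearest grid-local minimum, and finds the
    bottleneck saddle between the two basins by flooding cells in order of
    increasing energy (union–find): the cell whose activation first connects
    the basins is the highest point of the best (minimax) path. Serves as
    the independent oracle for path searches.
    """
    if potential.ndim != 2:
        raise ValueError("dense grid search is for 2D potentials")
    xs = np.linspace(lims[0][0], lims[0][1], n)
    ys = np.linspace(lims[1][0], lims[1][1], n)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    u = potential.energy(np.stack([xx, yy], axis=-1))

    # grid-local minima (strictly below 4-neighborhood)
    minima = []
    for i in range(1, n - 1):
        lower = (
            (u[i, 1:-1] < u[i - 1, 1:-1])
            & (u[i, 1:-1] < u[i + 1, 1:-1])
            & (u[i, 1:-1] < u[i, :-2])
            & (u[i, 1:-1] < u[i, 2:])
        )
        for j in np.flatnonzero(lower) + 1:
            minima.append(((i, int(j)), float(u[i, j])))
    if len(minima) < 2:
        raise ValueError("fewer than two minima on the grid")

    def nearest_min(pt):
        d = [
            (xs[i] - pt[0]) ** 2 + (ys[j] - pt[1]) ** 2 for (i, j), _ in minima
        ]
        return minima[int(np.argmin(d))]

    (ia, ja), ea = nearest_min(anchors[0])
    (ib, jb), eb = nearest_min(anchors[1])
    if (ia, ja) == (ib, jb):
        raise ValueError("anchors map to the same basin minimum")

    parent = np.full(n * n, -1, dtype=np.int64)  # -1 = inactive

    def find(z: int) -> int:
        root = z
        while parent[root] != root:
            root = parent[root]
        while parent[z] != root:
            parent[z], z = root, parent[z]
        return root

    order = np.argsort(u, axis=None, kind="stable")
    flat_a, flat_b = ia * n + ja, ib * n + jb
    saddle_idx = None
    for flat in order:
        parent[flat] = flat
        i, j = divmod(int(flat), n)
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < n and 0 <= nj < n and parent[ni * n + nj] != -1:
                ra, rb = find(int(flat)), find(ni * n + nj)
                if ra != rb:
                    parent[rb] = ra
        if parent[flat_a] != -1 and parent[flat_b] != -1 and find(flat_a) == find(flat_b):
            saddle_idx = (i, j)
            break
    assert saddle_idx is not None
    si, sj = saddle_idx
    return {
        "minima": [
            {"xy": (float(xs[ia]), float(ys[ja])), "energy": ea},
            {"xy": (float(xs[ib]), float(ys[jb])), "energy": eb},
        ],
        "saddle": {"xy": (float(xs[si]), float(ys[sj])), "energy": float(u[si, sj])},
        "grid_spacing": (float(xs[1] - xs[0]), float(ys[1] - ys[0])),
    }


@dataclass(frozen=True)
class SamplerConfig:
    """Metropolis random-walk settings for the umbrella sampler.

    ``thin`` records every thin-th state after burn-in (stride thinning to
    reduce the autocorrelation of the recorded chain); the recorded sample
    count still equals ``n_samples_per_window``.
    """

    n_samples_per_window: int
    burn_in: int = 500
    step_size: float = 0.2
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0
    thin: int = 4

    def __post_init__(self) -> None:
        if self.n_samples_per_window <= 0:
            raise ValueError("n_samples_per_window must be positive")
        if self.burn_in < 0 or self.step_size <= 0 or self.temperature <= 0 or self.thin < 1:
            raise ValueError("invalid sampler configuration")


def window_grid(
    pt_range: tuple[float, float] = (-1.5, 1.5),
    mt_range: tuple[float, float] = (-2.5, 2.5),
    step: float = 0.2,
) -> list[tuple[float, float]]:
    """Regular grid of window centers over (ξ_PT, ξ_MT); ranges inclusive."""
    pts = np.round(np.arange(pt_range[0], pt_range[1] + step / 2, step), 10)
    mts = np.round(np.arange(mt_range[0], mt_range[1] + step / 2, step), 10)
    return [(float(p), float(m)) for p in pts for m in mts]


def gen_umbrella_samples(
    potential: AnalyticPotential,
    centers: Sequence[Sequence[float] | float],
    force_constants: Sequence[float] | float,
    config: SamplerConfig,
) -> UmbrellaWindowSet:
    """Metropolis sampling of ``potential`` + ½k(ξ−ξ⁰)² per window.

    All windows are advanced in lockstep (vectorized proposals); the step
    size is auto-tuned per window toward 30–50% acceptance during burn-in.
    Proposals where the potential is non-finite are rejected, never raised.
    1D potentials are embedded as the first coordinate of the 2D window set
    (second coordinate zero, unbiased).
    """
    centers = [np.atleast_1d(np.asarray(c, dtype=float)) for c in centers]
    if len(centers) == 0:
        raise ValueError("need at least one umbrella window")
    d = potential.ndim
    if any(c.shape != (d,) for c in centers):
        raise ValueError(f"window centers must match potential dimension {d}")
    kvec = np.broadcast_to(np.atleast_1d(np.asarray(force_constants, dtype=float)), (d,))
    if np.any(kvec <= 0):
        raise ValueError("force constants must be positive")

    rng = np.random.default_rng(config.seed)
    b = beta(config.temperature)
    n_win = len(centers)
    cmat = np.stack(centers)  # (n_win, d)
    x = cmat.copy()
    steps = np.full(n_win, config.step_size)

    def total_energy(pts: np.ndarray) -> np.ndarray:
        u = potential.energy(pts)
        return u + 0.5 * np.sum(kvec * (pts - cmat) ** 2, axis=-1)

    e = total_energy(x)
    samples = np.empty((config.n_samples_per_window, n_win, d))
    accepted = np.zeros(n_win, dtype=int)
    tune_every = 50
    n_total = config.burn_in + config.n_samples_per_window * config.thin
    for it in range(n_total):
        prop = x + steps[:, None] * rng.standard_normal((n_win, d))
        e_prop = total_energy(prop)
        with np.errstate(invalid="ignore", over="ignore"):
            de = e_prop - e
        log_u = np.log(rng.random(n_win))
        accept = np.isfinite(e_prop) & (log_u < -b * de)
        x = np.where(accept[:, None], prop, x)
        e = np.where(accept, e_prop, e)
        if it < config.burn_in:
            accepted += accept
            if (it + 1) % tune_every == 0:
                rate = accepted / tune_every
                steps = np.where(rate < 0.30, steps * 0.8, steps)
                steps = np.where(rate > 0.50, steps * 1.25, steps)
                accepted[:] = 0
        else:
            k = it - config.burn_in
            if k % config.thin == config.thin - 1:
                samples[k // config.thin] = x

    windows = []
    for i in range(n_win):
        s = samples[:, i, :]
        if d == 1:
            s2 = np.column_stack([s[:, 0], np.zeros(s.shape[0])])
            center2 = np.array([cmat[i, 0], 0.0])
            k2 = np.array([kvec[0], 0.0])
        else:
            s2, center2, k2 = s, cmat[i], kvec
        windows.append(UmbrellaWindow(center2, k2, s2))
    return UmbrellaWindowSet(windows, temperature=config.temperature)


def _shape_mean(delta_g: float, shape: str, lam: np.ndarray, slope: float = 2.0, cubic: float = 8.0):
    """Mean ∂U/∂λ curve whose exact integral over [0,1] equals delta_g."""
    t = lam - 0.5
    if shape == "linear":
        return delta_g + slope * t
    if shape == "cubic":
        return delta_g + slope * t + cubic * t**3
    raise ValueError(f"unknown profile shape {shape!r}")


def _segment_integrals(delta_g: float, shape: str, lam: np.ndarray, slope: float = 2.0, cubic: float = 8.0):
    """Exact ∫ mean-gradient dλ over each [λᵢ, λᵢ₊₁]."""
    t = lam - 0.5
    prim = delta_g * lam + slope * t**2 / 2
    if shape == "cubic":
        prim = prim + cubic * t**4 / 4
    return np.diff(prim)


def gen_lambda_series(
    delta_g_target: float,
    profile_shape: str = "linear",
    noise_sd: float = 0.5,
    n_lambda: int = 12,
    n_samples: int = 500,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> LambdaSeries:
    """λ-series whose ground-truth ΔG is ``delta_g_target`` exactly.

    Per-λ ∂U/∂λ samples are Gaussian around a smooth mean curve integrating
    exactly to the target. Neighbor work samples follow the equal-variance
    Gaussian work model satisfying the Crooks relation for the same segment
    ΔG: W_fwd ~ N(Δg + βσ²/2, σ²), W_rev ~ N(−Δg + βσ²/2, σ²) with
    σ = ``noise_sd``, so BAR recovers the construction.
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    lam = np.linspace(0.0, 1.0, n_lambda)
    means = _shape_mean(delta_g_target, profile_shape, lam)
    dudl = [m + noise_sd * rng.standard_normal(n_samples) for m in means]

    seg = _segment_integrals(delta_g_target, profile_shape, lam)
    b = beta(temperature)
    half = b * noise_sd**2 / 2.0
    work_fwd = [
        dg + half + noise_sd * rng.standard_normal(n_samples) for dg in seg
    ]
    work_rev = [
        -dg + half + noise_sd * rng.standard_normal(n_samples) for dg in seg
    ]
    return LambdaSeries(
        lambdas=lam,
        dudl=dudl,
        work_fwd=work_fwd,
        work_rev=work_rev,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# distribution registry (serializable specs for distances/angles)

def sample_distribution(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n values from a registry distribution spec.

    Kinds: ``point`` (value), ``uniform`` (low, high), ``truncnorm``
    (mean, sd, low, high) and ``mixture`` (components: [{weight, dist}]).
    """
    kind = spec.get("kind")
    if kind == "point":
        return np.full(n, float(spec["value"]))
    if kind == "uniform":
        return rng.uniform(float(spec["low"]), float(spec["high"]), size=n)
    if kind == "truncnorm":
        mean, sd = float(spec["mean"]), float(spec["sd"])
        lo, hi = float(spec["low"]), float(spec["high"])
        a, bnd = (lo - mean) / sd, (hi - mean) / sd
        return stats.truncnorm.rvs(a, bnd, loc=mean, scale=sd, size=n, random_state=rng)
    if kind == "mixture":
        comps = spec["components"]
        weights = np.array([float(c["weight"]) for c in comps])
        weights = weights / weights.sum()
        which = rng.choice(len(comps), size=n, p=weights)
        out = np.empty(n)
        for k, comp in enumerate(comps):
            sel = which == k
            if sel.any():
                out[sel] = sample_distribution(comp["dist"], int(sel.sum()), rng)
        return out
    raise ValueError(f"unknown distribution kind {kind!r}")


# active-site placement convention (Å): leaving-group O6 at the origin, the
# methyl carbon on +x, the nucleophile in the xy-plane; the proton sits on
# the C10:N3–O6mG:N1 axis at the requested transfer asymmetry.
_R_O6_CM = 1.45
_N1G_POS = np.array([0.0, -2.3, 0.0])
_N3_POS = np.array([0.0, -5.2, 0.0])


def _synthetic_topology() -> Topology:
    return Topology(
        atom_names=("N3", "H3", "N1", "N1", "O6", "CM"),
        residue_ids=np.array([10, 10, 63, 91, 91, 91]),
        residue_names=("C", "C", "A", "6MG", "6MG", "6MG"),
        elements=("N", "H", "N", "N", "O", "C"),
    )


def gen_active_site_traj(
    n_frames: int,
    dist_dist: dict,
    angle_dist: dict,
    seed: int = 0,
    pt_asymmetry: float = -1.0,
    max_resample: int = 100,
) -> Trajectory:
    """Frames of the six mapped active-site atoms with drawn geometry.

    The nucleophile–electrophile distance (Cm–A63:N1, Å) and attack angle
    θ_inl (O6–Cm–A63:N1, deg) are drawn per frame from registry
    distributions; coordinates are placed so recomputing them reproduces
    the draws to ≤1e−9. Draws outside the physical ranges (distance > 0,
    angle in [0°, 180°]) are resampled and the count logged.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    dn1 = np.linalg.norm(_N3_POS - _N1G_POS)
    if not (-dn1 < pt_asymmetry < dn1):
        raise ValueError(f"pt_asymmetry must lie in (−{dn1:.2f}, {dn1:.2f})")
    rng = np.random.default_rng(seed)
    d = sample_distribution(dist_dist, n_frames, rng)
    theta = sample_distribution(angle_dist, n_frames, rng)
    resampled = 0
    for _ in range(max_resample):
        bad = ~((d > 0) & (theta >= 0.0) & (theta <= 180.0))
        if not bad.any():
            break
        resampled += int(bad.sum())
        d[bad] = sample_distribution(dist_dist, int(bad.sum()), rng)
        theta[bad] = sample_distribution(angle_dist, int(bad.sum()), rng)
    else:
        raise ValueError("could not draw physical geometry; check distributions")
    if resampled:
        logger.info("resampled %d unphysical geometry draws", resampled)

    top = _synthetic_topology()
    coords = np.empty((n_frames, top.n_atoms, 3))
    cm = np.array([_R_O6_CM, 0.0, 0.0])
    rad = np.radians(theta)
    n1a = cm[None, :] + np.column_stack(
        [-d * np.cos(rad), d * np.sin(rad), np.zeros(n_frames)]
    )
    r = (dn1 + pt_asymmetry) / 2.0
    h = _N3_POS + (r / dn1) * (_N1G_POS - _N3_POS)
    coords[:, 0] = _N3_POS
    coords[:, 1] = h
    coords[:, 2] = n1a
    coords[:, 3] = _N1G_POS
    coords[:, 4] = 0.0  # O6 at origin
    coords[:, 5] = cm
    return Trajectory(top, coords)


def gen_toy_structure(
    n_residues: int,
    atoms_per_residue: int,
    per_residue_sigma: Sequence[float] | float,
    n_models: int,
    seed: int = 0,
) -> tuple[Trajectory, Frame]:
    """Multi-model structure: reference + isotropic per-residue Gaussian noise.

    Each model displaces every atom of residue i by N(0, σᵢ²) per axis, so
    the expected RMS 3D fluctuation is σᵢ√3. The returned reference frame's
    trajectory carries B-factors computed as B = 8π²σᵢ² (the isotropic
    convention with ⟨Δr²⟩ = 3σᵢ²).
    """
    if n_models < 2:
        raise ValueError("need at least 2 models (fluctuations undefined)")
    if n_residues < 1 or atoms_per_residue < 1:
        raise ValueError("need at least one residue and one atom per residue")
    sigma = np.broadcast_to(
        np.atleast_1d(np.asarray(per_residue_sigma, dtype=float)), (n_residues,)
    )
    if np.any(sigma < 0):
        raise ValueError("sigmas must be >= 0")

    n_atoms = n_residues * atoms_per_residue
    resids = np.repeat(np.arange(1, n_residues + 1), atoms_per_residue)
    top = Topology(
        atom_names=tuple(f"C{j + 1}" for _ in range(n_residues) for j in range(atoms_per_residue)),
        residue_ids=resids,
        residue_names=tuple("G" for _ in range(n_atoms)),
        elements=tuple("C" for _ in range(n_atoms)),
    )
    # deterministic helix-like reference
    i = np.arange(n_atoms)
    phi = 0.6 * resids + 0.25 * (i % atoms_per_residue)
    ref = np.column_stack(
        [5.0 * np.cos(phi), 5.0 * np.sin(phi), 1.5 * resids + 0.3 * (i % atoms_per_residue)]
    )
    sigma_atom = sigma[resids - 1]
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_models, n_atoms, 3)) * sigma_atom[None, :, None]
    coords = ref[None, :, :] + noise
    bfac = np.asarray(sigma_to_bvalue(sigma_atom * math.sqrt(3.0)), dtype=float)
    traj = Trajectory(top, coords, bfactors=bfac)
    return traj, Frame(top, ref)
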