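"""Minimum free energy paths and stationary points on an estimated surface.

A zero-temperature string method relaxes a chain of images on the gridded
surface: steepest descent on the multilinear interpolant, followed by
reparameterization to equal arc length each iteration. The converged path's
1D profile is scanned for stationary points (R / TS1 / I / TS2 / P, or
R / TS / P for single-barrier profiles), and the path shape classifies the
mechanism as proton-transfer-first, methyl-transfer-first or concerted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .fes import FreeEnergySurface, project_profile


class PathError(RuntimeError):
    """String iteration failed; carries the convergence history."""

    def __init__(self, message: str, history: list[float] | None = None):
        super().__init__(message)
        self.history = history or []


class Mechanism(str, Enum):
    stepwise_pt_first = "stepwise_PT_first"
    stepwise_mt_first = "stepwise_MT_first"
    concerted = "concerted"


@dataclass(eq=False)
class ReactionPath:
    """Ordered images in (ξ_PT, ξ_MT) space with convergence history."""

    images: np.ndarray  # (n_images, 2)
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.atleast_2d(np.asarray(self.images, dtype=float))
        if self.images.shape[0] < 2:
            raise ValueError("a path needs at least two images")

    @classmethod
    def straight(cls, start, end, n_images: int = 32) -> "ReactionPath":
        start = np.asarray(start, dtype=float)
        end = np.asarray(end, dtype=float)
        t = np.linspace(0.0, 1.0, n_images)[:, None]
        return cls(start[None, :] * (1 - t) + end[None, :] * t)

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.images, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def progress(self) -> np.ndarray:
        arc = self.arc_length()
        total = arc[-1]
        if total <= 0:
            raise ValueError("path has zero length")
        return arc / total

    def resampled(self, n_images: int) -> np.ndarray:
        """Images redistributed to equal arc-length spacing."""
        arc = self.arc_length()
        if arc[-1] <= 0:
            raise ValueError("path has zero length")
        s = np.linspace(0.0, arc[-1], n_images)
        return np.column_stack(
            [np.interp(s, arc, self.images[:, d]) for d in range(self.images.shape[1])]
        )

    def to_dict(self) -> dict:
        return {"images": self.images.tolist(), "history": list(self.history)}


@dataclass
class StationaryPointSet:
    """Labeled stationary points with free energies relative to R.

    ``points`` maps labels (R, TS1, I, TS2, P — or R, TS, P) to
    (progress, ΔG) pairs with ΔG in kcal·mol⁻¹ relative to the reactant.
    """

    points: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if "R" not in self.points:
            raise ValueError("stationary point set must contain R")
        if abs(self.points["R"][1]) > 1e-12:
            raise ValueError("R must be anchored at 0")
        if "TS2" in self.points and "I" in self.points:
            if self.points["TS2"][1] < self.points["I"][1] - 1e-9:
                raise ValueError("TS2 must lie above the intermediate")

    @property
    def labels(self) -> list[str]:
        return sorted(self.points, key=lambda k: self.points[k][0])

    def energy(self, label: str) -> float:
        return self.points[label][1]

    @property
    def rate_controlling_barrier(self) -> float:
        """Highest transition-state free energy relative to R."""
        ts = [v for k, v in self.points.items() if k.startswith("TS")]
        if not ts:
            raise ValueError("no transition state present")
        return max(e for _, e in ts)

    @property
    def reaction_free_energy(self) -> float:
        return self.points["P"][1]

    def to_dict(self) -> dict:
        return {k: {"progress": p, "free_energy": e} for k, (p, e) in self.points.items()}


def string_mfep(
    surface: FreeEnergySurface,
    init_path: ReactionPath,
    n_images: int = 32,
    step: float = 0.01,
    tol: float = 1e-3,
    max_iter: int = 20_000,
) -> ReactionPath:
    """Zero-temperature string relaxation toward the minimum free energy path.

    Every image (endpoints included, so they settle into their basin
    minima) takes a steepest-descent step on the interpolated surface, with
    per-image displacement capped at half a grid cell for stability; images
    are then redistributed to equal arc length. Convergence is declared
    when the mean image displacement per iteration falls below ``tol`` Å.

    Raises :class:`PathError` if the path touches masked (unsampled) bins
    or fails to converge; the convergence history is attached.
    """
    if surface.ndim != 2:
        raise ValueError("string search needs a 2D surface")
    if n_images < 8:
        raise ValueError("n_images must be >= 8")
    values = surface.filled_values()
    axes = tuple(surface.axes)
    grads = np.gradient(values, *[a for a in surface.axes], edge_order=1)
    ginterp = [
        RegularGridInterpolator(axes, g, bounds_error=False, fill_value=None)
        for g in grads
    ]
    lo = np.array([a[0] for a in surface.axes])
    hi = np.array([a[-1] for a in surface.axes])
    cap = 0.5 * min(surface.spacing)

    images = ReactionPath(init_path.images).resampled(n_images)
    if surface.is_masked_at(images).any():
        raise PathError("initial path crosses masked (unsampled) bins")
    history: list[float] = []
    step_cur = step
    best = np.inf
    stall = 0
    for _ in range(max_iter):
        g = np.column_stack([gi(images) for gi in ginterp])
        # project out the tangential component (simplified string): moving
        # images along the curve only fights the reparameterization step
        tang = np.empty_like(images)
        tang[1:-1] = images[2:] - images[:-2]
        tang[0] = images[1] - images[0]
        tang[-1] = images[-1] - images[-2]
        norms_t = np.linalg.norm(tang, axis=1, keepdims=True)
        norms_t[norms_t == 0] = 1.0
        tang /= norms_t
        g_normal = g - (np.sum(g * tang, axis=1, keepdims=True)) * tang
        # endpoints descend freely so they settle into their basin minima
        g_normal[0] = g[0]
        g_normal[-1] = g[-1]
        disp = step_cur * g_normal
        norms = np.linalg.norm(disp, axis=1)
        big = norms > cap
        if big.any():
            disp[big] *= (cap / norms[big])[:, None]
        moved = np.clip(images - disp, lo, hi)
        # damp the sawtooth (zigzag) mode of the discrete string with a mild
        # curvature smoothing; scaling it with the step keeps the converged
        # curve independent of the step actually used
        moved[1:-1] += (5.0 * step_cur) * (moved[2:] + moved[:-2] - 2.0 * moved[1:-1])
        new = ReactionPath(moved).resampled(n_images)
        delta = float(np.mean(np.linalg.norm(new - images, axis=1)))
        history.append(delta)
        images = new
        if surface.is_masked_at(images).any():
            raise PathError("path trapped on masked bins", history)
        if delta < tol:
            return ReactionPath(images, history)
        # adaptive damping: where step*curvature is too large the images
        # overshoot and oscillate; halve the step when progress stalls
        if delta < best * 0.98:
            best = delta
            stall = 0
        else:
            stall += 1
            if stall >= 30:
                step_cur = max(step_cur * 0.5, 1e-6)
                stall = 0
    raise PathError(
        f"string did not converge in {max_iter} iterations "
        f"(last displacement {history[-1]:.2e} > tol {tol:.1e})",
        history,
    )


def path_profile(
    surface: FreeEnergySurface, path: ReactionPath, n_points: int = 200
) -> pd.DataFrame:
    """Free-energy profile along a path (thin wrapper over the projector)."""
    return project_profile(surface, path.images, n_points=n_points)


def _moving_average(y: np.ndarray, width: int = 5) -> np.ndarray:
    half = width // 2
    padded = np.pad(y, half, mode="edge")
    kernel = np.ones(width) / width
    return np.convolve(padded, kernel, mode="valid")


def _refine_extremum(x: np.ndarray, y: np.ndarray, idx: int, window: int = 5):
    """Local quadratic fit around a discrete extremum; falls back to the raw point."""
    half = window // 2
    lo = max(0, idx - half)
    hi = min(len(x), idx + half + 1)
    xs, ys = x[lo:hi], y[lo:hi]
    if xs.size < 3:
        return float(x[idx]), float(y[idx])
    c = np.polyfit(xs - x[idx], ys, 2)
    if c[0] == 0:
        return float(x[idx]), float(y[idx])
    xv = -c[1] / (2 * c[0])
    if not (xs[0] - x[idx] <= xv <= xs[-1] - x[idx]):
        return float(x[idx]), float(y[idx])
    yv = float(np.polyval(c, xv))
    return float(x[idx] + xv), yv


def stationary_points(
    progress: np.ndarray, free_energy: np.ndarray, smooth_width: int = 5
) -> StationaryPointSet:
    """Extract labeled stationary points from a 1D free-energy profile.

    Interior extrema are detected on a lightly smoothed copy (moving
    average) and refined by a local quadratic fit on the raw profile, ties
    broken toward lower progress. Profiles with one interior maximum are
    labeled R/TS/P; with two maxima flanking a minimum, R/TS1/I/TS2/P.
    Energies are reported relative to the first point (R = 0).
    """
    x = np.asarray(progress, dtype=float)
    y = np.asarray(free_energy, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("profile needs at least 5 points")
    ys = _moving_average(y, smooth_width) if smooth_width > 1 else y

    maxima, minima = [], []
    i = 1
    while i < x.size - 1:
        # treat plateaus as single candidates, tie toward lower progress
        j = i
        while j + 1 < x.size - 1 and ys[j + 1] == ys[j]:
            j += 1
        if ys[i - 1] < ys[i] and ys[j] > ys[j + 1]:
            maxima.append(i)
        elif ys[i - 1] > ys[i] and ys[j] < ys[j + 1]:
            minima.append(i)
        i = j + 1
    if not maxima:
        raise ValueError("no barrier: profile has no interior maximum")

    y0 = y[0]
    pts: dict[str, tuple[float, float]] = {"R": (float(x[0]), 0.0)}
    pts["P"] = (float(x[-1]), float(y[-1] - y0))

    if len(maxima) == 1:
        xp, yp = _refine_extremum(x, y, maxima[0])
        pts["TS"] = (xp, yp - y0)
    else:
        # keep the two highest maxima (in progress order) and the lowest
        # minimum between them
        top2 = sorted(sorted(maxima, key=lambda k: -y[k])[:2])
        between = [k for k in minima if top2[0] < k < top2[1]]
        x1, e1 = _refine_extremum(x, y, top2[0])
        x2, e2 = _refine_extremum(x, y, top2[1])
        pts["TS1"] = (x1, e1 - y0)
        pts["TS2"] = (x2, e2 - y0)
        if between:
            kmin = min(between, key=lambda k: y[k])
            xi, ei = _refine_extremum(x, y, kmin)
            pts["I"] = (xi, ei - y0)
    return StationaryPointSet(pts)


def classify_mechanism(
    path: ReactionPath, pt_done: float = 0.5, mt_done: float = -1.0
) -> Mechanism:
    """Classify a reactant→product path as stepwise or concerted.

    Endpoints must sit in the reactant (ξ_PT < 0, ξ_MT < 0) and product
    (ξ_PT > 0, ξ_MT > 0) quadrants. The mechanism is proton-transfer-first
    when the path reaches ξ_PT ≥ ``pt_done`` while methyl transfer has not
    begun (ξ_MT ≤ ``mt_done``); the mirrored condition (ξ_MT ≥ −``mt_done``
    while ξ_PT ≤ −``pt_done``) is methyl-transfer-first; otherwise the
    transfers advance together and the path is concerted.
    """
    pts = path.images
    if not (pts[0, 0] < 0 and pts[0, 1] < 0):
        raise ValueError("path must start in the reactant quadrant (ξPT<0, ξMT<0)")
    if not (pts[-1, 0] > 0 and pts[-1, 1] > 0):
        raise ValueError("path must end in the product quadrant (ξPT>0, ξMT>0)")
    dense = ReactionPath(pts).resampled(max(200, 4 * path.n_images))
    pt_first = np.any((dense[:, 0] >= pt_done) & (dense[:, 1] <= mt_done))
    mt_first = np.any((dense[:, 1] >= -mt_done) & (dense[:, 0] <= -pt_done))
    if pt_first and not mt_first:
        return Mechanism.stepwise_pt_first
    if mt_first and not pt_first:
        return Mechanism.stepwise_mt_first
    return Mechanism.concerted
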