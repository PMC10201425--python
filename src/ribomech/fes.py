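"""Free-energy-surface reconstruction from umbrella-window samples.

Biased samples of the reaction coordinates (ξ_PT, ξ_MT) collected under
harmonic restraints ½k(ξ−ξ⁰)² are combined with the weighted histogram
analysis method (WHAM) into a gridded 1D or 2D free-energy surface in
kcal·mol⁻¹, anchored so the minimum sampled bin is zero. Unsampled bins are
masked (+∞), never silently interpolated. Per-bin standard errors come from
a block bootstrap over within-window sample blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

from .constants import R_KCAL, beta

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """WHAM iteration did not reach tolerance; carries the final residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DisconnectedWindowsError(ValueError):
    """Umbrella windows form non-overlapping islands in bin space."""

    def __init__(self, components: list[list[int]]):
        self.components = components
        super().__init__(
            "umbrella windows form disconnected islands (window indices): "
            + "; ".join(str(c) for c in components)
        )


@dataclass(eq=False)
class UmbrellaWindow:
    """One biased simulation: center/force constant per coordinate + samples."""

    center: np.ndarray  # (2,) Å
    kforce: np.ndarray  # (2,) kcal·mol⁻¹·Å⁻²
    samples: np.ndarray  # (n, 2) Å

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.kforce = np.atleast_1d(np.asarray(self.kforce, dtype=float))
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.center.shape != (2,) or self.kforce.shape != (2,):
            raise ValueError("windows are 2D: center and kforce must have length 2")
        if self.samples.shape[1] != 2:
            raise ValueError("samples must be (n, 2)")
        if self.samples.shape[0] < 1:
            raise ValueError("every window needs at least one sample")
        if np.any(self.kforce < 0):
            raise ValueError("force constants must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass(eq=False)
class UmbrellaWindowSet:
    """All umbrella windows of one study plus the common temperature (K)."""

    windows: list[UmbrellaWindow]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if len(self.windows) == 0:
            raise ValueError("zero umbrella windows")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def total_samples(self) -> int:
        return sum(w.n_samples for w in self.windows)


@dataclass(eq=False)
class GridSpec:
    """Uniform bin-center grid per axis: ``lo:hi:step`` inclusive of ends."""

    lo: tuple[float, ...]
    hi: tuple[float, ...]
    step: tuple[float, ...]

    @classmethod
    def parse(cls, text: str) -> "GridSpec":
        """Parse e.g. ``"-1.5:1.5:0.2,-2.5:2.5:0.2"`` (one or two axes)."""
        lo, hi, step = [], [], []
        for part in text.split(","):
            bits = part.split(":")
            if len(bits) != 3:
                raise ValueError(f"bad grid axis spec {part!r}, want lo:hi:step")
            a, b, s = (float(x) for x in bits)
            if s <= 0 or b <= a:
                raise ValueError(f"bad grid axis spec {part!r}")
            lo.append(a)
            hi.append(b)
            step.append(s)
        return cls(tuple(lo), tuple(hi), tuple(step))

    @property
    def ndim(self) -> int:
        return len(self.lo)

    def centers(self) -> list[np.ndarray]:
        out = []
        for a, b, s in zip(self.lo, self.hi, self.step):
            n = int(round((b - a) / s)) + 1
            out.append(a + s * np.arange(n))
        return out


@dataclass(eq=False)
class FreeEnergySurface:
    """Gridded free energy over bin centers, kcal·mol⁻¹, min anchored at 0.

    ``mask`` flags bins with zero occupancy; their ``values`` are +∞ and any
    path search must refuse to traverse them. ``se`` is filled by
    :func:`fes_uncertainty` (NaN until then).
    """

    axes: list[np.ndarray]
    values: np.ndarray
    counts: np.ndarray
    mask: np.ndarray
    temperature: float
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.axes = [np.asarray(a, dtype=float) for a in self.axes]
        shape = tuple(a.size for a in self.axes)
        if self.values.shape != shape:
            raise ValueError("values shape does not match axes")
        finite = self.values[~self.mask]
        if finite.size and abs(finite.min()) > 1e-9:
            raise ValueError("surface must be anchored to min 0")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(float(a[1] - a[0]) if a.size > 1 else 1.0 for a in self.axes)

    @classmethod
    def from_function(
        cls, func, grid: GridSpec, temperature: float = 298.15
    ) -> "FreeEnergySurface":
        """Exact surface from an analytic energy function (testbeds, demos)."""
        axes = grid.centers()
        if grid.ndim == 1:
            pts = axes[0][:, None]
        else:
            xx, yy = np.meshgrid(axes[0], axes[1], indexing="ij")
            pts = np.column_stack([xx.ravel(), yy.ravel()])
        vals = np.asarray(func(pts), dtype=float).reshape(
            tuple(a.size for a in axes)
        )
        vals = vals - vals.min()
        return cls(
            axes=axes,
            values=vals,
            counts=np.ones_like(vals, dtype=int),
            mask=np.zeros_like(vals, dtype=bool),
            temperature=temperature,
        )

    def filled_values(self, pad: float = 50.0) -> np.ndarray:
        """Values with masked bins replaced by (finite max + pad), for interpolation."""
        out = self.values.copy()
        finite = out[~self.mask]
        fill = (finite.max() if finite.size else 0.0) + pad
        out[self.mask] = fill
        return out

    def is_masked_at(self, points: np.ndarray) -> np.ndarray:
        """True where the nearest bin of each query point is masked."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        idx = []
        for d, ax in enumerate(self.axes):
            i = np.clip(
                np.round((points[:, d] - ax[0]) / (ax[1] - ax[0])).astype(int),
                0,
                ax.size - 1,
            )
            idx.append(i)
        return self.mask[tuple(idx)]


def _bin_index(samples: np.ndarray, axes: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-bin flat index per sample; second array flags in-grid samples."""
    nd = len(axes)
    shape = tuple(a.size for a in axes)
    ok = np.ones(samples.shape[0], dtype=bool)
    multi = []
    for d in range(nd):
        ax = axes[d]
        step = ax[1] - ax[0] if ax.size > 1 else 1.0
        i = np.round((samples[:, d] - ax[0]) / step).astype(int)
        ok &= (i >= 0) & (i < ax.size)
        multi.append(np.clip(i, 0, ax.size - 1))
    flat = np.ravel_multi_index(tuple(multi), shape)
    return flat, ok


def wham(
    windows: UmbrellaWindowSet,
    grid: GridSpec,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> FreeEnergySurface:
    """Self-consistent WHAM on a binned grid.

    Iterates the coupled equations for the unbiased bin probabilities and
    the per-window free energies until the relative change in window free
    energies drops below ``tol``. A 1D grid may be requested only when the
    second coordinate is unbiased in every window (k_MT = 0).

    Raises
    ------
    DisconnectedWindowsError
        if the windows' occupied bins form disjoint islands (the relative
        free energies between islands would be undefined).
    ConvergenceError
        if ``max_iter`` is exhausted; the final residual is attached.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    axes = grid.centers()
    nd = grid.ndim
    if nd == 1:
        if any(w.kforce[1] != 0.0 for w in windows.windows):
            raise ValueError(
                "1D grid requested but some windows bias the second coordinate"
            )
        proj = [w.samples[:, :1] for w in windows.windows]
        centers = np.array([w.center[:1] for w in windows.windows])
        kf = np.array([w.kforce[:1] for w in windows.windows])
    else:
        proj = [w.samples for w in windows.windows]
        centers = np.array([w.center for w in windows.windows])
        kf = np.array([w.kforce for w in windows.windows])

    shape = tuple(a.size for a in axes)
    n_bins = int(np.prod(shape))
    n_win = len(windows)

    counts = np.zeros(n_bins, dtype=int)
    win_occupied = []
    n_retained = np.empty(n_win)
    dropped = 0
    for i, s in enumerate(proj):
        flat, ok = _bin_index(s, axes)
        dropped += int((~ok).sum())
        flat = flat[ok]
        if flat.size == 0:
            raise ValueError(f"window {i} has no samples inside the grid")
        counts += np.bincount(flat, minlength=n_bins)
        win_occupied.append(np.unique(flat))
        n_retained[i] = flat.size
    if dropped:
        logger.warning("dropped %d samples falling outside the grid", dropped)

    occ = counts > 0
    if not occ.any():
        raise ValueError("no samples fall inside the grid")

    # window-overlap connectivity through shared occupied bins
    adj = np.zeros((n_win, n_win), dtype=bool)
    for i in range(n_win):
        for j in range(i + 1, n_win):
            if np.intersect1d(win_occupied[i], win_occupied[j]).size:
                adj[i, j] = adj[j, i] = True
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        comps = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]
        raise DisconnectedWindowsError(comps)

    b = beta(windows.temperature)
    occ_idx = np.flatnonzero(occ)
    bin_coords = np.stack(
        [np.asarray(g).ravel()[occ_idx] for g in np.meshgrid(*axes, indexing="ij")],
        axis=1,
    )
    # bias energy of window i evaluated at occupied bin centers: (n_win, n_occ)
    bias = 0.5 * np.einsum(
        "id,iod->io",
        kf,
        (bin_coords[None, :, :] - centers[:, None, :]) ** 2,
    )
    neg_b_bias = -b * bias
    log_m = np.log(counts[occ_idx].astype(float))
    log_n = np.log(n_retained)  # samples actually inside the grid per window

    f = np.zeros(n_win)  # window free energies, kcal/mol
    residual = np.inf
    for _ in range(max_iter):
        # log denominator per occupied bin: logsumexp_i [ln N_i + βf_i − βw_i(b)]
        log_den = logsumexp(log_n[:, None] + b * f[:, None] + neg_b_bias, axis=0)
        log_p = log_m - log_den
        f_new = -logsumexp(log_p[None, :] + neg_b_bias, axis=1) / b
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)) / (1.0 + np.max(np.abs(f_new))))
        f = f_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} > tol {tol:.1e})",
            residual=residual,
        )

    log_den = logsumexp(log_n[:, None] + b * f[:, None] + neg_b_bias, axis=0)
    log_p = log_m - log_den
    fe = np.full(n_bins, np.inf)
    fe[occ_idx] = -(log_p) / b
    fe[occ_idx] -= fe[occ_idx].min()
    return FreeEnergySurface(
        axes=axes,
        values=fe.reshape(shape),
        counts=counts.reshape(shape),
        mask=(~occ).reshape(shape),
        temperature=windows.temperature,
    )


def project_profile(
    surface: FreeEnergySurface,
    path_points: np.ndarray,
    n_points: int = 200,
    bandwidth: float | None = None,
) -> pd.DataFrame:
    """Free-energy profile along an arc-length-parameterized path.

    The path polyline is resampled to ``n_points`` equally spaced arc-length
    positions, the surface is evaluated there by multilinear interpolation,
    and the profile is reported against normalized reaction progress in
    [0, 1]. ``bandwidth`` (Å of arc length) optionally applies a boxcar
    smoothing. Raises if any resampled point falls in a masked bin, naming
    the offending image index.
    """
    from scipy.interpolate import RegularGridInterpolator

    pts = np.atleast_2d(np.asarray(path_points, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("path needs at least two images")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        raise ValueError("path has zero length")

    bad = np.flatnonzero(surface.is_masked_at(pts))
    if bad.size:
        raise ValueError(f"path exits sampled region at image index {bad[0]}")

    s = np.linspace(0.0, arc[-1], n_points)
    resampled = np.column_stack(
        [np.interp(s, arc, pts[:, d]) for d in range(pts.shape[1])]
    )
    interp = RegularGridInterpolator(
        tuple(surface.axes), surface.filled_values(), bounds_error=False, fill_value=None
    )
    vals = interp(resampled)
    if surface.se is not None:
        se_grid = np.nan_to_num(surface.se, nan=0.0)
        se = RegularGridInterpolator(
            tuple(surface.axes), se_grid, bounds_error=False, fill_value=None
        )(resampled)
    else:
        se = np.full(n_points, np.nan)
    if bandwidth is not None and bandwidth > 0:
        half = max(1, int(round(bandwidth / (s[1] - s[0]) / 2)))
        kernel = np.ones(2 * half + 1) / (2 * half + 1)
        vals = np.convolve(np.pad(vals, half, mode="edge"), kernel, mode="valid")
    return pd.DataFrame(
        {"progress": s / arc[-1], "free_energy": vals, "se": se}
    )


def fes_uncertainty(
    windows: UmbrellaWindowSet,
    grid: GridSpec,
    n_blocks: int = 5,
    n_boot: int = 50,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Per-bin standard error of the WHAM surface by block bootstrap.

    Each window's sample series is cut into ``n_blocks`` contiguous blocks
    (preserving short-range correlation inside a block); replicates redraw
    blocks with replacement per window and rerun WHAM. The SE is the
    bootstrap standard deviation per bin, NaN where fewer than two
    replicates produced a finite value.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    for w in windows.windows:
        if w.n_samples < n_blocks:
            raise ValueError(
                f"window has {w.n_samples} samples, fewer than {n_blocks} blocks"
            )
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        new = []
        for w in windows.windows:
            blocks = np.array_split(np.arange(w.n_samples), n_blocks)
            pick = rng.integers(0, n_blocks, size=n_blocks)
            idx = np.concatenate([blocks[p] for p in pick])
            new.append(UmbrellaWindow(w.center, w.kforce, w.samples[idx]))
        try:
            fesb = wham(
                UmbrellaWindowSet(new, windows.temperature),
                grid,
                tol=tol,
                max_iter=max_iter,
            )
        except DisconnectedWindowsError:
            continue
        reps.append(np.where(fesb.mask, np.nan, fesb.values))
    if len(reps) < 2:
        raise ConvergenceError("fewer than two usable bootstrap replicates")
    stack = np.stack(reps)
    with np.errstate(invalid="ignore"):
        se = np.nanstd(stack, axis=0, ddof=1)
    se[np.sum(np.isfinite(stack), axis=0) < 2] = np.nan
    return se
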