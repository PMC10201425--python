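"""Independent MBAR reference implementation for cross-checking WHAM.

Self-consistent multistate Bennett acceptance ratio on the *unbinned*
pooled samples (no histogram), deliberately sharing no code path with the
package's binned WHAM estimator. Test-support code only.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from ribomech.constants import beta
from ribomech.fes import UmbrellaWindowSet


def mbar_pmf(
    windows: UmbrellaWindowSet,
    bin_edges: np.ndarray,
    coord: int = 0,
    tol: float = 1e-10,
    max_iter: int = 20_000,
) -> tuple[np.ndarray, np.ndarray]:
    """PMF over 1D bins from MBAR weights.

    Returns (bin_centers, free_energy) with the minimum anchored at zero;
    bins without samples carry +inf.
    """
    b = beta(windows.temperature)
    pooled = np.concatenate([w.samples for w in windows.windows])  # (N, 2)
    n_k = np.array([w.n_samples for w in windows.windows], dtype=float)
    centers = np.stack([w.center for w in windows.windows])
    kf = np.stack([w.kforce for w in windows.windows])

    # reduced bias energy of every pooled sample in every window's ensemble
    diff = pooled[None, :, :] - centers[:, None, :]
    u = b * 0.5 * np.sum(kf[:, None, :] * diff**2, axis=2)  # (n_windows, N)

    log_n = np.log(n_k)
    f = np.zeros(len(n_k))
    for _ in range(max_iter):
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)  # (N,)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new

    log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
    log_w = -log_denom  # unnormalized log weight of each sample, unbiased ensemble
    x = pooled[:, coord]
    idx = np.digitize(x, bin_edges) - 1
    n_bins = bin_edges.size - 1
    pmf = np.full(n_bins, np.inf)
    for k in range(n_bins):
        sel = idx == k
        if sel.any():
            pmf[k] = -logsumexp(log_w[sel]) / b
    finite = np.isfinite(pmf)
    pmf[finite] -= pmf[finite].min()
    mids = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return mids, pmf
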