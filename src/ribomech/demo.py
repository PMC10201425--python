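"""End-to-end synthetic demonstration pipeline.

Chains every stage on generated data with known ground truth: umbrella
sampling + WHAM on a double-well coordinate, a string-method path with
stationary points and mechanism call on a two-channel surface, an Eyring
rate from the rate-controlling barrier, alchemical pKa legs integrated to
an apparent pKa, and a predicted-then-refitted activity–pH profile. Used by
``ribomech report`` and reusable programmatically.
"""

from __future__ import annotations

import numpy as np

from .afe import AfeDeprotonationPair, apparent_pka, bar_series, delta_pka, ti_integrate
from .fes import FreeEnergySurface, GridSpec, wham
from .kinetics import PhRateModel, ThermoContext, fit_ph_profile, predict_ph_profile, tst_rate
from .pathway import ReactionPath, classify_mechanism, path_profile, stationary_points, string_mfep
from .synthetic import (
    AnalyticPotential,
    SamplerConfig,
    dense_grid_extrema,
    gen_lambda_series,
    gen_umbrella_samples,
)

# demo problem sizes: small enough for an interactive run, large enough
# that every recovered quantity is statistically meaningful
N_WINDOWS = 16
N_SAMPLES_PER_WINDOW = 1500
N_LAMBDA = 12
N_SAMPLES_PER_LAMBDA = 400


def _quad_vertex_value(x: np.ndarray, y: np.ndarray, around: float, half_width: float) -> float:
    """Value at the vertex of a local quadratic fit to (x, y) near ``around``."""
    sel = np.isfinite(y) & (np.abs(x - around) <= half_width)
    if sel.sum() < 3:
        raise ValueError("too few finite bins for a local quadratic fit")
    c = np.polyfit(x[sel] - around, y[sel], 2)
    xv = float(np.clip(-c[1] / (2 * c[0]), -half_width, half_width)) if c[0] != 0 else 0.0
    return float(np.polyval(c, xv))


def double_well_barrier(fes1d) -> float:
    """Barrier of a symmetric double-well surface: top vertex minus well vertices.

    Local quadratic fits around the barrier top (x ≈ 0) and the two wells
    (x ≈ ±1) average out per-bin statistical noise without the downward
    bias of a min-over-bins estimate.
    """
    x = fes1d.axes[0]
    y = np.where(fes1d.mask, np.nan, fes1d.values)
    top = _quad_vertex_value(x, y, 0.0, 0.2)
    wells = 0.5 * (_quad_vertex_value(x, y, -1.0, 0.2) + _quad_vertex_value(x, y, 1.0, 0.2))
    return top - wells


def run_demo(seed: int = 0, temperature: float = 298.15) -> dict:
    """Run the full pipeline; returns a JSON-serializable summary."""
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]

    # 1) umbrella sampling + WHAM on the double well (barrier ground truth = a)
    a = 5.0
    pot = AnalyticPotential.make("double_well_1d", a=a)
    centers = [[c] for c in np.linspace(-1.5, 1.5, N_WINDOWS)]
    ws = gen_umbrella_samples(
        pot,
        centers,
        100.0,
        SamplerConfig(
            n_samples_per_window=N_SAMPLES_PER_WINDOW,
            burn_in=500,
            temperature=temperature,
            seed=sub[0],
        ),
    )
    grid1 = GridSpec((-1.5,), (1.5,), (0.05,))
    fes1 = wham(ws, grid1)
    barrier = double_well_barrier(fes1)

    # 2) string MFEP + stationary points + mechanism on the two-channel
    # surface; the well depth is scaled so the rate-controlling barrier
    # (a − c ≈ 19.4 kcal/mol) sits in the experimentally relevant range
    pot2 = AnalyticPotential.make("two_channel_2d", a=22.4, c=3.0)
    grid2 = GridSpec((-1.6, -1.6), (1.6, 1.6), (0.04, 0.04))
    fes2 = FreeEnergySurface.from_function(pot2.energy, grid2, temperature=temperature)
    oracle = dense_grid_extrema(pot2)
    path = string_mfep(
        fes2, ReactionPath.straight((-1.0, -1.0), (1.0, 1.0), 32), n_images=32
    )
    profile = path_profile(fes2, path)
    sp = stationary_points(profile["progress"].to_numpy(), profile["free_energy"].to_numpy())
    mech = classify_mechanism(path)
    saddle = np.asarray(oracle["saddle"]["xy"])
    dense = path.resampled(1024)  # closest approach of the continuous path
    saddle_offset = float(np.min(np.linalg.norm(dense - saddle, axis=1)))

    # 3) Eyring rate from the demo surface's rate-controlling barrier
    ctx = ThermoContext(temperature=temperature)
    k_int = tst_rate(sp.rate_controlling_barrier, ctx)

    # 4) alchemical pKa: two deprotonation legs with a known ΔΔG
    dg_rna_true, dg_aq_true = 7.00, 4.19  # ΔΔG = 2.81 kcal/mol
    rna = gen_lambda_series(
        dg_rna_true, "linear", 0.5, N_LAMBDA, N_SAMPLES_PER_LAMBDA, seed=sub[1],
        temperature=temperature,
    )
    aq = gen_lambda_series(
        dg_aq_true, "linear", 0.5, N_LAMBDA, N_SAMPLES_PER_LAMBDA, seed=sub[2],
        temperature=temperature,
    )
    ti_rna, ti_aq = ti_integrate(rna), ti_integrate(aq)
    bar_rna, bar_aq = bar_series(rna), bar_series(aq)
    shift = delta_pka(AfeDeprotonationPair(ti_rna, ti_aq, temperature=temperature))
    acid = apparent_pka(4.2, shift)

    # 5) activity–pH profile: predict from the model, then refit a noisy copy
    model = PhRateModel(k_int=k_int, pka_a=acid.apparent_pka, pka_b=5.0)
    ph = np.linspace(3.5, 8.5, 21)
    profile_df = predict_ph_profile(model, ph)
    noisy = profile_df.copy()
    noise_rng = np.random.default_rng(sub[3])
    noisy["k_obs"] = noisy["k_obs"] * np.exp(0.1 * noise_rng.standard_normal(ph.size))
    fit = fit_ph_profile(noisy)

    return {
        "seed": seed,
        "temperature": temperature,
        "sizes": {
            "umbrella_windows": N_WINDOWS,
            "samples_per_window": N_SAMPLES_PER_WINDOW,
            "n_lambda": N_LAMBDA,
            "samples_per_lambda": N_SAMPLES_PER_LAMBDA,
        },
        "fes": {
            "double_well_barrier_true": a,
            "double_well_barrier_wham": barrier,
        },
        "path": {
            "mechanism": mech.value,
            "stationary_points": sp.to_dict(),
            "saddle_offset_from_grid_oracle": saddle_offset,
            "saddle_energy_oracle": oracle["saddle"]["energy"],
        },
        "rates": {
            "rate_controlling_barrier": sp.rate_controlling_barrier,
            "k_int_per_min": k_int,
        },
        "pka": {
            "ti": {"dg_rna": ti_rna.value, "dg_aq": ti_aq.value,
                   "true_rna": dg_rna_true, "true_aq": dg_aq_true},
            "bar": {"dg_rna": bar_rna.value, "dg_aq": bar_aq.value},
            "delta_pka": shift.value,
            "delta_pka_se": shift.se,
            "apparent_pka": acid.apparent_pka,
        },
        "ph_profile": {
            "model": model.to_dict(),
            "ph_optimum": model.ph_optimum,
            "refit": fit.model.to_dict(),
        },
    }
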