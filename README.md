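# ribomech

Analysis toolkit for mechanistic studies of the MTR1 methyltransferase
ribozyme — an in-vitro-selected RNA enzyme that transfers a methyl group
from *O*⁶-methylguanine (O6mG) to the N1 of a target adenine (A63), with a
protonated active-site cytosine (C10) acting as general acid. The package
implements the analysis layer that sits downstream of molecular simulation:
given trajectories, biased reaction-coordinate samples and alchemical
λ-series (real or synthetic), it reconstructs free-energy surfaces,
extracts reaction paths and barriers, converts barriers to rates, computes
pKa shifts, and predicts activity–pH profiles.

## What it computes

**Reaction coordinates and active-state geometry.** Proton- and
methyl-transfer progress variables as differences of distances,

    ξ_PT = |R(C10:N3) − R(H)| − |R(O6mG:N1) − R(H)|
    ξ_MT = |R(O6mG:O6) − R(Cm)| − |R(A63:N1) − R(Cm)|   (Å),

plus inline fitness (fraction of frames with the nucleophile–electrophile
distance in [2.75, 3.50] Å and the attack angle θ_inl in [140°, 180°]),
Kabsch-superposed RMSD, per-nucleotide fluctuations with the isotropic
B-value convention B = (8π²/3)·⟨Δr²⟩, and geometric hydrogen-bond
occupancy.

**Free-energy surfaces.** WHAM (weighted histogram analysis method) over
1D/2D grids from harmonic umbrella windows, with block-bootstrap per-bin
standard errors and masked (never interpolated) unsampled bins.

**Paths and mechanism.** A simplified zero-temperature string method finds
the minimum free energy path on the estimated surface; stationary points
are labeled R / TS1 / I / TS2 / P (or R / TS / P), and the path shape is
classified as proton-transfer-first, methyl-transfer-first, or concerted.

**Rates and pH profiles.** Eyring rates k = κ(k_BT/h)·exp(−ΔG‡/RT) in
min⁻¹; alchemical ΔG legs by thermodynamic integration or Bennett
acceptance ratio; pKa shifts ΔpKa = ΔΔG/(RT ln 10); and the two-state
noncooperative activity–pH model

    k_obs(pH) = k_int / (1 + 10^(pKa_B−pH) + 10^(pH−pKa_A) + 10^(pKa_B−pKa_A)),

with prediction and weighted nonlinear least-squares fitting.

**Synthetic data.** Every input can be generated with known ground truth:
Metropolis-sampled umbrella windows over analytic potentials, λ-series with
an exact ΔG and Crooks-consistent Gaussian work samples, active-site
trajectories with prescribed distance/angle distributions, and multi-model
structures with per-residue Gaussian disorder.

## Worked example

```python
import numpy as np
import ribomech as rm
from ribomech.fes import GridSpec
from ribomech.synthetic import AnalyticPotential, SamplerConfig
from ribomech.demo import double_well_barrier

# umbrella sampling on a double well with a known 5 kcal/mol barrier
pot = AnalyticPotential.make("double_well_1d", a=5.0)
windows = rm.gen_umbrella_samples(
    pot, [[c] for c in np.linspace(-1.5, 1.5, 16)], 100.0,
    SamplerConfig(n_samples_per_window=5000, seed=42),
)
fes = rm.wham(windows, GridSpec((-1.5,), (1.5,), (0.05,)))
print(round(double_well_barrier(fes), 2))          # 4.98  (truth: 5.00)

# apparent pKa of the general acid from its solution value and AFE shift
print(rm.apparent_pka(4.2, 2.06).apparent_pka)     # 6.26

# rate at the mutant's 32.59 kcal/mol barrier: below detection limit
print(rm.tst_rate(32.59) < 1e-6)                   # True

# activity-pH profile peaks midway between the two apparent pKa values
model = rm.PhRateModel(k_int=0.45, pka_a=6.26, pka_b=5.0)
print(round(model.ph_optimum, 2))                  # 5.63
print(round(rm.ph_fraction(model, 5.63), 3))       # 0.656
```

The WHAM barrier (4.98 kcal/mol) recovers the constructed 5.00 within the
sampling uncertainty; 6.26 is the predicted apparent pKa of the C10 general
acid (solution cytosine pKa 4.2 upshifted 2.06 units by the ribozyme
environment); the mutant barrier corresponds to a rate below the 10⁻⁶ min⁻¹
experimental detection limit; and the bell-shaped pH profile attains 65.6%
of the intrinsic rate at its optimum.

A command-line interface mirrors the library:

```bash
ribomech report --seed 11 --out demo/     # full synthetic end-to-end run
ribomech rates --barrier 19.43
ribomech ph-profile --kint 0.45 --pka-a 6.26 --pka-b 5.0
ribomech fes --windows w.csv --grid "-1.5:1.5:0.2,-2.5:2.5:0.2"
```

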