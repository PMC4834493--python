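# flipbind

Desk-scale tools for dissecting how a type-II kinase inhibitor binds its
target: free-energy landscapes along a path collective variable, binding
thermodynamics and unbinding kinetics, and the NMR/SPR observables that
constrain them.

## The scientific problem

Type-II inhibitors such as Imatinib bind the inactive "DFG-out"
conformation of tyrosine kinases. Whether the kinase flips before the drug
binds (conformational selection, *flip-bind*) or the drug drives the flip
(induced fit, *bind-flip*) is resolved by combining:

- a **free-energy profile F(s)** along a path progress variable
  `s = Σᵢ i·e^(−λdᵢ²) / Σᵢ e^(−λdᵢ²)` spanning bound → unbound, with its
  off-path distance `z = −(1/λ)·ln Σᵢ e^(−λdᵢ²)`;
- **basin thermodynamics**: ΔG between basins by Boltzmann quadrature
  `ΔG = −kT·ln(∫_X e^(−βF) ds / ∫_Y e^(−βF) ds)`, the 1 M standard-state
  correction `kT·ln(V/V₀)` with V₀ = 1660 Å³, and closure of the
  flip-bind vs bind-flip thermodynamic cycle;
- **unbinding kinetics** in the Eyring form
  `k_off = (kT/h)·κ·e^(−ΔG‡/kT)`, where the transmission coefficient κ is
  measured from unbiased trajectories shot off interfaces across the
  barrier (transition-interface-sampling style) and κ ≪ 1 signals a
  diffusive, non-TST crossing;
- **NMR observables**: Lipari–Szabo model-free S²/τc from ¹⁵N R1/R2/NOE,
  R1R2 exchange flags, combined ¹H/¹⁵N chemical-shift perturbations
  `Δδ = √(ΔδH² + (0.15·ΔδN)²)`, chemical-shift indices, H/D-exchange
  protection factors with `ΔG_unfold = RT·ln P`, and SPR dissociation
  fits `R(t) = R₀e^(−k_d t) + c`.

Because the real inputs (μs enhanced-sampling MD of a solvated kinase,
spectrometer data) are not reproducible at desk scale, every stage runs on
**synthetic data with known ground truth**: calibrated toy landscapes whose
topography mirrors a kinase–inhibitor profile (two near-degenerate bound
poses A/B, the main barrier at s ≈ 12, an external pose C at s ≈ 15.5
sitting 4 kcal/mol above A, a flat unbound plateau), BAOAB Langevin
dynamics, well-tempered multiple-walker metadynamics, and per-residue
relaxation/shift/HDX/SPR tables generated from the same forward models the
fitters invert. Every fitter is tested by parameter recovery.

## Worked example

```python
import numpy as np
from flipbind import (
    src_imatinib_profile, MetadParams, run_metad, reconstruct_with_uncertainty,
    find_critical_points, basin_free_energy, combine_cycle,
    rate_from_barrier, pptis_rate,
)

land = src_imatinib_profile()            # 7 kcal/mol desk-scale barrier
hills, _ = run_metad(land, MetadParams(), nsteps=4_000_000, nwalkers=4, seed=1)
fes = reconstruct_with_uncertainty(hills)
cp = find_critical_points(fes, min_prominence=0.3)
print([f"{m.label}@{m.s:.1f}:{m.F:.2f}" for m in cp.minima])
# ['A@3.0:0.00', 'B@6.0:0.26', 'C@15.6:3.82', 'D@27.9:4.66']

dg, err = basin_free_energy(fes, (12.0, 19.0), (0.0, 12.0))
print(f"external pose vs bound basin: {dg:.2f} +/- {err:.2f} kcal/mol")
# external pose vs bound basin: 3.88 +/- 0.01

cycle = combine_cycle([("path association", -14.0), ("DFG-flip penalty", 6.0)],
                      "flip-bind")
print(f"{cycle.route}: {cycle.total:.1f} kcal/mol")     # flip-bind: -8.0

print(f"ballistic bound: {rate_from_barrier(16.5, 1.0).k:.2f} s^-1")
# ballistic bound: 5.97 s^-1  (kappa = 1 upper bound on k_off)

rate, kap = pptis_rate(land, seed=1)     # interface shooting on the toy
print(f"kappa(saddle) = {kap.value:.2f}, k = {rate.k:.3g} s^-1")
# kappa(saddle) = 0.55, k = 8.57e+05 s^-1
```

The first block reconstructs the landscape from the deposited hills and
recovers the bound poses A/B and the metastable external pose C
(nominally 4 kcal/mol above the main minimum, ~1% basin population; the
sampled run lands at 3.8–3.9 and also shows a shallow spurious ripple D
on the unbound plateau — residual deposition noise that a longer run
flattens out). The cycle block shows that a −14 kcal/mol path-association
free energy plus a +6 kcal/mol flip penalty closes on the −8 kcal/mol
induced-fit total. The rate block contrasts the no-recrossing Eyring
bound over a 16.5 kcal/mol barrier (~6 s⁻¹) with the shot-trajectory
transmission coefficient that suppresses the toy-landscape rate below its
TST value.

The same machinery is exposed on the command line:

```sh
flipbind synth landscape --out out/        # toy profile + stationary points
flipbind metad --seed 1 --out out/         # HILLS log + reconstructed FES
flipbind thermo --fes out/fes.tsv          # minima, saddles, populations
flipbind synth spr --seed 3 --out out/ && flipbind spr-fit out/sensorgram.tsv
```

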