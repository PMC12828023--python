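# larvadose

Tools for quantifying radio-frequency electromagnetic-field (RF-EMF) effects
on *Aedes aegypti* larval development. The package implements the
computational chain of a reverberation-chamber exposure experiment at
3.6 GHz:

1. **Chamber characterization** (`larvadose.rc`) — decide from multi-position
   S11 sweeps whether a mode-stirred reverberation chamber is *well stirred*.
   The stirred component `S11_st = S11 − ⟨S11⟩` over N stirrer positions must
   have Rayleigh-distributed magnitude (modified Anderson–Darling statistic
   `A²ₘ = A²(1 + 0.6/N) ≤ 1.341` with maximum-likelihood scale), uncorrelated
   successive positions (lag-1 autocorrelation `r(1) < t₂`, with
   t₂ = 0.707/0.246/0.123 at N = 8/64/256), and a coefficient of variation
   sd/mean near the Rayleigh value √(4/π − 1) ≈ 0.523. The lowest usable
   frequency comes from the Weyl cavity mode count
   `N(f) = (8π/3)·abd·(f/c)³ − (a+b+d)(f/c) + ½ ≈ 100`.
2. **Dosimetry** (`larvadose.dosimetry`) — whole-body absorbed power
   `P_abs = Σ σ|E_int|² dV` from voxelized internal-field grids, quadratic
   rescaling with the incident field, whole-body SAR at ρ = 1000 kg/m³,
   the plane-wave conversion `S = E²/377 Ω`, exposure-averaging plane-wave
   sets (12 axis-aligned or the 52-wave extension), and spheroid / STL-mesh
   larva volumes.
3. **Development statistics** (`larvadose.devstats`) — Kaplan–Meier survival
   with emergence censoring, pairwise log-rank tests with a
   Schoenfeld-residual proportional-hazards check, the bootstrap
   slope-resampling comparison of development rate (1/duration) versus water
   temperature, a Gaussian linear mixed model for wing length (random
   intercept per replicate run, REML, Satterthwaite degrees of freedom), and
   Kruskal–Wallis tests for wing asymmetry and per-run mortality.
4. **Synthetic data** (`larvadose.synthetic`) — seeded generators for
   Rayleigh/Rician S11 ensembles and development cohorts with
   temperature-linear rates, diet effects, Bernoulli mortality and
   LMM-structured wing lengths, so the whole pipeline is testable without
   measurement files.

The `larvadose` command line orchestrates everything
(`characterize`, `dose`, `analyze`, `simulate`, `run-all`).

## Worked example

```python
import numpy as np
from larvadose.rc import CavityGeometry, characterize, theoretical_luf
from larvadose.synthetic import S11GeneratorSpec, simulate_s11
from larvadose.dosimetry import scale_pabs, whole_body_sar, power_density_to_field

# Lowest usable frequency of a 466 x 436 x 600 mm chamber
geom = CavityGeometry(0.466, 0.436, 0.600)
print(f"LUF = {theoretical_luf(geom) / 1e9:.3f} GHz")

# Characterize a synthetic well-stirred 8x8 sweep at 3.6 GHz
sweep = simulate_s11(S11GeneratorSpec(
    frequencies=np.linspace(1.0e9, 5.9e9, 197), n1=8, n2=8, seed=42))
rep = characterize(sweep, target=3.6e9)
print(f"verdict at 3.6 GHz: {rep.verdict}, CV interval "
      f"({rep.cv_interval[0]:.3f}, {rep.cv_interval[1]:.3f})")

# Dose bookkeeping: L4 larva, vertical position
pabs_he = scale_pabs(8.36e-6, e_ref=46.2, e_new=182.6)   # W
print(f"P_abs at 182.6 V/m: {pabs_he * 1e3:.2f} mW")
print(f"SAR at 1.87 uW/mm^3: {whole_body_sar(1.87e-6):.2f} W/kg")
print(f"E for 10 W/m^2: {power_density_to_field(10):.1f} V/m")
```

prints

```
LUF = 1.411 GHz
verdict at 3.6 GHz: True, CV interval (0.446, 0.612)
P_abs at 182.6 V/m: 0.13 mW
SAR at 1.87 uW/mm^3: 1.87 W/kg
E for 10 W/m^2: 61.4 V/m
```

The chamber supports ~100 modes at 1.411 GHz, so it is comfortably
overmoded at 3.6 GHz; the synthetic well-stirred sweep passes all three
uniformity statistics and its CV interval brackets the Rayleigh value 0.523;
the low-exposure L4 dose of 8.36 µW rescales quadratically to 0.13 mW at the
high-exposure field, i.e. a whole-body SAR of ~29 W/kg, and 61.4 V/m is the
plane-wave field equivalent to a 10 W/m² power density.

A full synthetic analysis run:

```bash
larvadose run-all --seed 1 --out results/
```

writes `uniformity.csv`, pairwise log-rank and slope-comparison tables,
the wing-length mixed-model table and a provenance-stamped `report.json`.

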