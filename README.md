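# spindlemech

Mechanics of the fission-yeast (*Schizosaccharomyces pombe*) anaphase B
spindle: how a bundle of ~10 cross-linked microtubules, built from a fixed
tubulin budget, resists the compressive forces of chromosome segregation.

The anaphase B spindle is a beam-like bundle of interpolar microtubules
anchored at two spindle pole bodies (SPBs).  Electron tomography shows a
stereotyped transverse organisation: antiparallel microtubules square-packed
at ~40 nm spacing in the central midzone (where cross-linkers of the Ase1/PRC1
and kinesin families bridge them), and parallel microtubules hexagonally
packed at ~30 nm near the poles.  During anaphase B the spindle elongates
~4-fold while the total polymerised tubulin L_T stays constant, so microtubule
number and cross-section shrink as the spindle lengthens.

`spindlemech` implements the quantitative machinery to analyse and model this
system:

- **Trace I/O** (`spindlemech.traces`): 3D microtubule polylines (TSV/JSON
  dialects) with pole-of-origin and minus-end annotation, and the uniform
  γ = 25/18 correction for freeze-substitution shrinkage.
- **Synthetic spindles** (`spindlemech.synthetic`): generators for maximal
  midzone overlap (MMO) architectures, Poisson/random-partition null models,
  and full 3D trace sets with square/hexagonal packing, curvature and noise.
- **Isotropic Fibre Tracking Analysis** (`spindlemech.ifta`): sphere-stepping
  axis tracing through curved bundles, computational straightening,
  cross-section extraction, nearest-neighbour distance and packing-angle
  statistics, midzone classification, Kolmogorov–Smirnov region comparison.
- **Transverse stiffness tensors** (`spindlemech.stiffness`): the 2×2 area
  moment of inertia tensor of a bundle of hollow cylinders,

      I_xx = N·I_MT + A_MT Σᵢ (yᵢ − ȳ)²,   I_xy = −A_MT Σᵢ (xᵢ − x̄)(yᵢ − ȳ),

  with A_MT = π(r₂² − r₁²), I_MT = (π/4)(r₂⁴ − r₁⁴) for r₁ = 7.5 nm,
  r₂ = 12.5 nm, optional rectangular cross-linker material, eigenanalysis
  (I_min, I_max, anisotropy I_max/I_min), idealized-array series and
  per-section spindle profiles (EI_MT = 20 pN·μm² converts MT units to
  physical stiffness).
- **Buckling simulation** (`spindlemech.buckling`): overdamped bead-spring
  filaments, SPBs confined to the spindle axis, midzone-restricted
  antiparallel cross-linkers, a force-ramp protocol (rest-length drop
  Δ = 1 μm, spring constant ramped to k_max = 240 pN/μm), critical-force
  quantification F_c, effective stiffness EI_eff = F_c (L_s/π)², and lateral
  elastic confinement α reproducing reinforced buckling with
  λ = 2π(EI/α)^{1/4} and f_c = 8π²EI/λ² = 2√(EI·α).
- **Scaling models** (`spindlemech.scaling`): N_MMO = 2L_T/(L_s + L_m),
  power-law fits F = A·L^p (free or fixed exponent), conserved-volume
  cylinder scaling EI ∝ L⁻², null-model exceedance probabilities.
- **Cell forces** (`spindlemech.forces`): the tubulin budget (sphero-cylinder
  cell volume, dimer counts, polymerized/free/total concentrations) and the
  forces resisting elongation (confined-nucleus drag, spindle-ablation
  relaxation fits, F_v = γv_s/2, F_e = x₀γ/τ).

## Worked example

```python
>>> import numpy as np, spindlemech as sm

# stiffness of the 2x2 square midzone motif (40 nm spacing)
>>> t = sm.bundle_tensor([[20, 20], [-20, 20], [20, -20], [-20, -20]])
>>> ms = sm.MicrotubuleSection()
>>> round(t.in_mt_units(ms).I_min, 1), t.in_mt_units(ms).anisotropy
(34.1, 1.0)

# removing one microtubule leaves the collinear row of three
>>> row = sm.bundle_tensor([[-40, 0], [0, 0], [40, 0]]).in_mt_units(ms)
>>> round(34.1 / row.I_min * 100)   # percent fold-change, ~1100 %
1137

# the 11-microtubule early anaphase B spindle predicted by the MMO rule
>>> sm.n_mmo(27.1, 2.5, 2.5)
10.84

# fibre tracking of a synthetic wild-type spindle
>>> from spindlemech.synthetic import wild_type_preset
>>> from spindlemech.ifta import midzone_sections
>>> arch, pack = wild_type_preset(L_s=2.5, positional_noise_sd=2.0, seed=1)
>>> rec = sm.synthesize_traces(arch, pack)
>>> axis = sm.trace_axis(rec, 200.0)
>>> secs = sm.cross_sections(rec, axis, step=100.0)
>>> pooled = np.concatenate([sm.nn_distances(s) for s in midzone_sections(secs)])
>>> round(float(np.median(pooled)))   # midzone packing distance, nm
38
```

The 2×2 motif is mechanically isotropic with minimal transverse stiffness
~34 I_MT; losing one microtubule collapses I_min to 3 I_MT (an ~1100 % fold
difference), which is why the square motifs mark peaks of bundle strength.
The MMO count 10.84 ≈ 11 matches the microtubule number observed at anaphase
B onset, and fibre tracking of the synthetic reconstruction recovers the
~40 nm square midzone lattice (the median nearest-neighbour distance sits
~2 nm below the lattice constant because the nearest-neighbour minimum is
biased low under positional noise).

A command-line pipeline mirrors the library:

```sh
spindlemech generate --l-s 2.5 --noise 2 --seed 1 --out run/
spindlemech analyze run/traces.tsv --out run/analysis/
spindlemech buckle --lengths 5,7,9,11 --replicates 3 --out run/buckling/
spindlemech forces --out run/forces.json
```

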