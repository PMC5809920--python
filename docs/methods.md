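# Methods

## The model

A perisynaptic astrocyte projection (PAP) is idealized as a cylinder of
length L = 1000 nm — the measured distance between the postsynaptic density
contact (the *alpha* face) and the intracellular Ca²⁺ stores (the *beta*
face) — and diameter D = 100 nm. Its volume, V = πD²L/4 = 7.854×10⁻²¹ m³,
is small enough that micromolar concentrations mean single-digit molecule
numbers (1 µM ≈ 4.73 molecules; one molecule ≈ 0.21 µM), which is why the
pipeline ends in integer allocation rather than concentrations.

IP3 is produced at the alpha face by phospholipase C (PLC) cleaving
membrane PIP2, and moves only by axial diffusion:

    ∂Ca/∂t = Dab ∂²Ca/∂z²,   Dab = 300 µm²/s.

In dimensionless variables φ = (Ca−C0)/(C1−C0), τ = t·Dab/L², η = z/L the
problem is ∂φ/∂τ = ∂²φ/∂η² with

* φ(0, η>0) = 0 (empty cylinder initially),
* φ(τ, 0) = 1 (constant source concentration at alpha),
* ∂φ/∂η = 0 at η = 1 (IP3 accumulates at beta; no removal).

The eigenfunction solution for these conditions is the odd sine series

    φ(τ, η) = 1 − (4/π) Σ_{n≥0} exp(−λ_n² τ) sin(λ_n η)/(2n+1),
    λ_n = (2n+1)π/2.

**Erratum note.** A published form of this solution circulates with
`((−1)ⁿ/(2n+2)) cos(λ_n η)` terms; that expansion does not satisfy its own
initial and boundary conditions (it returns φ = 1 at η = 1 for every τ).
The sine series above is the standard solution for exactly the stated
conditions, and it reproduces every downstream numeric consequence of the
analysis (profile shapes, all molecule counts). We implement the corrected
form and verify it three ways (below).

## Assumptions and their limits

* **No IP3 removal.** Valid only below the degradation horizon (~0.8 s);
  all reference snapshots are ≤ 5 ms. `total_ip3` logs a warning past the
  horizon.
* **Zero-order synthesis.** IP3 production is n_plc·κ_cat·t, abruptly
  capped at the PIP2 budget (3 clusters × 1000 molecules = 3000). No
  substrate-dependent slow-down, no PLC regulation, no PIP3.
* **1-D continuum diffusion.** Radial/angular structure and the leaf-like
  in vivo geometry are ignored; only the axial distance matters in 1-D.
  Fick's law is assumed even at single-digit copy numbers — the package
  flags (rather than hides) the regime where that assumption fails: if no
  grid position expects ≥ 1 molecule, the profile is marked degenerate.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `length_nm` | 1000 | nm | alpha→beta distance L |
| `diameter_nm` | 100 | nm | cylinder diameter D |
| `dab_um2_s` | 300 | µm²/s | IP3 diffusion coefficient (disputed alternative: 10) |
| `degradation_horizon_s` | 0.8 | s | earliest IP3 degradation; validity bound |
| `n_plc` | 1/10/100 | – | PLC copies at alpha |
| `kcat_per_s` | 1000/5000 | s⁻¹ | PLC specific activity |
| `pip2_budget` | 3000 | molecules | substrate cap |
| `grid_points` | 11 | – | allocation grid (η = 0, 0.1, …, 1) |
| `ip3r_footprint_nm2` | 380 | nm² | IP3R in-membrane area |
| `sharing_fraction` | 0.5 | – | store face fraction available to IP3R |

The canonical dimensionless times {0.005, 0.1, 0.3, 0.8, 1.5} map to
{16.7 µs, 333 µs, 1 ms, 2.667 ms, 5 ms} at the defaults. The reference
reports state only 0.1 and 1.5 explicitly for the profile figure; the full
set is inferred from the physical time list via τ = t·Dab/L².

## Numerical choices

* **Series truncation**: stop when the term bound (4/π)/(2n+1)·exp(−λ_n²τ)
  drops below 10⁻¹² (hard cap 1000 terms); φ is clamped to [0, 1] afterwards
  to absorb truncation noise only.
* **Small τ**: below τ = 0.01 the series converges slowly and the
  similarity form erfc(η/(2√τ)) is used, plus one reflection image about
  η = 1; the two routes agree within 10⁻⁶ at the switch point.
* **Allocation grid and normalization**: 11 equally spaced points with
  point-value weights N_i = n_total·φ_i/Σφ_j. This is the unique simple
  scheme that reproduces every reference count (41/2 at 333 µs, 29 at 1 ms,
  112 at 2.667 ms, 225 at 5 ms, 6/2 at 16.7 µs); trapezoid or midpoint
  quadrature weights miss several of them. Grid size is configurable.
* **Rounding**: nearest integer, ties away from zero (40.65→41, 224.52→225
  pin this down against floor and banker's rounding). Independent per-point
  rounding can drift from the rounded total by up to half a molecule per
  grid point; a largest-remainder mode is provided when exact conservation
  matters.
* **"Near alpha/beta"** are the η = 0 and η = 1 grid points themselves.
* **Finite-difference oracle**: backward-Euler (unconditionally stable)
  with 200 interior nodes and ghost-point closure of the no-flux face;
  time step min(10⁻⁴, τ_target/250) — the adaptive cap is needed because
  backward Euler is first-order in time and the early-τ solution is steep
  (a flat 10⁻⁴ step leaves 1.4×10⁻³ error at τ = 0.005, outside the 10⁻³
  three-way band). An explicit FTCS scheme (stability ratio ≤ ½ enforced)
  provides the third, independent route. The implicit update satisfies a
  per-step mass/influx balance as an algebraic identity (residual < 10⁻⁸).
* **Stochastic validator**: a lattice random walk (51 cells, step variance
  matched to unit diffusivity, reflecting far face, source cell replenished
  to fixed occupancy each step) whose replicate-averaged occupancy matches
  n_source·φ within Monte-Carlo error; at ~8-particle occupancy it
  quantifies the replicate-to-replicate scatter behind the low-copy caveat.
  Deterministic given its seed.

## One known inconsistency in the reference values

The reference summary prints a total of 1335 IP3 for 100 PLC at 5000/s in
its "2.6 ms" row. No single time is consistent with both that total and
the sibling rows: 1335 requires t = 2.670 ms, while the 10-PLC total of 133
in the same column requires t < 2.667 ms. Using the exact snapshot time
t = τL²/Dab = 2.667 ms (τ = 0.8), the pipeline reproduces 13 of the 14
(total, near-beta) pairs exactly — including the 112 near-beta count of
that very row — and yields 1333 for the inconsistent total. The frozen
golden table used by `papdiff table3 --check` carries 1333; the discrepancy
is deliberate and documented here.

## What the generated references do and do not establish

The oracles are numerical twins of the same governing equation, not
independent biological data: agreement establishes that the analytic
series, its small-τ branch, and the allocation arithmetic are implemented
correctly, and that the continuum profile is the correct mean of the
stochastic picture. It cannot validate the modelling assumptions
themselves (1-D geometry, constant source, no removal, zero-order
synthesis); those are order-of-magnitude idealizations by design.

## Design choices where the design was open

* `sharing_fraction = 0.5` reproduces the "≈10 effective IP3R" estimate
  from the ≈20-receptor geometric maximum; whether that factor is exactly
  one half or an independent estimate is not specified upstream. It is a
  modelling choice, exposed as a parameter.
* The store-face area is computed from the geometry (πD²/4 = 7854 nm² for
  D = 100 nm) rather than taken from the printed 7583 nm² (a likely digit
  transposition); both floor to 20 receptors at a 380 nm² footprint.
* 3000 molecules in the reference volume is 634 µM by exact conversion;
  the rounded "≈600 µM" figure is treated as presentation rounding and the
  package always reports the computed value.
* The sub-micromolar "no IP3 at all" reporting threshold (< 1 molecule)
  lives in the allocation/visibility layer, never in the unit conversions,
  which stay exact and invertible.

## Known limitations

No IP3 degradation or removal kinetics, no radial or angular diffusion, no
time-varying or spatially structured source, no IP3R/RyR gating or Ca²⁺
dynamics (receptor numbers enter only as capacity thresholds), and no
stochastic allocation in the main pipeline (the walker is a validator).
These follow the scope of the underlying order-of-magnitude analysis.
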