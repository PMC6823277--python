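# Methods

This note documents the models, conventions and numerical choices behind
`ionbridge`, and what the synthetic validation does and does not establish.

## Units and conventions

All lengths are nanometres internally; PDB input (Å) is converted by ×0.1 on
read and back-converted on write. Times are nanoseconds. If a file's mean
absolute coordinate is below 0.01 nm after conversion, a warning flags a
probable double conversion. Frame times are taken from a
`REMARK 250 FRAME TIMES (NS):` header when present, else default to
0, 1, 2, … ns; the default affects only labels, since every windowing
operation takes explicit times.

## Salt-bridge definition

A salt bridge is a contact between a positively charged site (Lys Cε, Arg
Cζ, or the backbone N of a chain's first residue) and a negatively charged
site (Asp Cγ, Glu Cδ, or the carboxyl carbon of the last residue) with
reference-atom distance **d < 0.6 nm, strict**. The strictness matters only
on a measure-zero boundary for continuous data but is fixed and unit-tested
(a frame at exactly 0.6 nm never counts). His, Cys and Tyr are never treated
as ionizable; protonation-state prediction is out of scope.

Choices that were genuinely open:

- **C-terminal reference atom.** The carboxyl carbon C is used (OXT only if
  C is absent), for symmetry with the side-chain carbon convention; the atom
  name is configurable in `identify_charged_sites`.
- **Screening-time → frame matching.** Nearest frame, required to lie within
  half the local frame spacing; a schedule time outside the trajectory span
  is an error rather than a clamp.

## Screening and occupancy

Candidate pairs are the full (+,−) cross product (ions excluded), ordered
deterministically by chain and residue number. A pair is *targeted* when
min over screening snapshots of d is below the cutoff — the "at least once"
rule. Occupancy is computed over **all frames** of the analysis window (no
subsampling); the window defaults to the full trajectory and is a config
knob. Distance mean ± SD uses the n−1 denominator.

Aggregation proceeds bottom-up: per-subunit pair occupancies first, then
(for symmetric oligomers) the arithmetic mean across the three subunits,
then per-positive-site sums of partner occupancies per scope, with the
combined column defined as intra sum + inter sum exactly. Per-site averages
divide by the number of positive sites listed for that scope; threshold
counts use strict ">". Cross-condition grand means report mean and sample SD
(n−1) over the per-condition averages. Windowed occupancies use contiguous
half-open 100-ns windows (the last window closed), so the frame-weighted
window average reconstructs the global occupancy identically.

The bundled PhCutA1 reference tables store only per-pair values; every sum
and average is recomputed. Because the published per-pair values are rounded
to 0.1 %, recomputed sums can differ from independently rounded aggregates
by ±0.1 in the last digit; comparisons are therefore made at 1-decimal
precision.

## Structural metrics

Superposition uses the Kabsch SVD algorithm with a determinant correction
(rotations are always proper; collinear point sets are rejected). RMSD is
per-frame versus a configurable reference frame (default frame 0 — the
choice of reference is a convention, not a result). R_g is mass-weighted
when element information is available and unweighted otherwise (Cα-only
selections use unit masses). RMSF aligns frames to the window-mean
structure with one refinement pass (align to frame 0 → mean → re-align →
mean) and reports, besides the per-atom values, the difference profile
RMSFᵢ − ⟨RMSF⟩, which sums to zero by construction.

For a rigid body with i.i.d. per-coordinate jitter σ, superposition removes
six rigid degrees of freedom, so the expected RMSF is σ√3·√(1 − 2/N) for an
N-atom selection; validation uses the all-atom selection (N = 66) where the
correction is ≈1.5 % and the σ√3 limit holds within the 5 % test tolerance.

## Electrostatic scorer

The per-residue score is a deliberately simple, self-contained Coulomb model
with a distance-independent but burial-dependent dielectric:

    E_ij = f·q_i·q_j / (ε(b)·r_ij),   f = 138.935 kJ·mol⁻¹·nm·e⁻²,
    ε(b) = ε_exposed + b·(ε_buried − ε_exposed),  ε_exposed = 80, ε_buried = 4,

with unit formal charges at the reference atoms (monopole approximation)
and b the mean burial of the two sites. Burial is a saturating heavy-atom
neighbor count: atoms outside the site's own residue within 0.9 nm of the
reference atom, divided by 30, clipped at 1. All five constants are
configuration keys (`ElectroParams`). The per-residue energy sums over all
other charged sites with no distance cutoff; summing per-residue energies
over all sites counts each unordered pair twice (documented and tested).
Only the qualitative contract is claimed: like charges score positive
(destabilizing), |E| grows with burial and with 1/r. Absolute published
per-residue energies from empirical force-field programs are not
reproduction targets.

Ensemble energies average per-snapshot values over an explicit schedule
(e.g. 100–400 ns every 20 ns = 16 snapshots). The regression of ΔT_d (°C)
on energy is ordinary least squares; R is the Pearson correlation, SD the
residual standard deviation √(SSE/(n−2)), and P the two-sided t-test on R
with n−2 degrees of freedom. At least 3 matched points and non-zero energy
variance are required.

## Synthetic generator

The generator emulates exactly the features the analysis consumes, not the
physics that produces them:

- **Topology.** Three identical chains (Met, the configured Arg/Lys and
  Asp/Glu residues, Gly cap) arranged with 3-fold symmetry; each residue has
  backbone N/CA/C and charged residues their side-chain reference atom.
- **Pair dynamics.** Each designated pair follows a two-state Markov chain
  with per-frame transition probabilities k_on·dt and k_off·dt, stationary
  bound probability p = k_on/(k_on+k_off), started from the stationary law.
  Defaults: bound distance ~ N(0.45, 0.05²) nm (a formed bridge, matching
  typical observed bridge lengths of ≈0.47 ± 0.10 nm), unbound
  ~ N(1.0, 0.1²) nm, truncated positive by rejection; relaxation rate
  k_on+k_off = 10 ns⁻¹ (nanosecond-scale side-chain contact dynamics),
  dt = 0.01 ns. The analytic occupancy is
  p·Φ((c−μ_b)/σ_b) + (1−p)·Φ((c−μ_u)/σ_u).
- **Geometry.** Distances are realized along the fixed inter-site axis; the
  two reference atoms of a designated pair are otherwise held while all
  remaining atoms get isotropic jitter σ_j = 0.02 nm. This suffices because
  every statistic in scope depends only on pair distances and rigid-body
  geometry — no forces, water or thermostats are modelled.
- **Ions.** `place_ions` puts each ion 0.3 nm from its site in exactly
  round(f·F) frames (chosen per seed) and ≥1.2 nm away otherwise, so
  recovered ion occupancies are fixed by frame arithmetic.

Everything is bit-reproducible for a given spec and seed.

**What passing tests show — and don't.** Recovery of p within three
effective-sample-size standard errors (ESS = n/(1+2Σρ_k), autocorrelation
sum truncated at the first non-positive term) validates the counting,
screening, windowing and aggregation machinery under a stationary, axially
realized two-state process. Real MD distances are non-Gaussian, states are
not perfectly two-valued, periodic-boundary images can split molecules
(no minimum-image correction is applied; inputs must be whole molecules),
and screening snapshots are correlated with analysis frames in richer ways.
The synthetic closure therefore certifies the *analysis*, not any force
field.

## Problem sizes and tolerances

Validation uses 40 000-frame trajectories (400 ns at 0.01-ns spacing) for
occupancy recovery at p ∈ {0.1, 0.5, 0.9}, 10 000 frames for RMSF limits
(5 % tolerance), 1 000 Kabsch-vs-quaternion instances at 1e-9 agreement, and
exact (machine-precision) identities for decompositions, windowed averages
and scheduled ion occupancies. These sizes give standard errors comfortably
inside the tested tolerances while keeping the whole suite in the
tens-of-seconds range.

## Known limitations

- Monopole charges at single reference atoms ignore charge delocalization
  over carboxylate/guanidinium groups.
- The burial→dielectric mapping is a proxy with the right monotonicity, not
  a calibrated solvation model.
- No periodic-boundary handling; no protonation-state prediction; no
  secondary-structure analysis.
- The frames-table dialect carries no residue identities; supplying a
  topology is the caller's responsibility when reading it back for site
  analysis.
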