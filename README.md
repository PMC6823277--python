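# ionbridge

Salt-bridge occupancy analysis for trajectory ensembles of multi-chain
proteins.

Hyperthermophilic proteins such as the trimeric CutA1 from *Pyrococcus
horikoshii* (PhCutA1) carry unusually many charged residues, and their
stability is thought to rest on networks of ion–ion interactions (salt
bridges) that fluctuate in solution. `ionbridge` turns snapshot ensembles of
such proteins — typically saved from molecular-dynamics runs as multi-model
PDB files — into the quantitative summaries used to compare those networks
across simulation conditions (e.g. different force fields):

- **Site and pair enumeration.** Ionizable sites are located at the field's
  standard side-chain reference atoms (Cε of Lys, Cζ of Arg, Cγ of Asp, Cδ of
  Glu), plus the chain termini; every favorable (+,−) combination becomes a
  candidate pair, split into intra- and inter-subunit scope.
- **Screening and occupancy.** A pair is targeted when its reference-atom
  distance d drops below 0.6 nm (strict) in at least one screening snapshot;
  its *occupancy* is the percentage of analysis frames with d < 0.6 nm.
  Aggregations: per-positive-residue sums of partner occupancies, per-residue
  averages per condition, cross-condition grand means, threshold counts
  (> 0.1, 1, 10, 40, 70, 80, 90 %), per-100-ns window robustness, and
  counter-ion (Cl⁻/Na⁺) occupancies.
- **Structural metrics.** Kabsch-superposition RMSD, radius of gyration
  R_g = √(Σmᵢ‖rᵢ−r_cm‖²/Σmᵢ), and per-atom RMSF about the window-mean
  structure.
- **Electrostatic scoring.** A burial-scaled Coulomb score
  E = f·qᵢqⱼ/(ε(b)·r) with ε interpolating from 80 (exposed) to 4 (buried),
  averaged over snapshots per charged residue and regressed (OLS) against
  experimental denaturation-temperature shifts ΔT_d of charge-removal
  mutants, reporting R, the residual SD and the two-sided P value.
- **Synthetic ground truth.** A generator builds toy trimers whose designated
  pairs follow two-state (bound/unbound) Markov distance dynamics with known
  stationary occupancy, so every pipeline stage is verifiable at desk scale
  without running MD.

## Worked example

```python
from ionbridge import synth, sites, occupancy

# trimer with one designated Lys–Glu bridge per chain, bound 75% of the time
spec = synth.default_spec(p=0.75, n_frames=20_000, seed=42)
topology, ref = synth.build_toy_trimer(spec)
traj = synth.simulate_bridge_trajectory(topology, ref, spec)

found = sites.identify_charged_sites(topology)
pairs = sites.enumerate_candidate_pairs(found)
rule = sites.ScreeningRule(times=sites.snapshot_times(0, 190, 10))
retained = sites.screen_pairs(pairs, traj, rule)
print(f"{len(found)} charged sites, {len(pairs)} candidate pairs, "
      f"{len(retained)} retained by screening")
for pair in retained[:3]:
    rec = occupancy.occupancy_percent(occupancy.distance_series(traj, pair))
    print(f"{pair.label:22s} {pair.scope}  occupancy {rec.occupancy_pct:5.1f}%  "
          f"d = {rec.mean_distance:.2f} ± {rec.sd_distance:.2f} nm")
print(f"analytic target for p=0.75: {spec.analytic_occupancy(0.75):.1f}%")
```

prints

```
18 charged sites, 81 candidate pairs, 6 retained by screening
A:LYS2--A:GLU4         intra  occupancy  74.0%  d = 0.59 ± 0.25 nm
A:ARG3--A:GLU4         intra  occupancy  92.1%  d = 0.18 ± 0.22 nm
B:LYS2--B:GLU4         intra  occupancy  76.3%  d = 0.58 ± 0.24 nm
analytic target for p=0.75: 74.9%
```

The designated Lys–Glu bridges recover the 74.9 % analytic crossing
probability to within sampling error (the occupancy standard error accounts
for the chain's autocorrelation via the effective sample size); screening
keeps only pairs that actually approach below 0.6 nm.

The same stages are available from the shell:

```sh
ionbridge simulate --p 0.75 --frames 20000 --seed 42 --out ens.pdb
ionbridge pairs --traj ens.pdb --screen-step 10 --out pairs.tsv
ionbridge occupancy --traj ens.pdb --pairs pairs.tsv --out occ.tsv
ionbridge metrics --traj ens.pdb --select CA --out metrics.tsv
```

A bundled reference dataset (`ionbridge.datasets`) provides the published
per-pair occupancy tables for PhCutA1 under six force-field/water-model
combinations; the aggregation layer recomputes all per-residue sums,
per-residue averages and grand means from those per-pair values.

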