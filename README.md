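# nataltrack

Particle backtracking plus natural tags for natal-source identification
in mixed populations.

## The problem

Many fishes (and other organisms with a passive dispersive phase)
spawn at several discrete sites whose offspring later mix. Natural
tags — microsatellite genotypes and otolith trace-element chemistry —
can discriminate breeding subpopulations and apportion a mixed cohort
among them, but every such analysis trains its discrimination
functions on young individuals *labelled by where they were caught*.
In flow-dominated systems that label is unreliable: a larva drifting
passively for days can be captured far from where it hatched, and the
mislabelled training data blur the very signal the tags carry.

`nataltrack` implements the corrective: hindcast each captured larva
through a gridded current field back to its hatch day, convert the
resulting occupancy distribution into hatch-region probabilities,
re-label the training set accordingly, and rerun the genetic and
otolith analyses on the revised labels. It is built around a
two-region (north shore / south shore) study design split at a
boundary latitude, with juvenile recruits as the mixed population.

Core pieces:

* **Transport** — clouds of n = 5,000 passive, neutrally buoyant
  particles seeded over a 5 m radius at each capture point, integrated
  backward in time with a 2nd-order (Heun) Lagrangian scheme,
  Smagorinsky horizontal diffusion (C_s = 0.005,
  K_H = C_s·Δx·Δy·|deformation|) and a vertical random walk
  (K_v = 5·10⁻⁴ m² s⁻¹). Daily occupancy grids record the fraction of
  the cloud per cell.
* **Natal assignment** — hatch-day cell probabilities summed per
  region; decision rules are the single most probable cell ("Best")
  or certainty thresholds τ ∈ {60, 70, 80, 90 %}; an optional < 8 mm
  TL cutoff restricts training to sizes that drift passively.
* **Genetics** — Monte-Carlo exact Hardy–Weinberg tests with
  Bonferroni screening and a locus-reliability filter; Weir–Cockerham
  θ (F_ST); frequency-method likelihoods (p², 2pq, unseen-allele floor
  0.01) with leave-one-out self-assignment; Paetkau-style Monte-Carlo
  exclusion (10,000 simulated genotypes, P = 0.05) and two-step
  juvenile classification with 30 % / 70 % decision bands.
* **Otolith chemistry** — LOD/CV quality control (≥ 90 % above LOD in
  each breeding area, standard CV < 10.5 %), ANCOVA size-detrending
  with an interaction screen, jackknifed LDA/QDA self-assignment and
  70 %-posterior juvenile classification.
* **Synthetic scenarios** — flow fields (uniform, solid-body gyre,
  river-plume jet), forward-simulated larvae with known hatch regions,
  Balding–Nichols genotypes at a target divergence F, and otolith
  chemistry with region-specific means and a size trend, all with
  recorded ground truth for recovery testing.

## Worked example

```python
from nataltrack.pipeline import RunConfig, run

result = run(RunConfig(seed=1, n_reference=60, n_juveniles=50,
                       n_particles=200, advect_fraction=0.3,
                       divergence_F=0.05))
truth = result["truth"]
null = result["scenarios"]["null"]
best = result["scenarios"]["best"]
print(f"true %N of larvae mixed across the line: "
      f"{truth['pct_crossed']:.0f}%")
print(f"null:    %N={null['pct_north']:.0f}  "
      f"self-assignment={null['self_assignment']['overall']:.1f}%")
print(f"revised: %N={best['pct_north']:.0f}  "
      f"self-assignment={best['self_assignment']['overall']:.1f}%")
```

prints

```
true %N of larvae mixed across the line: 30%
null:    %N=35  self-assignment=61.7%
revised: %N=65  self-assignment=86.7%
```

Thirty percent of the simulated larvae hatched north of the boundary
but drifted south before capture, so the capture-location ("null")
labels call only 35 % of the training set northern and the
leave-one-out genetic self-assignment reaches 61.7 %. Re-labelling
with the backtracked Best-estimate hatch regions restores the true
65 % northern share and lifts self-assignment to 86.7 % — the same
genotypes, better labels. The full report also carries F_ST, the
juvenile mixture breakdown (% excluded / north / south / failed), the
otolith metrics, and every threshold × size-cutoff scenario.

A CLI wraps the same calls: `nataltrack simulate`, `backtrack`,
`assign`, `genetics`, `otolith`, `report` (see `nataltrack --help`).

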