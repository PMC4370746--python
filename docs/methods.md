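# Methods

This note documents the models, numerical choices and limitations of
`nataltrack` in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Flow fields

A `FlowField` holds u, v (and optionally w, temperature) on a uniform
rectilinear (t, z, y, x) grid with a boolean land mask. The default
geometry mirrors the class of operational lake circulation products
the transport scheme is meant to consume: 2,000 m cells, 21 depth
levels, hourly snapshots. Coordinates are metres in a local
equirectangular frame about a stored lon/lat origin (1° latitude =
111,320 m); this keeps diffusion and displacement arithmetic
unambiguous, and conversion helpers map back to degrees. Depth is
plain z rather than a terrain-following coordinate — the transport
scheme only needs gridded velocities, and a sigma transform would add
complexity without exercising any method component.

Interpolation is trilinear in space and linear in time, and
*mask-aware*: corner weights on land cells are zeroed and the
remainder renormalised, so land never contributes velocity. The
interpolant is exact for fields constant or linear in each axis
(tested), which also makes the solid-body gyre — globally linear in
x and y — an exact test bed for the integrator.

Three analytic generators stand in for hydrodynamic-model output: a
uniform field, a divergence-free solid-body gyre, and a "plume" — a
Gaussian southward jet v(x) with optional sinusoidal wind modulation —
emulating a river inflow crossing the region boundary. Requested
speeds above 2 m s⁻¹ are rejected as unphysical for the target
setting.

## Particle transport

Each capture record seeds n particles uniformly on a disc (default
5,000 particles, 5 m radius) at the capture point. One step of the
scheme, at time step Δt = 600 s by default:

1. **Advection (Heun / 2nd order):** predictor with u(X, t), corrector
   with u(X*, t ± Δt), displacement = the average. Backward runs
   negate the advective displacement; the random-walk part is
   time-symmetric and applied identically in either direction, which
   is the standard hindcast treatment.
2. **Horizontal diffusion:** random displacement √(2·K_H·Δt)·N(0,1)
   per axis with the Smagorinsky closure
   K_H = C_s·Δx·Δy·√((∂u/∂x)² + (∂v/∂y)² + ½(∂u/∂y + ∂v/∂x)²),
   C_s = 0.005, gradients taken as centred differences at the
   particle's cell. A constant-K_H override exists because the
   Smagorinsky diffusivity vanishes identically in still water; the
   override is what diffusion-only calibration runs (heat-kernel
   occupancy, 4·K_H·t displacement scaling) use.
3. **Vertical random walk:** √(2·K_v·Δt)·N(0,1) with
   K_v = 5·10⁻⁴ m² s⁻¹.

Boundary handling: specular reflection at the rectangular domain
edges, surface and bottom. Steps that would end on an interior land
cell are rejected (the particle keeps its pre-step position for that
step). True specular reflection off a rasterised, cell-aligned
coastline is ill-defined; rejection conserves probability mass
exactly, which matters because the natal assignment sums that mass.
A `freeze` policy is available instead, in which particles leaving
the domain deactivate and appear as explicit out-of-domain mass.

Δt = 600 s is stable and accurate for 2 km cells at ≤ 2 m s⁻¹
(a particle crosses no more than a third of a cell per step); it must
divide 86,400 s so that daily occupancy snapshots fall exactly on
capture-time-of-day anchors. Hatch day = capture date minus the
otolith ring count in whole days; the hatch-day grid is the final
day's occupancy. Determinism: a single seeded generator drives every
stochastic term, and identical (seed, config, inputs) reproduce
occupancy grids bit-for-bit.

## Natal assignment

Hatch-day cell probabilities are summed by region: a cell is northern
iff its centre latitude exceeds the boundary (41.81° N by default);
points exactly on the line count as southern — a deterministic,
documented tie rule. Out-of-domain mass (freeze policy only) is
reported separately and belongs to neither region, so
p_N + p_S + p_out = 1 to 1e-12.

Decision rules: "Best" takes the region of the single most probable
hatch cell (ties across regions fall back to the larger summed region
probability, and a full tie is unassigned); threshold mode assigns
region r iff p_r ≥ τ, else unassigned. Certainty is evaluated on the
hatch-day grid only, not integrated along the trajectory. Revised
training sets retain records assigned at the chosen rule and,
optionally, shorter than 8 mm TL — the size below which larvae are
treated as purely passive drifters. Retained counts are necessarily
non-increasing in τ.

## Genetics

*Allele frequencies* are relative counts over non-missing gene copies.
Likelihoods use the frequency method: p² for homozygotes, 2pq for
heterozygotes, multiplied across loci; alleles unseen in a reference
are floored at f₀ = 0.01 so no likelihood is exactly zero (the
convention of the widely used assignment software this mirrors;
configurable). Missing loci are skipped for the individual; an
individual is retained while it has ≥ 1 scored locus. A
Dirichlet-posterior ("bayesian") scoring mode is provided as an
alternative; all defaults use the frequency method.

*HWE testing* is a Monte-Carlo exact test: the 2N observed gene copies
are shuffled into N genotypes and the p-value is the add-one-corrected
fraction of shuffled tables whose conditional probability given the
allele counts is ≤ the observed table's (full enumeration is
infeasible for multi-allelic loci; the biallelic case is verified
against exact enumeration in the tests). Significance uses
α = 0.05 divided by the number of loci per population-year batch.
The locus filter removes a locus that violates HWE in both
populations within one year or in the same population across both
years — exactly the reliability rule of the two-region, two-year
design.

*F_ST* is the Weir–Cockerham (1984) θ: per-allele variance components
a (among populations), b (among individuals within populations) and
c (within individuals), with the multilocus estimate the ratio of the
summed a-components over the summed totals. Monomorphic loci
contribute zero components; θ is invariant under allele relabelling
and population order.

*Self-assignment* is leave-one-out: each reference individual is
withheld, its own population's frequencies recomputed without it
(by allele-count subtraction, verified call-for-call against naive
full recomputation), and the individual assigned to the arg-max
log-likelihood.

*Juvenile classification* is two-step. Step 1 computes a Monte-Carlo
exclusion p-value against each reference: the fraction of 10,000
genotypes simulated from the reference frequencies whose likelihood is
≤ the query's. A juvenile with both p-values below 0.30 plausibly
came from neither focal subpopulation and is excluded. The "percent
of belonging" screen is implemented on this resampling p-value — the
natural membership quantity the two-step design produces; a
normalised posterior would be the alternative reading. Step 2 scores
the remainder with s = L_N/(L_N + L_S): s ≥ 0.70 assigns north,
s ≤ 0.30 south, anything between is a failed assignment.

## Otolith chemistry

Elements enter the discriminant analysis only if ≥ 90 % of samples in
*each* breeding area are above the detection limit and the glass
standard CV is < 10.5 %. An ANCOVA (concentration ~ group + radius +
group:radius) screens each element: a significant interaction
(α = 0.05) means the size trend differs by region and the element is
unusable; otherwise the additive model's common slope detrends the
data, adjusted = observed − β·(radius − mean radius). Centring at the
training-set mean radius preserves group means there; the detrended
refit slope is ~ 0 by construction. Discrimination is LDA (QDA
available for the unequal-covariance check) with equal class priors —
capture effort should not masquerade as prior information in a
mixed-stock setting — jackknifed (leave-one-out) for self-assignment,
and juveniles are assigned where the posterior reaches 0.70, else
failed.

## Synthetic data generator

The generator encodes the natural-tag premise: genotypes and otolith
chemistry are always drawn from an individual's *true* hatch region,
never its capture region. That single design choice is what makes
mislabelled (null) training degrade discrimination and
backtrack-revised training recover it.

* **Larvae.** Hatch sites are placed in three strata: a configurable
  fraction inside the plume jet just north of the boundary (these
  cross before capture), the rest in still water well north or south
  of it. Each larva is integrated *forward* with the full stochastic
  scheme from its hatch time to the common capture time, so realised
  crossings — not intent — are recorded as truth. Ages are uniform on
  a configurable range; total length is the monotone map
  TL = 5 mm + 0.6·age + N(0, 0.5), reflecting hatch at ~5 mm and
  ~30 d to ~20–25 mm, so the 8 mm cutoff lands mid-cohort. Default
  study conditions for the end-to-end scenario: 30 % cross-boundary
  advection, jet speed 0.05 m s⁻¹ on a 40 × 80 km domain tall enough
  that the oldest jet-carried larvae stay clear of the southern wall.
* **Genotypes.** Balding–Nichols: per locus, ancestral frequencies
  ~ Dirichlet(1) over 8 alleles; each region's frequencies
  ~ Dirichlet(p_anc·(1−F)/F); genotypes drawn in HWE within the true
  region. F = 0.05 and 7 loci reproduce the weak-divergence regime of
  a two-subpopulation reference; W–C θ recovers F without calibration.
* **Otolith chemistry.** Concentrations ~ N(region mean, region SD)
  plus a common slope times centred radius, truncated at zero; radius
  grows ~5 µm/day from 20 µm. Default means/SDs are the strongly
  separated Sr (SS 847 ± 216 vs NS 443 ± 55 µg g⁻¹) and moderately
  separated Ba (SS 30 ± 24 vs NS 99 ± 37 µg g⁻¹) regime of a
  two-source system, with slopes −0.00134 (Sr) and −0.340 (Ba) per µm.

What the generator does *not* emulate: larval behaviour (swimming,
vertical migration), mortality, temperature-dependent growth,
genotyping error and null alleles, multi-element LA-ICP-MS noise
structure, more than two source regions, and real coastline geometry.
Passing tests therefore show the *method chain* is correct and that
label revision helps when pre-capture drift mislabels training data;
they do not validate any particular field system's circulation or tag
chemistry.

## Pipeline and problem sizes

`pipeline.run` executes null + {Best, 60, 70, 80, 90 %} × {all sizes,
< 8 mm} scenarios, always computing the null baseline without
consulting the flow field. One global seed fans out to per-stage
seeds through `numpy.random.SeedSequence`, making whole runs
reproducible byte-for-byte. Reports are emitted as JSON and TSV.

Default problem sizes in the test and acceptance configurations —
50–80 reference larvae, 40–60 juveniles, 150–300 particles per cloud,
Δt = 1,800 s, 400–1,000 exclusion simulations — were chosen as the
smallest cohorts at which the directional contrasts (revised vs null)
are decisively resolved across seeds; all constants revert to the
full-scale defaults (5,000 particles, Δt = 600 s, 10,000 simulations)
outside the synthetic study.

## Known limitations

* Backward advection is the negated forward displacement; for strongly
  sheared, time-varying fields backward and forward stochastic
  formulations differ by a drift term proportional to ∇K_H, which is
  neglected (K_H is small and smooth here).
* Coast handling by step rejection slightly over-concentrates mass at
  concave coastlines relative to true reflection.
* The exclusion screen interprets "30 % membership" as the Monte-Carlo
  exclusion p-value (documented above); with weak divergence this
  excludes a noticeable share of genuine members (p < 0.3 happens
  ~30 % of the time for true members by construction).
* Only two regions are supported end-to-end; a multi-region partition
  is an extension point, not implemented.
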