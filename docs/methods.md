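# Methods

## The model

`adhesim` simulates the adhesion of two apposing membrane segments — a T-cell
membrane carrying TCR and LFA-1 proteins, and an apposing (antigen-presenting
or supported) membrane carrying peptide-MHC (self and foreign) and ICAM-1 —
as a lattice Monte Carlo model with three ingredients:

1. **A fluctuating separation field.** The membranes are discretized into
   `nx x ny` apposing pairs of square patches of linear size `a = 15 nm`,
   periodic in both directions. Each patch pair `i` carries one continuous
   separation `l_i >= 0` (nm). Curvature of the separation field costs the
   discretized bending energy

       E_bend = (kappa / 2 a^2) * sum_i (Delta_d l_i)^2,
       Delta_d l_i = l_i1 + l_i2 + l_i3 + l_i4 - 4 l_i,

   with the effective rigidity `kappa = kappa1*kappa2/(kappa1+kappa2)` of the
   two membranes (default 20 kBT, representative of lipid and plasma
   membranes with rigidities 10–40 kBT). There is no lateral tension term and
   no spontaneous curvature.

2. **Diffusing, singly-occupying proteins.** Each patch holds at most one
   protein per membrane. Proteins hop between nearest-neighbour patches
   (excluded volume only; no lateral protein–protein interactions).

3. **Square-well binding.** An apposed TCR/pMHC pair is bound iff
   `l` lies in the closed window 15 ± 0.5 nm, contributing `-U` (with
   `U = Us` for self- and `U = Uf` for foreign-pMHC); an apposed
   LFA-1/ICAM-1 pair is bound iff `l` lies in 40 ± 0.5 nm, contributing
   −9.5 kBT. The windows are disjoint by construction, and the 25 nm
   rest-length mismatch `Δl` is what drives curvature-mediated segregation of
   the two complex types.

All energies are dimensionless in kBT (temperature never appears
separately); all lengths are in nm; time is measured in t0, the duration of
one MC step.

## Dynamics

Three Metropolis move types, with acceptance `min(1, exp(-ΔE))`:

1. **Separation shift.** A patch pair is chosen uniformly at random and
   `l -> l + δl` with `δl ~ U(-0.5, 0.5)` nm is proposed. `ΔE` combines the
   local bending change (a closed-form 13-patch stencil, exact to 1e-9 kBT
   against full recomputation) and any bond formed or broken at that patch.
   Proposals with `l + δl < 0` are rejected (hard impenetrability; inert in
   practice, since separations stay in ~10–45 nm at the default parameters).
2. **Protein hop.** A protein is chosen uniformly, a direction uniformly
   among the 4 neighbours; the move is rejected if the target patch is
   occupied. A *bound* protein whose hop would immediately form a *new*
   complex at the target is excluded — counted as a rejected attempt, not
   re-drawn — so measured complex lifetimes are not contaminated by
   instantaneous partner swaps. An unbound protein hopping into binding
   position is an ordinary downhill move.
3. **Pair hop.** An apposing cognate pair (bound or not) is chosen uniformly
   and moved to a neighbouring pair of patches if both targets are free.
   A bond whose source and target separations are both inside the window
   diffuses intact (its formation time travels with it); otherwise the move
   pays or gains the binding energy.

One MC step (t0) = `nx*ny` type-1 attempts, then `N` type-2 attempts
(N = total proteins), then `M` type-3 attempts, where the attempt count `M`
is frozen at the start of the substep at the instantaneous number of
apposing partner pairs; each attempt selects uniformly from the live pair
registry (the substep ends early if it empties). Substep order is fixed
(1, 2, 3) and selections are with replacement; per-object attempt rates are
one per step for every patch, protein and pair.

Equilibrium properties are invariant under these scheduling conventions
(detailed balance holds within each substep); kinetic prefactors in t0 units
are not, which matters for one reported constant (see *Dwell-time law*).

## Observables

A conformation row is sampled every `sampling_interval` steps (bond counts
per complex kind, the number of patch pairs below the 20 nm close-contact
threshold, the number inside the TCR/pMHC binding window, minimum
separation, energy breakdown). Equilibrium averages exclude the first
`equilibration_steps` (defaults: 2e8-step trajectories, 4e7 discarded,
sampled every 2e5 t0; six runs per parameter set from three mixed and three
high initial separation intervals, with quantities reported as mean ± error
of the mean over runs).

**Close-contact events.** A contact event is a maximal contiguous run of
sampled conformations each containing at least one patch pair below 20 nm;
it qualifies as a close-contact zone if at least one conformation in the run
holds at least one TCR/pMHC complex (this absorbs transient drops of a small
zone's instantaneous complex number to zero). Zone probability is the
fraction of equilibrated samples inside qualifying events; zone lifetime is
the unweighted mean duration of qualifying events (a single event spanning
the whole measurement window reports the window length To); zone area is the
mean over in-event samples of (sub-threshold patch count) * a^2, with no
connected-component labelling (at the study conditions one zone dominates).
Boundary-censored events are flagged and included in lifetime means by
default, consistent with reporting To for a never-interrupted zone.

**Dwell times.** Bond formation and rupture are recorded on the fly with
step-resolution timestamps inside a configurable measurement window (default:
the second half of the trajectory). A dwell time is counted when a bond both
forms and ruptures inside the window; bonds alive at the window end are
censored and reported separately, and bonds that predate the window are
left-censored and dropped.

**Analytic companions.** The critical LFA-1/ICAM-1 concentration for
curvature-mediated segregation is `c * kBT / (kappa * Δl^2)` with prefactor
`c = 0.65 ± 0.15` (52/μm² at the defaults, i.e. about 50/μm²). The
two-dimensional binding constant is `K2D = ∫ k2D(l) P(l) dl` with
`k2D(l) = a^2 exp(U)` inside the TCR/pMHC window and 0 outside, so it
reduces to (window probability mass) × a² e^U; `P(l)` is accumulated over
in-event conformations.

## Desk-scale protocols (`adhesim.experiments`)

Full-size trajectories (six × 2e8 steps on 100×100) are not desk-scale; the
package therefore ships scaled protocols whose sizes were chosen once from
measured relaxation times, and reports the scale factors alongside results.
Scaled presets shrink the lattice linearly and rescale species counts by the
area ratio, preserving all areal densities (120/μm² per species) and all
energies.

* **Single-pair dwell law** (`measure_dwell_times`, `lifetime_law`): one
  TCR/pMHC pair on a 20×20 lattice. Each episode starts with the pair
  apposed on a membrane held flat at a separation drawn uniformly from the
  binding window, runs the full move schedule until the pair separates
  laterally, and records only bonds formed *during* the episode (the initial
  bond starts from the stationary in-window distribution rather than a fresh
  binding event and is discarded). A single free trajectory is impractical
  because after lateral separation the unconstrained membrane height
  diffuses away from the binding window and rebinding stalls — the episode
  protocol samples natural formation-to-rupture lifetimes at fixed cost.
* **In-zone dwell law** (`zone_dwell_law`): dwell times counted on the fly
  inside segregated close-contact zones of scaled (30×30) scenarios — the
  environment in which complexes actually live in the full model, with the
  zone coexisting with LFA-1/ICAM-1 domains. Self complexes are probed at
  U = 5–7 kBT with a single long-lived foreign complex (Uf = 14 kBT)
  anchoring the zone; foreign complexes are probed at U = 8–9 kBT with
  three foreign pMHCs and Us = 6 kBT. Separations start from the mixed
  interval (14.5, 40.5) nm with one foreign complex pre-bound at the
  membrane centre, so the zone nucleates deterministically at every U; the
  pre-bound anchor predates the measurement window and is left-censored out
  of the dwell statistics.
* **LFA-1/ICAM-1 equilibrium** (`equilibrium_lfa_concentration`): scaled
  preset near 40 nm with TCR binding too weak (4 kBT) to form zones.
* **Zone-stabilization scan** (`contact_zone_scan`): at reduced scale both
  branches of the stabilization transition are hysteretic on affordable run
  lengths — zones do not nucleate from separated membranes below ~8 kBT, and
  sub-threshold zones take 1–3 million steps (25×25) to dissolve from
  in-contact starts. The scan therefore probes *zone survival* from
  in-contact initial conformations, with a per-energy schedule: the low edge
  (U = 5) gets 3.2e6 steps with a 2.2e6-step equilibration (longer than the
  observed dissolution times) averaged over two runs; stable energies get
  1.2e6/0.6e6 single runs. At 25×25 the survival threshold lies between 5
  and 6 kBT, a shift of less than 1 kBT from the full-scale value of about
  6 kBT.
* **Window fraction** (`window_fraction_run`): the fraction of zone patches
  (l < 20 nm) inside the TCR/pMHC binding window, averaged over in-event
  conformations of a scaled run at U = 8 kBT (≈ 20%; the fraction is
  zone-relative, since membrane regions in the LFA-1/ICAM-1 state never
  contribute binding-window patches).

## Dwell-time law and the t0-prefactor

Measured mean dwell times follow `tau = exp(c + U) * t0` with unit slope in
U to within statistics, a per-kBT fold increase of e ≈ 2.7. The constant c
is a kinetic prefactor in t0 units and is *not* scheduling-invariant: this
implementation measures c ≈ −1.05 for an isolated pair on a free membrane,
and c rising from ≈ −1.02 (U = 5) to ≈ −0.95 (U = 9) inside segregated
close-contact zones (pooled ≈ −0.99), because zone confinement slows the
escape of the local separation from the binding window and the effect grows
with zone size. Both the selection conventions (random-with-replacement,
fixed substep order) and the bond's membrane environment move c at the
0.05–0.1 level, while leaving the slope — and every equilibrium
observable — untouched.

## Numerical choices

* Binding windows are closed intervals (the open/closed distinction is
  measure-zero for the continuous separation field).
* Incremental ΔE bookkeeping is exact: the local bending stencil and the
  bond ledger reproduce brute-force total-energy differences to ≤ 1e-9 kBT
  (property-tested for all three move types); the recomputed-from-scratch
  bond view remains the source of truth against the incremental cache.
* `ΔE = 0` moves are accepted.
* Dwell timestamps have one-step granularity; a bond formed and broken
  within one step records a zero-length dwell (suppressed by exp(-U), hence
  negligible at the energies studied).
* One seeded RNG per trajectory; the six-run protocol and all experiment
  drivers derive child seeds deterministically via seed sequences. Identical
  seed, parameters and initial state give bit-identical outputs.
* Degenerate lattices (a dimension below 3) are permitted for fixtures only;
  the periodic Laplacian then double-counts wrapped neighbours.

## What the scaled runs do and do not show

The scaled protocols preserve densities, energies and per-object attempt
rates, so local kinetics (dwell times, acceptance rates) and areal
equilibria (bond concentrations, window fractions) transfer directly to
full scale. Collective properties do not transfer exactly: the
stabilization threshold carries a finite-size shift, zone areas and complex
numbers are bounded by the smaller lattice, and transition-region
hysteresis is stronger because nucleation and dissolution both slow down
per unit area. The model itself idealizes T-cell adhesion: no cytoskeletal
forces or microvilli, no CD45/glycocalyx repulsion, no co-receptors, no
lateral tension, single-occupancy point-like proteins, and square-well
bonds without distance-dependent softening. Agreement of the scaled tests
with the model's full-scale behaviour therefore validates the
implementation and the model's internal physics, not the biology it
abstracts.

## Known limitations

* Near the stabilization threshold, single scaled runs are metastable;
  only multi-run averages with relaxation-calibrated schedules are
  meaningful (the scan protocol does this; ad-hoc short runs will show
  hysteresis).
* The regression constant c of the dwell-time law is convention-dependent
  at the ±0.1 level (see above); cross-implementation comparisons should
  fix the scheduling conventions or compare slopes and ratios instead.
* Snapshot resume restarts dwell bookkeeping: bonds alive at a snapshot
  are treated as formed at the resume step.
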