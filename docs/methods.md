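# Methods

This note documents the models, conventions, and numerical choices behind
`pufasite`, and what the synthetic ground truth does and does not establish
about real data.

## Contact model and residence statistics

A contact exists between a lipid molecule and a residue in a frame when any
atom of the lipid (whole-lipid mode) or any of its head-group atoms
(head-group mode) lies within the contact cutoff (default 6 Å, the
coarse-grained convention that captures the first Lennard-Jones minimum) of
any residue atom, under the orthorhombic minimum-image convention. Two
per-residue statistics summarize engagement:

- **Total interaction time** — `dt ×` the number of frames with ≥1 lipid in
  contact. The union over lipids is used so that simultaneous contacts are
  not double-counted and a residue's total can never exceed the trajectory
  duration; a sum variant (counting multiplicity) is available behind a
  flag since the narrative definition admits both readings.
- **Longest lifetime** — `dt ×` the longest run of consecutive frames in
  contact with any *one* lipid. A single absent frame breaks a run (gap
  tolerance 0 by default; a tolerance parameter exists for sensitivity
  analysis). An episode of k frames contributes `k·dt`; no half-frame end
  corrections.

Statistics are averaged position-wise across the symmetric subunits (all
subunits must have equal residue counts; results are reported against the
first subunit's numbering). Residues whose statistic is strictly above
`Q3 + 1.5·IQR` over all residues are classified high-contact /
stable-contact. Quantiles use linear interpolation between order statistics
(the numpy default); the convention is recorded because it affects fence
values on small residue sets. Ties exactly at the fence are excluded
("above" is strict).

Per-lipid aggregation of the same tensor gives each lipid a total
interaction time and longest lifetime with the whole protein. **UQ binders**
are lipids at or above the upper quartile of total time (inclusive, since a
value "in the upper quartile" includes the boundary); **constant binders**
are lipids in contact in literally every frame (a max-missing-frames
tolerance exists, default 0). For a chosen bound lipid, a residue is a
**binder** when its minimum heavy-atom distance to the lipid is ≤ the
hydrophobic cutoff (4.0 Å) in at least a fraction θ of frames (default
θ = 0.5, always reported — the distinction is qualitative in the source
analyses and θ is this package's explicit operationalization), **proximal**
when persistently within the 6-Å shell without meeting the binder
criterion, else unclassified.

## Spatial enrichment

Occupancy is binary per frame per voxel — the fraction of frames in which
at least one selected atom visits the voxel — so 0.03 reads "present in 3%
of frames"; an atom-count-weighted mode gives densities instead. Grids are
axis-aligned with origin at the box corner and half-open voxel intervals.
Threshold contours are `occupancy ≥ t` masks and nest monotonically.

Slab profiles count (frame, head-group atom) contact events within a shell
cutoff (default 3 Å) of a reference residue set, binned by the head-group
atom's z in 0.5-Å layers, optionally per consecutive time interval; the
binned total equals the unbinned event count by construction. Fold
enrichment divides two identically binned profiles and flags
numerator-only and empty bins instead of emitting infinities.

The radial distribution function is lateral by default: distance of
head-group atoms from the protein's center-of-geometry axis, normalized by
the uniform-density expectation over annular areas within the box, so
g(r) → 1 for a laterally uniform distribution. Whether such a profile
should be referenced to the channel axis or to the protein surface is
genuinely ambiguous in common usage, so a 3-D minimum-distance-to-surface
variant is provided behind a flag; its normalization is qualitative (shell
width only) and the axis mode carries the quantitative calibration. Both
modes label their output.

## Pose clustering

Jarvis–Patrick: neighbor lists contain every pose within the distance
cutoff (a fixed-size nearest-neighbor variant is available); two poses link
when each lists the other and they share at least the required number of
common neighbors (default 3); clusters are connected components of the
link graph, and unlinked poses form an explicitly reported singleton bin.
GROMOS: the pose with the most within-cutoff neighbors becomes a centroid
(ties to the lowest index), it and its neighbors are removed permanently,
and the procedure repeats — eliminated poses never re-enter later clusters.
Representatives minimize the mean distance to other cluster members (ties
to the lowest index). RMSD is computed on raw coordinates by default
(appropriate when the protein is positionally restrained, as in the
restrained coarse-grained runs these analyses come from); optimal rigid
superposition (Kabsch) is available for unrestrained input.

## Chemical interaction criteria

The hydrogen-bond criterion is deliberately the literal geometric one: a
hydrogen covalently bound to N/O/S (identified from the bond list, or a
≤1.2 Å heavy-atom heuristic when bonds are absent) within 3.5 Å of an N/O/S
acceptor, with no angle term. A conventional distance-plus-angle mode
exists but is off by default — fidelity to the stated criterion over
convention. Salt bridges are N–O pairs ≤ 4 Å; hydrophobic contacts are C–C
pairs ≤ 4.0 Å. Coarse-grained systems have no hydrogens, so hydrogen-bond
detection raises a clear error directing users to bead-level contact
analysis. Bond lifetime statistics share the run-length implementation
(and its oracle suite) with the contact statistics.

## Electrophysiology fits

The Boltzmann form is implemented exactly as
`G(V) = Gmin + (Gmax−Gmin)/(1+exp[(V50−V)·s])` with the slope factor s in
mV⁻¹ multiplying the voltage difference (s > 0 gives an activating curve);
the common alternative `(V50−V)/s` is deliberately not used. The Hill form
is the standard `ΔEffect_max/(1+(L50/[L])^|H|)`; the Hill coefficient's
magnitude is constrained (|H| = 1 by default — the robustness constraint
used when limited fatty-acid solubility caps the accessible concentration
range at ~70 µM) and its direction sign is recorded as metadata rather
than fitted, because the magnitude of both saturating effects grows with
concentration regardless of sign convention. Relaxations are fitted with
`A·exp(−t/τ)+C` over a window after a configurable capacitive blank
(tail-current G(V) extraction likewise averages a configurable 5–20 ms
window after the blank, since "shortly after the step" is not a number).

Fits minimize unweighted least squares via trust-region reflective
optimization with analytic-free Jacobians; standard errors come from the
least-squares covariance. Initial guesses are data-driven (V50 from the
half-range crossing, s from the 25–75% rise span `2·ln3/(V75−V25)`, L50
from the concentration nearest half-max effect, τ from a third of the fit
window) so convergence needs no user tuning; noiseless recovery from
initial guesses perturbed ×0.5–×2 is part of the test suite. Degenerate
flat data and all-zero effects raise fit errors instead of returning
garbage.

## The synthetic system

The generator produces the statistical structure the analyses assume, with
no physics: a static, four-fold symmetric ring of one-bead pseudo-residues
(6 Å spacing) centered in an orthorhombic box (180 × 180 × 100 Å), and
two-bead lipids (head + tail) performing lateral Gaussian random walks
(σ = 4 Å/frame) at a leaflet-fixed z, half of each species per leaflet.
Frames are 0.5 ns apart (the typical trajectory-save interval). Two
binding sites, each with one anchor residue per subunit, bind free
outer-leaflet lipids within a 12-Å capture radius with probability p_on
per frame (LIN 0.03, STE 0.01 — a planted 3-fold affinity ratio) and
release with k_off = 0.005/frame; bound heads are pinned 2.5 Å above their
anchor, making the planted binder residues unambiguous. One LIN lipid is
pinned permanently to site I, planting a constant binder. Dwell times are
geometric (discrete-time), mean exactly 1/k_off — the closed-form oracle
for the kinetics checks, which themselves run at k_off = 0.05 to
accumulate hundreds of completed episodes.

Three quantitative design points matter:

1. **Separation of time scales.** Mean planted dwell (200 frames) is two
   orders of magnitude above a diffusive passage through a 6-Å contact
   shell (~2–4 frames at σ = 4), so planted sites are outliers in both
   statistics by construction, not by luck.
2. **Linear-regime affinities.** Per-frame binding probabilities are small
   enough that binding per zone passage stays roughly linear in p_on;
   otherwise every passage would bind for both species and the occupancy
   ratio would collapse toward 1 regardless of the planted affinity ratio.
   The realized LIN/STE enrichment at the sites is ~2.2–3.7 across seeds.
3. **Heterogeneous background.** Residues carry a fixed per-position depth
   profile below the head-group plane: crevice walls (5 Å deep) flank each
   anchor, and remote positions alternate shallow (~0.5 Å) and deep
   (~4–5 Å). Real protein surfaces are rugged and lipid-binding sites sit
   in crevices; a perfectly uniform surface is also a degenerate input for
   quartile-fence outlier calling, because every background residue then
   shares one narrow, extreme-value-tailed contact distribution and the
   fence sits inside its tail. The bimodal background keeps the fence far
   above the background while leaving planted anchors orders of magnitude
   higher still. Lipid tails hang 10 Å below the head plane, outside
   contact range, so the head group carries the binding signal — mirroring
   head-group-led electrostatic binding.

What the generator does **not** emulate: forces and energetics, membrane
elasticity or curvature, lipid exchange between leaflets, protein
dynamics, crowding (sites are non-exclusive by default; an exclusivity
flag exists), or realistic lipid chemistry. Passing tests therefore
establish that the *analysis machinery* is correct — contact bookkeeping,
run-length statistics, outlier calling, clustering, detection criteria,
fits — and that it recovers planted truth under controlled kinetics; they
do not validate force fields, sampling adequacy, or biological
conclusions on real trajectories.

## Problem sizes and numerics

Full-scale recovery runs use the 4×20-residue tetramer with 24 lipids and
20,000 frames; 20 seeded realizations complete in about two minutes via a
float32, comparison-based minimum-image contact kernel (coordinates are
wrapped first so each component needs one comparison instead of a
division-and-round). Distances are otherwise float64. Contact boundaries
are inclusive (d ≤ cutoff). The dwell-distribution check uses a
Kolmogorov–Smirnov test on the randomized probability integral transform,
which is exact for discrete distributions (the plain KS statistic is
anti-conservative under ties). RDF uniformity checks use equal-area
annuli so each bin's sampling error is well inside the tolerance band.
Deterministic tie-breaking (lowest index) is used throughout clustering;
all random processes take explicit integer seeds, and the pipeline's JSON
report contains no wall-clock values, so reruns are byte-identical.

## Known limitations

- Orthorhombic boxes only; triclinic input is rejected.
- Leaflet assignment is a midplane split on head-group z; it will
  misassign lipids mid-flip (none exist in the synthetic system).
- The surface-referenced RDF mode is qualitative (see above).
- GRO files carry no chain identifiers, so subunit identity survives a
  PDB round trip but not a GRO round trip.
- The hydrogen-bond criterion without an angle term over-counts bent
  geometries relative to conventional definitions; that is a property of
  the stated criterion, reproduced intentionally.
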