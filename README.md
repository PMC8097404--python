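# pufasite

Mapping fatty-acid binding sites on membrane proteins from molecular-dynamics
trajectories — with the matching electrophysiology curve fits.

Polyunsaturated fatty acids (PUFAs) such as linoleic acid (LIN) modulate
voltage-gated channels like KCNQ1: their charged carboxyl head group engages
basic residues on the voltage sensor and pore while the flexible tail packs
into hydrophobic crevices, shifting the voltage dependence of opening
(ΔV50 < 0) and raising the maximal conductance (ΔGmax > 0). Saturated fatty
acids (stearic acid, STE) with rigid tails do neither. `pufasite` implements
the trajectory-analysis toolchain used to localize such lipid interaction
sites and the curve fits used to quantify their functional consequences:

- **Contact statistics.** For every residue and lipid species, the *total
  interaction time* (time with ≥1 lipid within the 6 Å contact cutoff, union
  over lipids) and the *longest lifetime* (longest uninterrupted contact run
  with any one lipid). Statistics are averaged across the symmetric channel
  subunits, and residues falling above the Tukey fence `Q3 + 1.5·IQR` are
  called **high-contact** (total time) and **stable-contact** (longest
  lifetime) residues.
- **Binder analysis.** Per-lipid interaction statistics; **UQ binders**
  (total interaction time ≥ upper quartile), **constant binders** (in contact
  every frame), and the discrimination of **binder** residues (persistent
  direct contact ≤ 4.0 Å) from merely **proximal** residues (within 6 Å).
- **Spatial enrichment.** Binary-per-frame voxel occupancy grids (1 Å,
  OpenDX export), layered 2-D occupancy maps, 0.5-Å slab contact profiles
  along the bilayer normal, species fold-enrichment ratios, and lateral
  radial distribution functions around the channel axis.
- **Pose clustering.** Jarvis–Patrick (distance cutoff + common-neighbor
  linking) and GROMOS (greedy maximal-neighbor extraction) clustering of
  binder conformations with representative-pose selection (smallest mean
  RMSD to cluster members) and cluster populations.
- **Chemical interactions.** Distance-criterion hydrogen bonds (donor H to
  N/O/S acceptor ≤ 3.5 Å), salt bridges (N–O ≤ 4 Å), hydrophobic contacts
  (C–C ≤ 4.0 Å), and their lifetime statistics.
- **Electrophysiology fits** in a statsmodels-like Model/Results style:

  Boltzmann conductance–voltage curve

      G(V) = Gmin + (Gmax − Gmin) / (1 + exp[(V50 − V)·s])

  Hill concentration–response with the Hill coefficient constrained
  (|H| = 1 by default, sign recorded as metadata)

      ΔEffect([L]) = ΔEffect_max / (1 + (L50/[L])^|H|)

  and single-exponential relaxations `I(t) = A·exp(−t/τ) + C`, each
  returning estimates, standard errors, and a `summary()` table, plus
  per-cell ΔV50 / ΔGmax effect summaries.

Because real microsecond MD of a channel cannot be regenerated at desk
scale, the package ships a first-class **synthetic-data generator**: a
four-fold symmetric toy channel in a periodic box with lipids diffusing
laterally and binding planted sites with Markov on/off kinetics, plus
forward-modelled G(V)/dose–response/relaxation curves. Every downstream
stage is tested against this ground truth and against independent
brute-force oracles.

## Worked example

```python
import pufasite as p

spec = p.SyntheticSystemSpec(seed=42, n_frames=20000)
traj, truth = p.simulate_lipid_trajectory(spec)

tensor = p.compute_contact_tensor(traj, "LIN", cutoff=6.0)
stats  = p.symmetry_average(p.residue_stats(tensor), traj.topology.subunit_map)
cls    = p.classify_contact_residues(stats)
print("high-contact:", sorted(r for _, r in cls.high_contact))
print("stable-contact:", sorted(r for _, r in cls.stable_contact))
print("planted:", sorted({r for s in truth.planted_site_residues.values() for _, r in s}))

lstats = p.lipid_interaction_stats(tensor)
print("constant binders:", sorted(
    p.identify_constant_binders(lstats, tensor.duration).constant_binders))
```

prints

```
high-contact: [6, 15]
stable-contact: [6, 15]
planted: [6, 15]
constant binders: [4]
```

i.e. the two residue positions planted as binding-site anchors (residue 6 =
site I, residue 15 = site II, reported against the first subunit after
symmetry averaging) are recovered exactly as both high-contact and
stable-contact residues, and molecule 4 — the lipid pinned to site I for the
whole run — is the unique constant binder.

Fitting a synthetic conductance–voltage curve:

```python
gv  = p.generate_gv_data(p.BoltzmannCurveSpec(gmin=0, gmax=1, v50=-20, s=0.1))
res = p.BoltzmannModel.from_dataframe(gv).fit()
print(res.summary())
```

```
BoltzmannResults
============================================
parameter           estimate       std err
gmin             1.45098e-10     8.225e-12
gmax                       1     4.206e-10
v50                      -20     6.018e-09
s                        0.1      5.47e-11
--------------------------------------------
n = 15, SSR = 3.7132e-19, R^2 = 1.0000
```

The half-activation voltage V50 = −20 mV and slope s = 0.1 mV⁻¹ are
recovered to numerical precision from the 15-point −80..+60 mV protocol.

## Command line

```bash
pufasite simulate --seed 42 --frames 2000 --topology toy.gro --coordinates toy.xtc
pufasite map-sites --config run.yaml --out results/
pufasite fit-gv gv_curve.csv
pufasite fit-dose dose_response.csv --fix-emax -25
```

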