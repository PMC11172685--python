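# Methods

This note records the models, conventions and numerical choices behind
`allokit`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinate conventions and structure I/O

All residues are addressed by author (PDB) numbering of the closed-state
SHP2 crystal structure; every residue id in the pocket definitions
(Arg111, Glu83, Arg23, …) is interpreted in that frame. PDB reading and
writing go through biotite; alternate locations are resolved to the
highest-occupancy conformer (ties fall to the first-listed, conventionally
'A'). Hydrogens are kept when present but excluded by definition from the
`CA`, `heavy` and `heavy_to_CB` selections. `heavy_to_CB` keeps N, CA, C,
O, CB and OXT — the backbone-plus-Cβ atom set used as the clustering
metric.

The default domain intervals are N-SH2 = 3–104, C-SH2 = 112–216,
PTP = 221–524. These are configuration, not ground truth: the domain
boundaries are not sharply defined and several pocket members sit on the
inter-domain linkers (e.g. Ala105/Asp106 just past the N-SH2 interval,
Arg111 in the SH2–SH2 linker). Pocket members therefore carry their own
domain tags, taken from the source structure annotations; validation
against the interval map reports disagreements as warnings rather than
errors, because a hard check would be unsatisfiable for interface
residues. One such warning is expected for Phe113, which is tagged to the
PTP side of the tunnel pocket but falls numerically inside the C-SH2
interval.

## Pocket model

A pocket is a named set of member residues plus *key pairs* — cross-domain
residue pairs whose Cα distances act as integrity coordinates. Three
pockets are built in: the SHP099 tunnel site at the C-SH2/PTP interface,
the N-SH2/PTP interface site flanked by Glu83/Arg265 with its capping loop
(His85–Asp90, Gln92–Val95), and the three-domain junction pocket whose
members span all three domains with the Arg23/Glu176 gatekeeper pair at
its rim.

The junction pocket's default key pairs are six representative
cross-domain pairs — one per domain pair per terminus of the member list
(8↔144, 106↔189, 8↔239, 106↔242, 144↔239, 189↔242). The exact pairs behind
the published integrity traces are not enumerated anywhere, so this is an
editorial choice; the full pair matrix can be assembled from `members` if
a study needs it.

**Integrity profile.** Per frame, the mean absolute deviation of key-pair
Cα distances from an explicitly supplied reference state (crystal
structure or dominant-cluster representative — never inferred). Frames
with deviation ≤ 2.0 Å (configurable) are *formed*, the rest *disrupted*.
The published evidence for disruption is qualitative (diverging distance
traces), so the 2 Å figure is this package's operational threshold: small
against the ~4–8 Å distance jumps that accompany genuine pocket collapse,
large against ~0.5 Å thermal noise. Distances are internal coordinates,
so the profile is exactly invariant under rigid-body motion of frames.

**Loop state.** 'in' iff the loop Cα centroid lies within 8 Å
(configurable) of the pocket-member Cα centroid.

**Salt bridge.** Both the Cα–Cα distance and the minimum charged-N to
carboxylate-O distance are reported; the bridge criterion is side-chain
N⋯O ≤ 3.5 Å, the standard geometric definition. The reported sub-3 Å
bound-state distance is an observation, not the criterion, so the package
records distances and leaves the threshold configurable.

## Superposition and rotation angles

Superposition is weighted least squares via SVD (Kabsch) with the
determinant correction, so reflections are never returned; inputs with
fewer than 3 points or rank < 2 raise. The test suite checks it against an
independently implemented quaternion-eigenvalue (Horn) oracle to 1e−8 Å
over 1000 random instances.

The interdomain rotation angle between two structures superposes both on
the shared anchor-domain Cα set, then extracts the rigid rotation mapping
the mobile domain across structures; the angle comes from the matrix trace
(range [0°, 180°], symmetric in its arguments), with the axis available as
auxiliary output. Shared residues are matched by (chain, residue number,
residue name); name mismatches at the same number are excluded and logged.

## Clustering

Frames are globally superposed onto frame 1 on the backbone+Cβ set, then
k-means (k = 10 default, fixed seed) runs on the flattened coordinates.
Euclidean distance on superposed coordinates is a monotone proxy for RMSD
at fixed atom count. Each cluster's representative is the member frame
closest to the cluster mean; the dominant conformation is the
representative of the most populated cluster. Clustering is delegated to
scikit-learn, whose k-means relocates empty clusters internally;
assignments are bit-reproducible for a fixed seed.

## Screening rules

- Pre-filter: reject metal-containing compounds (any element outside
  {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}; list configurable),
  molecular weight > 700 Da (inclusive threshold kept), |net formal
  charge| > 1 a.u. Reports record the first failing rule plus all failing
  rules per compound.
- Ranking uses the best pose (pose_rank 1) per compound; affinity ties
  break lexicographically by compound id. How the original screen reduced
  multiple poses or broke ties is unstated; best-pose is the conventional
  choice.
- Progressive consensus at depths 20/40/60/80/100: at each depth, common
  compounds of both top-d lists not already selected are added. The final
  set equals the plain intersection of the top-100 prefixes; depth labels
  are the smallest scheduled depth containing the compound in both lists.
- The manually curated (h-VI) selection is inherently human judgement and
  is only ever ingested as a list, never computed.
- Tunnel-site cross-check: a hit is competitive iff its affinity is within
  2 kcal/mol (configurable margin) of the −13 kcal/mol reference pose of
  SHP099.
- The Tier-I top-2000 cut is a config default, not hard-coded.

## Stability triage

Ligand heavy-atom RMSD is computed against the initial docked pose after
superposing each frame onto frame 1 on receptor Cα atoms; the ligand is
never refit, so the series measures genuine pose drift. No
graph-automorphism symmetry correction is applied — for symmetric ligands
the reported RMSD is an upper bound. The 3 Å threshold is the stability
criterion; the class boundaries on the below-threshold fraction
(highly stable ≥ 0.90, unstable < 0.50) are this package's
operationalization of the three published class names — the original
split rule is unstated and the published class counts depend on
trajectories that are not available, so the boundaries are exposed as
configuration and echoed in output provenance. Final hits are compounds
highly stable against both receptor states.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of a seeded spec (one RNG per call, no
global state; same spec ⇒ identical output).

- **Toy receptor.** CA+CB beads (plus charged side-chain beads for
  Arg/Lys/Asp/Glu) on jittered grids around three well-separated domain
  centers, numbered so every builtin pocket resolves. The gatekeeper pair
  is placed 17 Å apart — the pre-binding separation — with charged groups
  facing; the capping loop starts in its 'in' position. Sufficient for
  every metric in scope (Cα distances, backbone+Cβ RMSD, centroids,
  N⋯O distances); it has no secondary structure, no sterics, no chemistry.
- **Trajectories.** Independent Gaussian fluctuations (σ = 0.3 Å per
  coordinate by default) around the base structure, plus rigid offset
  events applied to named atom sets from a chosen frame onward (pocket
  disruption, salt-bridge closure, loop-out). Real MD has correlated,
  anharmonic motion; these are statistical stand-ins that make planted
  signals exactly known. 100 frames stand for a Tier-III production run
  sampled at 1 ns.
- **Score tables.** Per-compound affinity = baseline (−7 kcal/mol) +
  shared latent + receptor noise; variances are split so the
  inter-receptor Pearson correlation equals ρ while the marginal spread
  stays at the noise floor σ (0.5 kcal/mol default). Planted binders (30
  by default) have the shared part lowered by Δ = 3 kcal/mol. Under these
  conditions a planted hit can, rarely, slip just past rank 100 in one
  list (the top-100 cut sits ≈ 4σ into the planted distribution), so
  recovery across 100 seeds is occasionally 99% rather than 100%.
- **RMSD traces.** Below-threshold fractions are drawn from bands sitting
  strictly inside the classifier boundaries (≥ 0.95 / 0.60–0.85 /
  0.05–0.40), frame 1 pinned at 0; the truth record carries the achieved
  fraction exactly.
- **Libraries.** Each violator breaks exactly one pre-filter rule
  (organometallics; > 700 Da alkanes; ±2-charged ions), the remainder are
  ordinary drug-like organics.

Passing tests on this data demonstrates algorithmic correctness —
detection of planted events, exact recovery of planted rankings and
classes — not predictive validity on real trajectories or real docking
scores.

## Problem sizes and known limitations

The published end-to-end campaign (0.26 M-compound library, ~28.6 µs of
trajectories) is far beyond a desk run; the package's own checks use
2000-compound tables, 100-frame trajectories and 100-seed repetitions,
which exercise every code path at full statistical resolution of the
planted effects. The structure-derived checks (sub-1 Å agreement of the
closed-state crystal structures; the ~120° C-SH2 rotation to the open
state) require fetching the four public PDB entries and only run with
network access. Contact profiling infers ligand polarity from elements
and covalent distance (1.8 Å cutoff) rather than a bond table; formal
charges and aromatic rings for ligands must be supplied explicitly.
Binding free energies, docking scoring functions and geometric cavity
detection are out of scope: pocket membership is data, not something the
package detects.
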