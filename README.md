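# allokit

Trajectory analytics and multi-tier virtual-screening triage for cryptic
allosteric pockets on SHP2.

SHP2 (gene *PTPN11*) is a non-receptor protein tyrosine phosphatase that
toggles between an autoinhibited **closed** state — the N-SH2 domain plugs
the PTP catalytic cleft — and an **open** state reached through a ~120°
rotation of the C-SH2 domain. Oncogenic activating mutations such as E76K
shift the equilibrium to the open state and weaken the classic allosteric
inhibitors (SHP099-type "molecular glues") that bind the C-SH2/PTP tunnel.
`allokit` implements the analysis stack used to characterize a third,
cryptic pocket at the N-SH2/C-SH2/PTP three-domain junction and to triage
candidate binders for it:

- **Pocket integrity over trajectories.** For a pocket defined by member
  residues and cross-domain residue pairs, the per-frame mean absolute
  deviation of pair Cα distances from a closed reference state,
  `d̄(t) = mean_k |d_k(t) − d_k(ref)|`, labels each frame *formed*
  (`d̄ ≤ 2 Å` by default) or *disrupted*. A capping-loop in/out state and
  the Arg23–Glu176 gatekeeper salt bridge (minimum side-chain N⋯O
  distance, 3.5 Å criterion) are tracked the same way.
- **Rigid-body metric core.** Least-squares (Kabsch) superposition with
  reflections excluded, paired RMSD, interdomain rotation angles extracted
  from the rotation-matrix trace, and a geometric protein–ligand contact
  profile (H-bond, hydrophobic, salt-bridge, cation-π).
- **Conformational clustering.** k-means (k = 10 by default) on globally
  superposed backbone+Cβ heavy-atom coordinates; the representative of the
  most populated cluster is the docking receptor.
- **Multi-tier screen.** Library pre-filter (no metals, MW ≤ 700 Da,
  |net charge| ≤ 1 a.u.), affinity ranking, progressive top-20/40/60/80/100
  consensus between two receptors, merging with a manually curated hit
  list, a cross-docking check against the SHP099 tunnel site
  (−13 kcal/mol reference), and Tier-III MD job planning.
- **Pose-stability triage.** Ligand heavy-atom RMSD vs the docked pose
  after receptor-Cα superposition; a 3 Å threshold and the fraction *p* of
  frames below it give three classes (highly stable *p* ≥ 0.90, unstable
  *p* < 0.50, else partially stable); final hits are highly stable against
  both the wild-type and E76K receptors.
- **Synthetic data.** Every input class (bead receptor, fluctuating
  trajectories with planted events, paired score tables with planted
  binders, RMSD traces, SDF libraries) can be generated with known ground
  truth, so the full pipeline is testable offline.

## Worked example

The published Tier-II hit tables ship with the package. Merging the
affinity-selected (t-BA) and visually curated (h-VI) candidate sets and
planning the Tier-III MD matrix:

```python
from allokit.datasets import load_tba_hits, load_hvi_hits
from allokit import merge_hit_sets, plan_tier3, rank

tba, hvi = load_tba_hits(), load_hvi_hits()
ranked = rank(tba, "wtSHP2-b")
print(len(tba.compounds), len(hvi.compounds))
merged = merge_hit_sets(tba.compounds, hvi.compounds)
print(len(merged), merged.overlap)
print(len(plan_tier3(merged.ids, ["wtSHP2", "mtSHP2"])))
print(ranked.compound_ids[0], ranked.affinities[ranked.compound_ids[0]])
```

prints

```
18 21
39 0
78
NSC-163300 -8.6
```

i.e. 18 affinity-selected plus 21 curated candidates, no overlap between
the two selection routes, 39 compounds entering Tier III as 78
receptor×ligand MD jobs, with NSC-163300 (−8.6 kcal/mol) the strongest
predicted binder against the SHP099-bound wild-type receptor.

A shell-level run of the same flow:

```sh
allokit consensus scores_wt.csv scores_mt.csv --depths 20,40,60,80,100 --out hits.csv
allokit plan-tier3 --hits-file hits.csv --receptors wtSHP2,mtSHP2 --out jobs.csv
```

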