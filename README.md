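# trajkit

Trajectory analysis for two-domain protein systems: superposition-based
flexibility metrics, protein–protein interface complementarity, inter-helix
angles, conformational-substate clustering, contact occupancy, and
essential-dynamics PCA — with a synthetic trajectory generator that provides
ground truth for validating every stage.

## Who this is for

Molecular-modelling studies of allosteric enzymes (the motivating case is a
two-domain cyclase whose catalytic site sits at the domain interface and is
modulated by ligand and G-protein binding) routinely ask the same battery of
questions of an MD trajectory: how flexible is each domain (RMSD
distributions, RMSF profiles), how complementary is the domain interface
(buried area, gap volume, gap index), how far has a diagnostic helix pair
opened, which conformational substates does a loop visit, which contacts are
maintained, and what are the dominant collective motions.  trajkit packages
those analyses behind one consistent atom-selection and trajectory model,
plus a comparative pipeline that contrasts bound and unbound states.

## The quantities it computes

* **RMSD / RMSF** after optimal (Kabsch) superposition, against iteratively
  converged average structures; per-residue displacement maps between two
  systems' averages (displayed 0 → 4 Å) and ΔRMSF maps (−1.2 → +1.2 Å).
* **Interface complementarity.**  Accessible surface area by deterministic
  Shrake–Rupley sampling; buried area on complexation
  ΔASA = (ASA_A + ASA_B − ASA_AB)/2; the inter-molecular **gap volume** by
  grid integration of a documented point-classification rule; and the
  **gap index** = gap volume / ΔASA (Å), where 1–5 is the typical range for
  protein–protein interfaces and lower means tighter packing.
* **Inter-helix angles** from signed N→C helical axes (initial direction
  from second-difference cross products, refined by a full helix-curve
  least-squares fit).
* **Substates** by GROMOS-style neighbor-counting clustering of the
  pairwise-RMSD matrix, with medoid and average structures per cluster.
* **Contact occupancy** (distance, hydrogen-bond with angle criterion, ion
  coordination) and **ligand mobility** (positional RMSD in the receptor
  frame; internal RMSD after self-fit).
* **Essential dynamics**: mass-weighted covariance of backbone heavy atoms
  (N, Cα, C), eigen-decomposition, mode projections, per-mode filtered
  trajectories, fractional variances and per-residue involvement.

## Worked example

The synthetic generator builds a two-domain system (chains A and B, each a
slab interface plus a helix pair) with prescribed substates, and the
analysis stages recover the construction:

```python
from trajkit import (GeneratorConfig, build_two_domain_system,
                     generate_trajectory, gap_index, angle_series,
                     cluster_substates, discard_equilibration)

config = GeneratorConfig(
    seed=7, n_frames=150, interface_separation=2.4, angle_a_deg=26.0,
    substate_displacements=[[0, 0, 0], [6, 0, 0], [0, 6, 0]],
    transition_matrix=[[0.94, 0.03, 0.03],
                       [0.03, 0.94, 0.03],
                       [0.03, 0.03, 0.94]])
base = build_two_domain_system(config)
traj, truth = generate_trajectory(base, config)
production = discard_equilibration(traj, 30)   # drop equilibration frames

metrics = gap_index(base, "chain A", "chain B")
print(f"gap volume {metrics.gap_volume:7.1f} A^3")
print(f"buried area (dASA) {metrics.delta_asa:6.1f} A^2")
print(f"gap index {metrics.gap_index:5.2f} A ({metrics.complementarity_band})")

angles = angle_series(production, "chain A and resid 408-420",
                      "chain A and resid 468-475")
print(f"helix pair angle {angles.mean:5.2f} +/- {angles.sd:.2f} deg")

substates = cluster_substates(production, "chain B and resname FIL",
                              "chain B and resid 978-988 and name N,CA,C",
                              cutoff=1.5)
print(f"substates: {substates.n_clusters}, populations {substates.sizes}")
```

prints

```
gap volume  1145.0 A^3
buried area (dASA)  191.1 A^2
gap index  5.99 A (loose)
helix pair angle 26.03 +/- 0.75 deg
substates: 3, populations [46, 45, 29]
```

The interface buries 191 Å² and the enclosed gap of 1145 Å³ gives a gap
index of 6.0 Å — a loose contact on the usual 1–5 complementarity scale, as
expected for a 2.4 Å slab separation.  The helix-pair angle reproduces the
configured 26° opening to within the per-frame noise, and clustering finds
exactly the three generated substates with populations matching the Markov
chain's dwell pattern.

## Command line

```bash
trajkit simulate --system apo --n-frames 100 --out apo.pdb   # fixture + ground truth
trajkit angles apo.pdb --range-a "chain A and resid 408-420" \
                       --range-b "chain A and resid 468-475" --out angles.csv
trajkit study --seed 0 --outdir study/     # four-system comparative study
```

`study` runs the apo / +ligand / +partner / +both analogue systems through
every stage and writes per-system CSV/JSON tables plus a pairwise comparison
report (displacement maps, ΔRMSF maps, deltas of all scalar summaries).

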