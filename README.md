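# gorgedyn

Analysis of "breathing" motions in deep enzyme active-site gorges, built
around the canonical case of *Torpedo californica* acetylcholinesterase
(TcAChE): the catalytic triad sits at the bottom of a ~20 Å deep, ~5 Å
narrow gorge whose bottleneck (mainly F330 and Y121) must transiently
widen for substrate-sized molecules to pass. The package turns an MD
trajectory (or a synthetic ensemble with known ground truth) into the
quantities that characterise this gating and its allosteric control:

- **Bottleneck radius R(t)** — per snapshot, the widest-path tunnel from
  an interior start point to bulk solvent on a clearance grid; R is the
  path's minimum clearance, i.e. the largest probe that can traverse the
  gorge.
- **Radius statistics** — normalized 8-bin (0.5 Å) histogram, constrained
  Gaussian fit `y = y0 + A√(2/π)·exp(−(x−x_c)²/2σ²)` with y0 = 0 and
  A = 0.5 fixed, open-state fraction (R > 2.4 Å, an acetylcholine-sized
  probe), mean ± sd, range, and two-sample comparisons.
- **Motion/radius correlation** — per-atom correlation vectors
  ρ_i between Cartesian position and R(t), and mass-weighted per-residue
  vectors d_n = Σ m_i ρ_i / Σ m_i whose magnitude ranks how much each
  residue's motion tracks the gorge; gorge-residue classification
  (heavy atom within 10 Å of the bound ligand) and per-subdomain RMSD.
- **Torsion mutual information** — I = S(1) + S(2) − S(1,2) over φ/ψ/χ
  torsion histograms (nats, read as kT), block-averaged with a
  circular-shift shuffle null, restricted to pairs within 14 Å Cα–Cα.
- **Dynamic communities and routes** — Girvan–Newman partitioning of the
  residue MI network (edge length 1/I, max-modularity stopping) and
  layered searches for ≥ 5-residue communication routes from gorge
  residues over I > 1 kT edges.

A synthetic-data module generates breathing-pocket pseudo-proteins,
coupled torsion pairs, and Gaussian radius samples with known ground
truth, so every stage is testable end to end without microsecond MD.
See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Run the whole pipeline on a synthetic breathing pocket (60 snapshots,
10 decorated residues with couplings 0.1 … 1.0, plus four torsion pairs
with correlations 0.95/0.9/0.5/0.0):

```python
from gorgedyn.pipeline import RunConfig, run_all

cfg = RunConfig(outdir="demo", seed=1, synthetic={
    "breathing": {"n_frames": 60, "n_residues": 10, "noise_sd": 0.1},
    "torsions": {"n_pairs": 4, "rho": [0.95, 0.9, 0.5, 0.0],
                 "n_frames": 5000},
})
report = run_all(cfg)
print(report["stats"]["A"])
```

prints (abridged)

```
gauss_fit:     x_c = 2.38 Å, sigma = 0.57 Å
open_fraction: 0.45
mean ± sd:     2.36 ± 0.60 Å   range 1.17 – 3.40 Å   n = 60
```

The pocket's true clearance is 2.5 Å + 1.0·B(t): the measured mean and
fitted center sit a grid-discretization offset (≲ 0.15 Å at 0.5 Å
spacing) below the latent mean, and the open fraction says the mouth
exceeded the 2.4 Å acetylcholine probe in 45% of snapshots. The
correlation stage ranks the decorated residues by |d_n| exactly in the
order of their planted couplings (|d| rising 0.56 → 0.97 for c_n
0.1 → 1.0 in `demo/dvec.tsv`), and the MI table in `demo/mi.tsv`
recovers the planted pair couplings (e.g. I ≈ 0.95 nats for ρ = 0.95,
≈ 0 for independent pairs).

The same stages are available from the shell:

```sh
gorgedyn run    --config run.yaml
gorgedyn radius --topology top.pdb --traj traj.xtc --hint 4.4 68.6 64.9 --out radius.tsv
gorgedyn stats  --in radius.tsv --out stats.json
gorgedyn mutinf --topology top.pdb --traj traj.xtc --out mi.tsv
gorgedyn community --mi mi.tsv --out communities.json
gorgedyn routes --mi mi.tsv --gorge gorge.txt --out routes.json
```

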