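# Methods

`gorgedyn` analyses the "breathing" motions of a deep enzyme active-site
gorge — the canonical case being *Torpedo californica* acetylcholinesterase
(TcAChE), whose catalytic triad sits at the bottom of a ~20 Å deep, ~5 Å
narrow aromatic gorge gated at a bottleneck formed mainly by F330 and Y121.
The pipeline has six stages: per-snapshot bottleneck radius, radius
statistics, motion/radius correlation, torsion mutual information, dynamic
communities, and communication routes. This note records the models,
defaults, and numerical choices behind each, and what the synthetic suites
do and do not demonstrate.

## Bottleneck radius by grid widest path

The minimal gorge radius R of a snapshot is the radius of the largest
spherical probe that can travel from an interior start point to bulk
solvent. On a cubic grid (default spacing 0.5 Å, 26-neighbour
connectivity) covering the structure plus a margin, each grid point gets a
*clearance*: the distance to the nearest van der Waals surface, computed
with one KD-tree per distinct radius class. Bondi element radii are used
uniformly; geometry is heavy-atom only, a deliberate choice since crystal
structures carry no hydrogens and radius comparisons then remain
internally consistent.

R is the widest-path bottleneck: the largest clearance threshold c at
which the start point still connects to a bulk-exposed point through cells
of clearance ≥ c. We compute it by bisection over the sorted unique
clearance values with connected-component labelling, which is exactly
equivalent to (and in the test suite verified against) an independent
max-heap widest-path Dijkstra, but runs in a few labelling passes of C
code rather than a Python node loop. An explicit path achieving the
bottleneck is then recovered by deterministic breadth-first search inside
the supra-threshold region (lexicographic tie-breaks throughout, so
results are bit-reproducible).

Probe semantics (defaults): inner probe 1.4 Å (cavity search), outer
probe 3.0 Å (a point must clear it to count as solvent-exposed), minimum
tunnel radius 0.9 Å (below it a snapshot is flagged "closed", with the
best achievable bottleneck still reported), shell radius 5.0 Å. "Bulk" is
the boundary-connected component of the region farther than the shell
radius from every atom center; requiring boundary connectivity keeps wide
*internal* cavities from terminating the search, which is the role the
shell-depth parameter plays in surface-peeling formulations (the
parameter is accepted for config compatibility, as is the cross-snapshot
clustering threshold; per-snapshot single best tunnels make clustering
unnecessary since only the per-snapshot minimal radius feeds downstream).
The start point is the maximal-clearance grid point within 5 Å of a
user hint (catalytic-triad or ligand centroid in practice).

Grid resolution bounds the accuracy: the analytic-pocket suite requires
agreement with the exact clearance only to within one grid spacing, and
halving the spacing must move R by at most one coarse spacing.

## Radius statistics

The distribution of R over snapshots is summarised by a normalized
histogram of 8 bins of width 0.5 Å (origin: the 0.5-Å lattice point at or
below the smallest value, overridable), a constrained Gaussian fit

    y(x) = y0 + A √(2/π) exp(−(x − x_c)² / (2σ²)),  y0 = 0, A = 0.5 fixed,

an "open" fraction (R strictly above a 2.4 Å probe modelling
acetylcholine), mean ± sample sd and range, and a two-sided two-sample
comparison (Welch's t by default, Kolmogorov–Smirnov via config — the
choice of test is a free parameter here, so p-values across variants are
not interchangeable).

The fit form is kept verbatim for comparability with published values
even though it carries no 1/σ normalisation: its peak height is ≈0.3989
for every σ, so the fitted σ absorbs the height mismatch and is biased
relative to the sample sd, while the fitted center x_c remains a faithful
location estimate for symmetric, peaked histograms. Two numerical
consequences are worth knowing: the least-squares fit is run from a
deterministic multi-start grid (x_c over the 8 bin centers, σ over
{0.2, 0.4, 0.8} Å, best residual wins), and on *flat* histograms the
verbatim form attains its best residual at a far-away center with a huge
width — peakedness, not just symmetry, is required for center recovery.
Fits are unweighted (bin-count weighting is another free choice we fix).

## Motion/radius correlation (ρ and d)

After rigid-body superposition of every frame onto a reference (Kabsch
SVD on all Cα by default; Eq-style time correlations are meaningless with
global rotation/translation left in), each atom i gets the correlation
3-vector between its Cartesian position and R(t),

    ρ_i = ⟨(r_i(t) − ⟨r_i⟩)(R(t) − ⟨R⟩)⟩ / √(⟨|r_i − ⟨r_i⟩|²⟩ ⟨(R − ⟨R⟩)²⟩),

with population (1/N) moments in numerator and denominator alike, and
each residue the mass-weighted average d_n = Σ m_i ρ_i / Σ m_i. By
Cauchy–Schwarz |ρ_i| ≤ 1, and |d_n| ≤ max |ρ_i| over the residue's atoms
(convexity). Frames with a missing R (closed or failed snapshots) are
dropped pairwise rather than imputed. Reported thresholds for "low" and
"high" |d| (0.1 and 0.4) are dimensionless here; published usage sometimes
attaches Å to them although the quantity is a correlation.

Gorge residues are classified by a minimum-heavy-atom-distance criterion:
any residue with a heavy atom within 10 Å of a bound-ligand heavy atom.
For TcAChE with the inhibitor E2020 the published enumeration of this set
(86 residues) ships with the package, along with the five gorge
subdomains (Ω-loop 67–94, S1 114–150, S2 225–296, S3 324–400, S4
428–450) and per-subdomain Cα RMSD series after a global fit.

## Torsion mutual information

Residue conformation is reduced to backbone φ/ψ plus side-chain χ1 and χ2
(χ1 only for proline, whose ring leaves higher χ redundant); ω, bond
lengths and angles are ignored. Longer side-chain torsions (χ3, χ4) are
deliberately omitted: they add estimator dimensions without changing any
behaviour the synthetic suites can resolve.

For two torsion series, I = S(1) + S(2) − S(1,2) with plug-in histogram
entropies in nats over equal-width bins spanning (−180°, 180°] (24 bins
of 15° by default, a common bias/variance compromise for dihedral data).
One nat equals one kT when entropies are expressed in units of k, which
is how the 1 kT coupling threshold downstream is calibrated.

The series is split into 5 blocks (trailing remainder dropped). Within
each block, a deterministic circular-shift shuffle null (5 evenly spaced
shifts) is subtracted from every torsion-pair I — plug-in MI is positively
biased, and the downstream threshold needs a calibrated zero. The
residue-pair value per block is the *maximum* over the pair's
torsion-torsion combinations (sum available via config; max avoids
inflating I for torsion-rich side chains), and the final I is the block
mean clamped at zero. Pairs whose mean-structure Cα–Cα distance is ≥ 14 Å
are masked as ineligible.

Calibration: on wrapped bivariate-Gaussian pairs the estimator is
compared against the *discretized* ground truth computed by quadrature
(rectangle probabilities of the bivariate normal), not the continuous
closed form −½ ln(1−ρ²); the difference between the two is the
discretization bias, which at 30° angular sd and 24 bins is ≈0.08 nats
for ρ = 0.9 and shrinks as bins grow. The 30° generator default is both
the documented wrap-validity bound and the regime where doubling the bin
count moves the estimate by < 0.1 nats.

## Communities and communication routes

The residue network has a node per chain-qualified residue and an edge
per eligible pair with I > 0, edge weight I and edge length 1/I (strongly
coupled residues are "close"; some distance convention is required and
none is canonical). Girvan–Newman proceeds by removing the edge of
maximal length-weighted betweenness (ties: lexicographically smallest
edge) and keeps the partition along the removal sequence that maximizes
weight-I modularity on the original graph — the standard stopping
companion when no community count is prescribed. Dimers are analysed as
one two-chain graph, so communities may span the interface. On clearly
modular graphs (clique families joined by weak bridges) this provably
recovers the exhaustive max-modularity partition, which the test suite
checks by brute force on ≤ 8 nodes; on graphs whose optimum is not
reachable by any betweenness removal sequence (e.g. a path glued to a
clique) Girvan–Newman is a heuristic, as always.

Routes model dynamic communication from the gorge outward: starting at a
gorge residue, expand layer by layer over edges with I > 1 kT, visiting
each node once per origin (a breadth-first *tree*, with each node's
parent its lexicographically smallest upper-layer neighbour). Every
maximal origin-to-leaf path is a candidate route; routes shorter than 5
residues are discarded as local, and duplicates across origins collapse.
Because pruning edges reorganises the tree, the route *set* is not
literally monotone in the threshold; what is monotone — and what the
tests assert — is the supra-threshold reachable set, within which all
routes stay.

## Synthetic data: what it emulates, and what it does not

The breathing generator builds a dead-end pocket: a solid floor disc, a
wide cylindrical chamber (flare × base radius), and a single constriction
ring at the mouth whose radius follows base + amplitude·B(t), where B(t)
is a stationary AR(1) process (coefficient 0.9) clipped to [−1, 1] —
autocorrelated, bounded breathing without any enzyme physics. Every
escape path crosses the mouth, so the true bottleneck clearance is
base + amplitude·B(t) − ring-vdW analytically (2.5 Å for the defaults at
zero amplitude). Decorated single-atom carbon residues outside the pocket
translate along fixed radial directions by c_n·amplitude·B(t) plus noise;
being single-atom, their d_n equals their ρ_i exactly, which makes the
mass-weighting transparent to test. Note the discrimination of coupling
*magnitudes* by |d_n| relies on the noise term: with zero noise every
coupled residue correlates perfectly with B(t) regardless of |c_n|, so
rank-recovery suites run at noise sd = 0.1 × amplitude.

Torsion pairs are wrapped bivariate Gaussians (sd ≤ 30° enforced so the
wrap is negligible) with the closed-form MI attached; radius samples are
plain normal draws. All randomness flows from per-spec seeds.

None of this mimics real protein geometry, secondary structure,
force-field physics, or the multi-tunnel topology of a real enzyme
surface: passing suites demonstrate the *estimators and algorithms* are
correct on known ground truth at desk scale, not that any particular
biological number is reproduced. Published headline numbers from
microsecond trajectories (per-system open fractions, community counts,
named routes) depend on sampling we do not perform. Problem sizes in the
shipped suites — tens to hundreds of frames, ≤ 10⁵-sample angle series,
≤ 15-node networks, pocket grids of ~10⁵ cells — were chosen as the
smallest scales at which each statistical property is resolvable.

## Known limitations

- The grid tunnel search returns one best tunnel per snapshot; there is
  no multi-tunnel enumeration or back-door/side-door detection.
- The constrained fit's σ is systematically biased (no 1/σ factor in the
  form); compare centers, not widths, across datasets.
- Plug-in MI with shuffle-null correction underestimates strong couplings
  at coarse bins (discretization) and is only defined for residues with
  at least one torsion; glycine without neighbours drops out.
- Girvan–Newman with 1/I lengths can fail to split networks whose
  inter-community coupling is spread over many weak edges; a single
  community with near-zero modularity is the honest output there.
- PDB is the only structure format; XTC/DCD/multi-model PDB the only
  trajectory formats (via MDAnalysis).
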