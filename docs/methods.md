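# Methods

This note documents the models, conventions and numerical choices behind
`gtcore`, and what its synthetic benchmarks do and do not establish.

## Coordinate substrate

Structures are read from PDB-format text (ATOM/HETATM/MODEL/ENDMDL/
REMARK 2) via Biopython's parser, wrapped in a small chain/residue/atom
hierarchy. Conventions:

- **Alternate locations** collapse to the highest-occupancy conformer;
  ties keep the first-listed (conventionally altloc A).
- **Insertion codes** are carried as part of the residue key so 52 and
  52A never collide.
- **Hydrogens** are parsed but excluded from all distance scopes by
  default; crystal structures rarely resolve them.
- **Resolution** comes from REMARK 2; models without one are dropped by
  the resolution filter (with a warning), and the filter is strict
  (`resolution < cutoff`, default 2.5 Å).
- Parsed coordinates are snapped to the file's fixed 3-decimal precision;
  the writer emits the same fixed-width format, so parse→write→parse is
  exact at 0.001 Å.
- Trajectories are multi-model PDB files; a topology check rejects any
  frame whose (chain, residue, atom-name) set differs from frame 0,
  naming the first divergent frame. Binary trajectory formats are out of
  scope.

## Core definition and position maps

The hydrophobic-core column sets on the 231-column GT-A alignment are
fixed constants: PBC {86, 87, 100}, Rossmann-shared {1, 2, 3, 13, 17, 20,
32, 33, 34, 86, 87}, GT-A-specific {100, 156, 183}; tether pair
(156, 183); xED-Asp at 180. Membership is reported as sets, not a
partition — column 100 genuinely belongs to both the PBC and the
GT-A-specific layer, 86/87 to both the PBC and the Rossmann layer.

Position maps (alignment column ↔ author residue number per structure
chain) are consumed as TSV. They originate upstream from profile-HMM
alignments; building profiles is out of scope here, so the map is an
input contract, not a computation. Mechanism labels (inverting /
retaining / GT2-related retaining) are likewise input metadata — they
come from family-level biochemical knowledge, not from structure — with
an `unknown` fallback excluded from group statistics.

## Tether distances and the mechanism comparison

`min_residue_distance` is the minimum Euclidean distance over an atom
scope: side-chain heavy atoms by default (glycine falls back to Cα, with
a log entry), with all-heavy and Cβ-only scopes available; the scope is
recorded on every output table. The default follows the biological
question — side-chain packing — while the all-heavy scope reproduces a
plain minimum-atomic-distance reading.

Redundancy reduction is greedy longest-first identity clustering:
each sequence joins the first representative with identity ≥ 0.90, else
founds a cluster. Identity is identical aligned positions divided by the
shorter sequence's length, from a global alignment under an identity
scoring scheme (match 1, mismatch 0, internal affine gaps, free end
gaps). This is deliberately simpler than CD-HIT proper, which uses word
filtering and its own length convention; at the 90% level and on
single-domain chains the assignments agree in practice, but exact parity
with CD-HIT is not claimed.

The mechanism comparison is a two-tailed two-sample *t* test on the
tether-pair distances, Welch by default (the retaining group's variance
is visibly larger than the inverting group's; pooled-variance Student is
available by flag). GT2-related retaining chains count as retaining.
Medians use the mean-of-middle-two convention for even counts. Density
exports for violin plots use a Gaussian KDE with Silverman bandwidth,
and the bimodality readout reports the locations of the largest KDE
local maxima.

## PBC similarity network

Fragments are Cα point sets at requested alignment columns (default
86–100, the PBC span; the span is configurable since the exact residue
window differs across superfamilies). Because correspondence comes from
the position map, pairwise similarity needs no alignment search:
it is the RMSD after optimal superposition (Kabsch, SVD with the
determinant correction so only proper rotations are allowed — mirror
images retain a nonzero residual). A precomputed external RMSD matrix
can be substituted by users who ran a structural aligner such as
TM-align; the network logic is unchanged.

Edges keep pairs with RMSD ≤ cutoff (inclusive; 2.5 Å default). Clusters
are connected components — the reproducible object; spring layouts are
emitted for drawing only. No sequence-order check is applied across
labels, so fragments with topological insertions still compare.

## Dihedrals and D-in/D-out occupancy

`torsion` implements the IUPAC signed dihedral in (−180, 180]: looking
down the central bond, clockwise rotation from the near arm to the far
arm is positive. Under this convention the angle is *invariant* when the
quartet is read backwards, and *negated* by mirror reflection; both
properties are regression-tested. Collinear degeneracies raise rather
than returning a garbage angle. Chi angles use the standard atom
quartets (Asp chi1 = N-CA-CB-CG, chi2 = CA-CB-CG-OD1; analogues per
residue type); missing atoms yield an absent value with a log entry.

D-in/D-out is an operational definition: each frame is assigned to the
nearest of two user-supplied reference (chi1, chi2) points under the
wrapped Euclidean metric on the torus, with frames farther than a
rejection radius (default 90°) from both references — and exact ties —
left undefined. No fixed angular windows exist for these states in the
literature; references are meant to be measured from the two conformers
of a crystal structure or taken from the generator. Asp chi2 is folded
into (−90, 90] before classification because the carboxylate's OD1/OD2
labelling is 2-fold ambiguous (flag to disable). Occupancy ratios are
computed over defined frames; the undefined fraction is reported
separately.

Water bridges use a distance-only criterion (water O within 3.5 Å of an
Asp carboxylate oxygen and of the partner's hydroxyl oxygen): the inputs
usually lack usable hydrogens, so no angular term is imposed.
Protonation states are not modelled; traces carry at most a metadata
label.

## Variant counting

Mutation tables are deduplicated on the (family, patient, sample,
position, alt-allele) key. The pruning described for public cancer
catalogues names only patient and sample identifiers; including position
and alt allele counts *distinct mutational events* per patient-sample,
which is the defensible reading and the one implemented. Reference
alleles are cross-checked against a supplied sequence when available;
mismatches warn and are kept by default (public variant tables often
disagree with isoform numbering), with a drop policy by flag. Each core
hit is annotated with a hydrophobicity-class change (Kyte–Doolittle
hydrophobic set). The summary also reports distinct (family, column)
core sites as the recurrent-hotspot view alongside the per-event count.

## Assay fits

Michaelis–Menten fits are unweighted nonlinear least squares with
duplicate wells averaged first; initialization is Vmax₀ = max rate and
Km₀ = concentration nearest half-max; standard errors come from the
covariance of the fit. Degenerate (flat/saturated) data and
non-convergence return flagged failures, not exceptions. kcat is
reported only when the enzyme molar concentration is supplied; otherwise
efficiency is Vmax/Km in signal units and labelled as such. Fold changes
propagate relative errors in quadrature.

Melt curves: Tm is the temperature of the maximum of the smoothed
(Savitzky–Golay, order 2, default 5-point window) first derivative
dF/dT inside the analysis window (default 40–70 °C), refined sub-grid by
a parabola through the peak and its neighbours. Derivative peaks outside
the window (e.g. a GFP-tag transition near 88 °C) are reported as
secondary transitions. Wider smoothing windows bias sharp transitions
by < 0.05 °C on the default 0.5 °C ramp grid; the window is exposed for
noisy data.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic under (parameters, seed) — one NumPy
Generator stream per artifact — and always return machine-readable
ground truth; downstream tests read truth only from there.

- **Structures** are geometric scaffolds: residues on a coarse grid with
  small positional jitter, and the two tether residues given explicit
  side-chain atoms whose closest pair sits at exactly the planted
  distance (quantized to the 0.001 Å PDB precision so write→read→measure
  is exact). They are not physically realistic proteins — no rotamer
  libraries, no packing energies — which is sufficient because every
  downstream computation is geometric or statistical.
- **Mechanism sets** default to the study conditions: 60 inverting
  chains at N(5.5, 0.75²) Å and 60 retaining chains from
  0.3·N(5.5, 0.75²) + 0.7·N(9.5, 0.8²), the low component labelled
  GT2-related; resolutions uniform in (1.0, 2.45) Å.
- **Trajectories** rebuild the tracked Asp frame-by-frame at the
  scheduled reference chis plus Gaussian noise (default σ = 15°), using
  the exact inverse of the torsion measurement. Ratios are realized as
  exact shuffled frame counts, so recovered occupancies test the
  measurement chain, not binomial luck. A bridging water is present in
  every frame (constant topology) but positioned to bridge only in D-in
  frames. Desk-scale frame counts (10⁴) stand in for microsecond MD;
  nothing about force fields, kinetics or waters' physics is claimed.
- **Mutation tables** plant exact per-column hit counts (default 42 core
  hits, 7 on the tether) and an exact number of duplicate rows (default
  25% of 400).
- **Assay curves** use the doubling concentration grids 0.3125–5 mM
  (acceptor) and 0.0625–1 mM (donor) in duplicate wells, with
  multiplicative Gaussian noise; melts are rising logistics on a
  25–95 °C ramp read every 0.5 °C.

Passing these benchmarks shows the analysis chain recovers known inputs
at the stated tolerances. It does not validate conclusions about real
GT-A corpora: real structure sets bring correlated errors, missing
atoms, alternative conformers and family imbalance that the scaffolds do
not model, and the published corpus-level numbers (e.g. the 972-chain
p-value or catalogue-wide variant totals) depend on external databases
that are inputs, not outputs, of this package.

## Problem sizes and calibration checks

The test suite runs the null calibration of the mechanism comparison at
2,000 replicates (n = 30 per group), the occupancy recovery at 10,000
frames per programmed ratio, the distance oracle at 200 random residue
pairs, and the rigid-invariance check at 100 random motions. Replicated
null tables are sampled directly from the programmed distributions
(`make_distance_table`) rather than through thousands of generated PDB
files; the structure→measurement path is separately shown to reproduce
planted distances to machine precision, so the shortcut is statistically
neutral.

## Known limitations

- PDB format only; mmCIF, assemblies and symmetry expansion are not
  handled.
- Identity clustering is not bit-compatible with CD-HIT (documented
  above).
- The per-column Shannon entropy is a descriptive conservation score for
  plots, not an evolutionary-rate estimate (no tree, no substitution
  model).
- State classification needs well-separated references (≥ 30° apart on
  the torus is enforced); heavily overlapping rotamer basins would
  require a density-based assignment instead.
- kcat/Km fold changes assume both fits converged and share units;
  cross-assay comparisons are the caller's responsibility.
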