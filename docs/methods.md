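# Methods

This note records the models and procedures `ligdyn` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not establish.

## Trajectory descriptors

All descriptors operate on a frame stack [n_frames × n_atoms × 3] in Å
after rigid superposition of each frame onto a reference frame (the first
frame by default). Superposition is a least-squares Kabsch fit (via
`scipy.spatial.transform.Rotation.align_vectors`) over a selection that
defaults to protein heavy atoms — the protein frame is the natural frame
for ligand-relative quantities, and using heavy atoms avoids hydrogen
placement artifacts. Fewer than 3 or collinear selection atoms raise an
alignment error.

**Adaptability** γ_x is the mean over frames of the Euclidean distance of
atom x from its reference-frame position. The reference frame's own zero
term is included in the average, matching a denominator of N_frames over
all timesteps; `include_reference_frame=False` switches to averaging the
other frames only (for a 2-frame trajectory with one atom displaced 1 Å
the two conventions give 0.5 vs 1.0 Å). Hydrogens are dropped from the
returned profile by default. **RMSF** is the RMS deviation about each
atom's time-mean aligned position and requires ≥ 2 frames. **Ligand
RMSD** superposes each frame on protein heavy atoms and evaluates RMSD
over ligand atoms with no second ligand fit, so it mixes internal ligand
motion with drift in the pocket — the convention that makes it a pocket
stability readout. **COM distance** is mass-weighted by default
(geometric centroid by flag; the choice is a convention, both are
exposed).

Closed-form limits used as oracles: for i.i.d. per-axis N(0, σ²)
displacements, |displacement| is Maxwell with mean σ√(8/π), so
γ → σ√(8/π), RMSF → σ√3, and γ/RMSF → √(8/3π) ≈ 0.921. A caveat
discovered during design: when the *alignment atoms themselves* carry
noise, the rigid fit absorbs part of it (6 fitted degrees of freedom
against 3N coordinates), biasing γ low by roughly 1 − 1/N_align — about
2% for 50 alignment atoms. The analytic-limit tests therefore keep the
alignment subset rigid (σ = 0) and put motion on the ligand, which makes
the superposition exact and the Maxwell limit clean. Real trajectories do
not offer rigid subsets; users comparing absolute γ values across
different alignment choices should expect percent-level offsets.

**Buried SASA** = SASA(P) + SASA(L) − SASA(PL) with each term from
Shrake–Rupley point sampling: 960 Fibonacci-lattice points per atom on
the probe-expanded sphere (Bondi vdW radii, probe 1.4 Å), a point being
accessible when outside every neighbour's expanded sphere. 960 points
give ≤ 1% error on an isolated sphere and ≤ 1.5% against the two-sphere
spherical-cap closed form; the count is configurable. The implementation
is quadratic in atoms per call, adequate at the pocket scale this
package targets.

## Structure QC

The curation protocol is expressed as geometry/connectivity heuristics;
QM-derived fields (HOMO–LUMO gap, electron count, charges,
polarizabilities) enter only as *inputs*.

- **Clashes**: non-bonded pairs closer than 0.5 × the covalent-radius
  sum. The KD-tree search is tested equal to all-pairs enumeration.
- **Bond perception**: bonded iff distance ≤ r_cov(a) + r_cov(b) + 0.45 Å;
  order upgraded through 1.5/2/3 at midpoints between reference
  equilibrium lengths of adjacent orders. Hybridization from neighbour
  count, corrected by planarity (3-coordinate) or angle (2-coordinate).
- **Valence audit**: bond-order sum vs. allowed valence (C 4, N 3, O 2,
  S 6, P 5, halogens 1), with +1 per positive formal charge for donor
  elements and 0.5 slack so perceived resonance orders (amides,
  aromatics) do not false-positive. Any one-bond neighbourhood with
  formal charge ≥ +2 is flagged as local charge excess — the signature of
  over-protonation around e.g. a guanidino carbon (+3 within one bond).
- **Geometry deviations**: bond lengths beyond 10% of the reference
  table, angles beyond 12° of the ideal VSEPR value for the perceived
  hybridization, sp2 centers pyramidalized beyond 0.25 Å out-of-plane.
  Thresholds are defaults chosen so that idealized geometry passes while
  the canonical pathologies (bonds stretched 17%, an angle opened 20°, a
  0.5 Å pyramidalized planar center) are flagged; all configurable. The
  numeric criteria are this package's declarations — the geometric
  pathologies themselves, not specific cutoffs, are the established
  facts. In the deviation checks the bond table can be supplied
  *independently* of the coordinates, reflecting real curation practice:
  connectivity is chemical identity (perceived from an idealized or
  reference structure), geometry is what is measured.
- **Property outliers**: per element group (≥ 8 points), residuals from a
  least-squares line of y on x, robust z via median/MAD, flag |z| > 4.
  Constant-x groups fall back to a univariate screen. The QC default
  (4 s.d.) is deliberately distinct from the much wider 20 s.d. filter
  applied to model *training targets*, which only removes catastrophic
  values while keeping genuine chemical diversity.
- **Electronic flags**: gap < 0.1 eV → convergence warning; odd electron
  count for a declared closed-shell species → failure.

All checks are deterministic and permutation-covariant; a report's
verdict is `clean` iff no warn/fail findings.

## Graphs and training data

Nodes are retained heavy atoms (waters and monatomic ions always
excluded); an edge joins every pair within 4.5 Å with weight 1/d.
The radius reading of "nearest neighbors within 4.5 Å" (rather than a
fixed k) is adopted because it is the only reading consistent with a
per-edge inverse-distance weight. Extra per-atom features (partial
charge, adaptability) append as columns, each with a 0/1 mask column so
protein atoms with no ligand-only feature remain representable.
Augmentation jitters every node per-axis uniform in [−0.05, +0.05] Å
(uniform chosen as the minimal assumption for a bounded "translation of
0.05 Å"; Gaussian available) and recomputes edges from the jittered
coordinates.

Affinity pairs: records cluster by (protein group, affinity type);
singleton clusters are discarded; the base complex is the member with the
median affinity (lower median on even sizes, ties to the smallest entry
id) — a deterministic choice that centers the label distribution; label =
log10(K_target/K_base), base 10 matching pKi/pKd conventions. The base's
self-pair (label 0) is excluded by default.

## Models

A compact reverse-mode autodiff engine (numpy arrays, topological-order
backward pass) underlies three networks; parameter counts sit near 10⁴ —
two orders below published-scale configurations (which the ModelConfig
docstring records for reference: 3 blocks/batch 128/200 epochs for the
graph task, 5 conv/batch 8/15 epochs node, 5 conv/batch 50/50 epochs
pair). Optimizer: Adam, lr 1e-3. Graph convolutions use weighted
symmetric degree normalization with self-loops; the QM model's messages
are gated per-channel by a 2-layer perceptron of the edge weight and
integrated by a GRU cell; pooling is sum for the QM head (extensive
targets), masked mean per ligand/protein for the affinity head. The two
QM targets are standardized to unit variance during training and
de-standardized at inference, giving equal loss weight. Training is
bit-reproducible for a fixed seed on single-threaded BLAS; inference is
batch-size independent to 1e-5 and exactly deterministic.

Evaluation: Pearson/Spearman/MAE on flat vectors; top-k overlap is
|top-k(pred) ∩ top-k(true)|/k per structure then averaged, ties broken
by descending value then ascending index (deterministic, matching a
stable sort on negated values).

## Benchmark construction and splits

Benchmark sets keep groups sharing (publication, protein, affinity type)
with ≥ 15 members, affinity span ≥ 2 log10 units, ≤ 5 records of the same
protein elsewhere in the collection, and no member flagged for a
site cofactor/metal. The 15-member floor is the established rule; the
2-decade range and co-occurrence cap of 5 quantify qualitative criteria
("high dynamical range", "few additional occurrences") and are
configurable.

Splitting clusters protein sequences by greedy single-linkage on 3-mer
containment identity (shared 3-mers over the smaller 3-mer set) at a
0.3 threshold — an alignment-free stand-in for percent identity with the
same leakage-control semantics, removing any external alignment-tool
dependency — then assigns whole clusters to train/validation/test by
seeded greedy deficit-filling toward the target fractions (default
80/10/10; 82/9/9 equally valid via the parameter). Achieved fractions
land within one cluster's mass of the targets; a cluster is never split.

B-factor validation drops entries whose modal B value covers ≥ 80% of
atoms (boundary inclusive — the conservative, more-excluding reading),
then correlates per-atom B with RMSF per entry and reports the
per-entry vector and mean. Pearson correlation makes the result
invariant under affine B rescaling.

## Synthetic fixtures

Generators are pure functions of (seed, parameters). The complex
generator traces a gently turning backbone of 4-atom pseudo-residues at
canonical bond lengths and docks a mixed-element zig-zag ligand 2.7–4 Å
from the chain, clash-free by construction. Trajectories displace atoms
i.i.d. Gaussian per frame (per-atom σ from a mobility profile) and then
apply one shared random rigid motion per frame (up to 10°/3 Å) so that
alignment is exercised; frame 0 is the unperturbed reference. QM tables
make electron affinity and chemical hardness exact linear functions of
ligand element counts (+0.02 eV noise) and place halogen
charge/polarizability pairs on per-element lines with planted off-line
outliers recorded as ground truth. Affinity clusters share a protein per
cluster and draw ligand variants whose true log10 affinity is linear in
composition (σ = 0.05 noise); element effect sizes are set so a cluster
spans the multi-decade range of a published SAR series, and a
configurable fraction of clusters deliberately violates benchmark
filters.

What passing tests show: the estimators agree with independent oracles
and closed forms, the filters recover planted truth, and the models can
learn relationships that are genuinely encoded in their inputs. What they
do not show: performance on real MD (correlated, anharmonic motion;
solvent; conformational transitions), real chemistry (the geometry
generator produces idealized fragments, not strained rings or metals), or
real affinity data (assay noise is not i.i.d. Gaussian in log space).
Desk-scale problem sizes (hundreds of molecules, tens of complexes,
thousands of frames) were chosen so the full suite runs in minutes on one
CPU; they are statements about correctness, not about reachable accuracy
at scale.

## Numerical choices and degenerate inputs

- RMSD of a superposition is recomputed from transformed coordinates
  (not the solver's residual norm) for full float precision.
- Zero-s.d. target sets: the outlier filter retains everything; target
  standardization falls back to unit scale.
- Empty prediction inputs return empty outputs; single-frame RMSF,
  sub-3-atom alignments, and fraction vectors not summing to 1 raise
  typed errors mapped to distinct CLI exit codes (0 ok, 2 usage,
  3 format, 4 validation, 5 internal).
- CSV affinities are written at %.17g and parsed with round-trip float
  precision so read∘write is exact; HDF5 arrays round-trip bit-exact.
- PDB coordinates carry the format's three decimals (1e-3 Å round trip);
  missing B factors stay absent rather than becoming 0, which is a legal
  B value.

## Known limitations

Bond perception is purely distance-based and will mis-order bonds in
strained or resonance-delocalized systems; the valence audit's 0.5 slack
correspondingly tolerates half-integer sums. The SASA routine is
O(n²) per call. Sequence identity by 3-mer containment saturates for
repetitive sequences and is not a substitute for alignment when near the
threshold. The models ship no pretrained weights and make no claim about
published-scale correlations; they are baselines demonstrating that the
featurization carries the signal.
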