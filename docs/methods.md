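# Methods

This note documents the model implemented by `akscore`, the conventions and
numerical choices behind it, what the synthetic-data generator does and does
not emulate, and the scaled-down study sizes used by the test suite and the
acceptance script.

## Featurization

A protein–ligand complex is represented as a 16-channel atomic-density grid.
The grid is a 30 Å cube of 30×30×30 voxels (1.0 Å spacing) centered on the
ligand center of mass (mass-weighted, standard atomic weights); voxel centers
therefore sit at ±0.5, ±1.5, …, ±14.5 Å from the center along each axis.
Each atom deposits

    n(r) = 1 − exp[−(r_vdw / r)^12]

at every voxel center, where `r` is the atom–voxel-center distance and
`r_vdw` the atom's van der Waals radius (AutoDock4 parameter set, shipped in
`akscore.atoms.VDW_RADII`, overridable).  `n(0)` is defined as the limit
value 1.  Per-atom contributions are summed without saturation (a `clamp`
flag caps voxels at 1 for sensitivity studies).  Atoms farther than
`r_vdw + 5 Å` from a voxel center are skipped; their contribution is below
10⁻³, and the voxelizer-vs-brute-force test bounds the resulting error.

Atoms are classified into eight classes — hydrophobic (aliphatic or aromatic
C), aromatic (aromatic C), hydrogen-bond donor (H bonded to N/O/S, plus the
heavy atom bearing it), hydrogen-bond acceptor (N/O/S with a lone pair),
ionizable positive, ionizable negative, metallic (Mg/Zn/Mn/Ca/Fe), and
excluded volume (every atom).  Protein and ligand atoms feed separate
channel blocks, giving 16 channels (protein first, then ligand, in the class
order above).

Conventions adopted where a choice was open:

- Densities are evaluated at voxel centers (not integrated over voxels);
  this makes the 24 proper cube rotations act exactly on the voxel lattice,
  so rotation augmentation is an exact symmetry of the featurization.
- Hydrogens, when present in the input files, contribute like any other
  atom; the donor flag sits on both the polar hydrogen and its heavy donor.
- The positive/negative classes are restricted to atoms of recognized
  ionizable groups (amines/ammonium/guanidinium/imidazolium; carboxylate,
  phosphate, sulfonate, alkoxide), then signed by the Gasteiger partial
  charge of the center *including its (implicit or explicit) hydrogens* —
  an ammonium nitrogen is itself Gasteiger-negative while the protonated
  group is positive, and it is the group chemistry that the class encodes.
- Ligand aromaticity and charges come from the molecular graph (SDF/MOL2
  bond orders via RDKit).  PDB files carry no bond orders, so protein-side
  aromaticity uses the His/Phe/Trp/Tyr ring templates, and protein ionizable
  groups use residue templates (Lys/Arg side-chain N, Asp/Glu carboxylates,
  C-terminal OXT); backbone amide N counts as donor (except proline), and
  the only protein N acceptors are the His imidazole nitrogens.

The refined-set filter applies the five dataset quality conditions
(resolution ≤ 2.5 Å; affinity measured as Ki or Kd; noncovalent binding;
1:1 stoichiometry; ligand elements within {C, N, O, P, S, F, Cl, Br, I},
with H additionally tolerated since protonated structures carry it).
Records are rejected with the first failed condition in that fixed order;
missing metadata raises instead of silently passing.

## Network

The scoring network consumes the (16, 30, 30, 30) grid and regresses the
binding free energy in kcal/mol.  Architecture:

- Stem: Conv3D, 16→64 channels, kernel 5, stride 2, 'same' padding
  (asymmetric where needed), giving a (64, 15, 15, 15) tensor.
- 15 pre-activation residual blocks in the grouped-convolution (ResNeXt)
  style, cardinality 16.  Each block is three convolution stacks —
  norm → ReLU → 1×1 conv, norm → ReLU → grouped 3³ conv (16 parallel
  branches), norm → ReLU → 1×1 conv — plus the shortcut, which is a plain
  identity except where the channel count changes (then a 1×1 projection).
  Blocks 1–10 stay at 64 channels; blocks 11–15 carry 160, 160, 160, 192,
  384 channels, all at stride 1 (the spatial size stays 15³ after the stem).
- Head: global average pooling → Dense(64) → norm → ReLU → Dense(1).

Normalization layers normalize over all axes except the trailing one — for
the channel-first block tensors that is the last spatial axis (parameter
size 15), and for the head features the 64-dim feature axis.  This is the
behavior a Keras `BatchNormalization` layer with its default `axis=-1`
exhibits on channel-first data, and the architecture's printed parameter
budget is only consistent with it: the default configuration carries exactly
1,294,925 parameters — 1,293,447 trainable and 1,478 non-trainable (the
running mean/variance pairs of 45 spatial norms of size 15 plus one
64-feature norm: 2 × (45·15 + 64) = 1,478).  These counts are asserted as a
regression test; the block tuples were fixed by solving for the
configuration that reproduces them exactly.

Weights are He-normal initialized (seeded); biases start at zero except the
final regression bias, which starts at the training-label mean so that early
optimization goes into structure rather than intercept travel.  The loss is
the mean absolute error in kcal/mol; optimization is Adam with β₁ = 0.99,
β₂ = 0.999, ε = 10⁻⁷.  Candidate learning rates are 1e-4, 5e-4, 7e-4 and
1e-3 (default 7e-4).  The training set is re-permuted every epoch, and with
rotation augmentation enabled each complex contributes its 24 lattice
rotations as separate examples within the epoch.

The compute core is written in numpy: pointwise (1×1) convolutions are
batched BLAS matrix products; larger kernels go through a flattened-spatial
im2col in which each kernel offset is a contiguous shifted slice of the
padded buffer (outputs at halo positions are computed and cropped), so
operand assembly runs at memcpy speed and the contraction is a single GEMM
per sample.  All tensors are float32.  Backward passes are exact gradients
(verified against finite differences end to end).

Practical note on batch size: because the normalization statistics are
batch statistics, very small batches (2–4) cripple optimization — the
64-feature head norm computed over two samples leaves almost no usable
signal.  Batches of ≥ 8 train well; the training default is 16.

## Ensemble

The ensemble predictor is the unweighted mean of N independently seeded,
independently trained networks sharing one architecture and training set
(no bagging: members differ only in initialization, shuffling and
augmentation order).  The conventional ensemble size is 20; a 30-member
variant exists for head-to-head comparisons.  Member order is fixed in the
size-vs-quality curve; callers can shuffle members with a seeded RNG to
probe ordering variance.  Inference-time rotation averaging is off by
default (rotations are a training augmentation).

## Evaluation metrics

- Scoring power: Pearson correlation between predictions and experimental
  affinities, plus MAE/RMSE.
- Ranking power: within each receptor cluster of five complexes, Spearman's
  rho, Kendall's tau-b and the Predictive Index (PI) are computed and then
  averaged over clusters.  Tau-b uses the square-rooted denominator
  √((Nc+Nd+T)(Nc+Nd+U)) — the unrooted form is not bounded by 1.  PI
  weights each pair by the experimental affinity gap; the default scoring
  gives concordant pairs 1 and everything else 0 (range [0, 1]), and a
  `pearlman` mode scores discordant pairs −1 (range [−1, 1]).
- Docking power: fraction of cases whose native pose scores within the best
  k of {native} ∪ decoys, k ∈ {1, 2, 3}; lower (more negative) scores are
  better by default and decoys tied with the native pose count against it.
- Ties, everywhere they matter, are declared on values rounded to 6
  decimals, making tie counts platform-reproducible.
- The bootstrap comparison resamples ⌈2n/3⌉ points with replacement 1000
  times, computes Pearson R and RMSE for both predictors per resample,
  redraws degenerate resamples (counted), and combines the bootstrap means
  and standard deviations Welch-style:
  t = (mean_a − mean_b) / √(sd_a² + sd_b²).

## Interpretation

Channel ablation measures ΔMAE = MAE(ablated) − MAE(baseline) on an
evaluation set after destroying one input channel, either by zeroing it or
by permuting the channel's whole voxel blocks across complexes (preserving
the channel's value population and within-complex spatial structure while
decoupling it from the labels; a voxelwise shuffle would also destroy
spatial structure and is deliberately not the default).  Shuffle-mode
results are averaged over several permutation seeds and reported with their
spread; zero mode is deterministic.  Note the classic caveat: zeroing a
channel the model *uses* (even as a constant background) inflates ΔMAE
without the channel being *informative*; the shuffle mode is the
distribution-preserving probe.

For Grad-CAM the regression head is first converted to a 20-class
classifier over binned affinities (equal-count bins over the training
labels by default; equal-width available), with the backbone frozen and the
new head trained by softmax cross-entropy on the frozen 64-dim features.
The class-score gradient with respect to the last residual block's feature
maps is spatially averaged into channel weights; the rectified weighted sum
of the feature maps is upsampled trilinearly from 15³ to 30³, and each atom
receives the sum of map values at voxel centers within `r_vdw + 1 Å`.  The
default target class is the model's own predicted bin (self-consistent
choice; the class is otherwise caller-specified).

## Synthetic data

The generator emulates the geometry the pipeline consumes — not chemistry.
A complex is a typed atom cloud: ligand atoms inside a spherical pocket
(default radius 3.5 Å), protein atoms on a surrounding shell (1.2–6.5 Å
beyond the pocket).  Ligand sizes are drawn per complex from 8–18 atoms
(ligand series span sizes, and packed volume is the planted signal);
aromatic draws are realized as benzene-like six-rings so the written SDF
files are valid.  Atom classes follow configurable compositions whose
defaults roughly track binding-site statistics (≈40 % hydrophobic C, ≈15 %
aromatic, ≈27 % donors/acceptors, ≈10 % charged, a trace of metals on the
protein side).  With `shared_protein_seed` set, every complex shares one
pocket, emulating a ligand series against a single receptor — without it,
each complex's unique pocket acts as a fingerprint a high-capacity model
can memorize instead of learning the planted law (a property the
interpretation tests exploit deliberately).

The planted affinity is a known linear functional of the complex's own
grid: affinity = w · (per-channel density sums) + N(0, σ²), in kcal/mol.
Default weights are dominated by the ligand and pocket excluded-volume
terms with smaller hydrophobic/acceptor terms, scaled so affinities land in
the pKd 4–9 window; σ defaults to 0.5 kcal/mol, comparable to the intrinsic
spread of experimental affinity measurements.  Because the label is exactly
linear in channel sums, a linear model on the 16 sums is the oracle ceiling,
any competent model must recover the weighted channels, and ablating a
channel with nonzero weight must hurt — provided the study is designed so
no correlated shortcut exists (shared pocket; for single-channel planting,
the varying atoms carry only the excluded-volume class).

Fixture complexes are written as PDB (residue templates chosen so re-typing
reproduces the intended classes) plus SDF (rings bonded aromatically,
isolated heteroatoms as radicals/ions), and a labels CSV; reading them back
through `chem_io` reproduces coordinates to 10⁻³ Å and the voxel grids to
within SDF coordinate precision.

What passing tests on this generator do **not** show: performance on real
complexes, with real chemistry, real binding-mode diversity, or label noise
correlated with structure.  The generator validates the pipeline's
mechanics and the learnability of a planted signal, nothing more.

Decoy poses for docking power are rigid-body perturbations of the ligand
(rotation up to π about the ligand center of mass plus a translation of
0.5–8 Å).  Since the grid recenters on the ligand, a pure translation
leaves the ligand channels bit-identical and shifts the protein channels —
decoy discrimination is therefore a protein-environment signal, as it
should be.  Generic rotations resample the density on the lattice and
conserve the ligand density mass only to a few percent (measured ≤ 2.3 %);
the exact conservation holds for the 24 lattice rotations.

One consequence worth stating plainly: the planted affinity law is linear
in channel sums and those sums barely move under near-pocket rigid
perturbations, so the synthetic world plants *no pose preference* — under
the oracle law itself the native pose ranks near the middle of its decoys.
An affinity-trained model's docking power on this generator therefore
hovers at or below chance (the acceptance run reports it as such), and the
docking-power machinery is instead validated against decoy sets with
planted native ranks in the metric tests.  Real native poses are favored
by physics the generator does not emulate (sterics, interaction
complementarity).

## Study sizes used by the suite and the acceptance script

All sizes are package choices documented here once:

- Unit tests run a miniature configuration (stem 16, blocks 16/16/32, head
  8) on up to 8 complexes.
- The capacity demonstration trains the default 1.29M-parameter network on
  20 generated complexes in three constant-learning-rate phases (10 epochs
  at 1e-3 with batch 10, then full-batch fine-tuning at 5e-4 and 1e-4,
  stopping early once the target error is reached; no augmentation —
  augmentation only slows pure memorization).  Full batches make the
  normalization statistics deterministic: with partial batches the
  training-mode MAE carries an irreducible batch-composition noise floor of
  a few tenths of a kcal/mol regardless of fit quality.  The memorization
  error is then measured in eval mode after `calibrate_norms` sets the
  running statistics exactly (the default momentum of 0.99 converges far
  too slowly for short runs).
- The planted-channel ablation study trains the miniature configuration on
  20 single-receptor complexes whose variable ligand atoms carry only the
  excluded-volume class, then checks both ablation modes rank that channel
  first.
- The acceptance script's scoring study trains a 4-member ensemble of the
  miniature configuration on 24 complexes and evaluates on 12 held-out
  complexes, 6 ranking clusters of 5, and 5 docking cases of 30 decoys.

## Known limitations

- The trailing-axis normalization convention is unusual (it is what the
  parameter budget dictates); it behaves like a batch norm over a spatial
  slab and works, but channel-axis batch norm would be the textbook choice.
- Batch sizes below ~8 impair optimization (see above).
- Pure-numpy training is orders of magnitude slower than a GPU framework;
  the default architecture trains at laptop-CPU speeds of roughly half a
  minute per 20-complex epoch, which is why the demonstration studies are
  sized as they are.
- The ionizable-group SMARTS set is deliberately small; exotic charged
  chemotypes will fall back to neutral typing.
- Protein typing trusts residue/atom names; nonstandard residues degrade to
  element-based rules.
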