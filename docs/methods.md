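# Methods

`cgdesign` implements fixed-backbone protein sequence design (inverse
folding): given the backbone atoms N, Cα, C, O of a single chain, predict a
categorical distribution over the 20 amino acids at every position in one
forward pass, and evaluate the resulting designs with a battery of sequence-
and structure-quality measures. This note documents the model, the numerical
choices, the synthetic data used for testing, and the limits of what the
tests demonstrate.

## Graph representation

Residue neighborhoods are defined on virtual Cβ atoms reconstructed from the
backbone by the fixed linear combination

    rCβ = −0.58273431·u + 0.56802827·v − 0.54067466·(u×v) + rCα,
    u = rCα − rN,   v = rC − rCα,

which is defined for every residue type, glycine included. Two graph modes
exist:

* **contact graph** (default): directed edges between every pair of
  unmasked residues with ‖Cβᵢ − Cβⱼ‖ ≤ cutoff (default 12 Å, boundary
  inclusive); the edge set is symmetric and each edge stores the index of
  its reverse partner;
* **k-nearest-neighbor graph**: each residue receives edges from its k
  (default 30) nearest residues; distance ties break toward the lower
  residue index so construction is deterministic.

Self-loops are removed; residues missing any of the four backbone atoms are
masked and excluded from the graph, the features, the loss and all metrics.
For each edge (i, j) the second-order-edge (SOE) index enumerates the shared
neighbors n ∈ Nᵢ ∩ Nⱼ, i.e. the two-hop compositions (i→n, n→j).

## Featurization

All features are rigid-motion invariant. Each residue carries an orthonormal
local frame Q = [b, n, b×n] with b = (u−v)/‖u−v‖ and n = (u×v)/‖u×v‖;
degenerate geometry (collinear u, v) falls back to the identity frame and is
flagged. Distances are encoded by 16 Gaussian radial basis functions with
centers evenly spaced on [2, 22] Å and width equal to the spacing; sequence
offsets i−j are encoded by a 16-dim sinusoidal code (8 frequencies, signed
and unclipped); relative orientations by the unit quaternion of QᵢᵀQⱼ with
the sign fixed by w ≥ 0.

Node features (88 dims): unit vectors Cα→{N, C, O, virtual Cβ} in the local
frame (12); sin/cos of the three backbone bond angles and of ω/φ/ψ (12),
zero-filled at chain termini and next to masked residues; RBF-encoded
distances Cα→{N, C, O, virtual Cβ} (64).

Edge features (1119 dims): the 25 inter-residue unit vectors between the
five backbone atoms (incl. virtual Cβ) rotated into the target residue's
frame (75); RBF encodings of all 8×8 interatomic distances, where each
residue contributes the 5 backbone atoms plus 3 *learnable* virtual atoms
placed at x·u + y·v + z·(u×v) + rCα with (x, y, z) constrained to the unit
sphere by projection on every evaluation (1024); the relative quaternion
(4); and the positional encoding of i−j (16).

A note on the node dimension: the enumerated node blocks total 88; the
configuration echo records the dimension so downstream code never assumes a
different value.

## Network

The network stacks identical blocks (default 10, width 128); in each block
edge states update first, then node states.

Edge update: ê = MLP(hᵢ ∥ e ∥ hⱼ) for every directed edge; candidate
refinements are the symmetric update MLP(ê_ij ∥ ê_ji), the SOE update
(mean over shared neighbors n of MLP(ê_in ∥ ê_nj ∥ ê_ij), zero when the
shared-neighbor set is empty) and a plain second MLP of ê. The candidates
are merged by a selective kernel — the branch sum is squeezed by an MLP and
per-branch excitation MLPs produce dimension-wise logits normalized by a
softmax across branches — followed by dropout, residual, layer
normalization, and a position-wise feed-forward with its own
residual/normalization.

Node update: a single-head graph attention over incoming edges (query from
the node, key from the edge, value from MLP(hⱼ ∥ eⱼᵢ ∥ hᵢ); raw dot-product
logits, no scaling) plus a global context branch, where a per-dimension
softmax over all nodes of the graph weights value vectors into a single
graph summary G that is concatenated back to every node. The two branches
merge through a selective kernel; the first node residual applies no
dropout (the edge residual does), matching the update equations as printed.
Ablation switches turn the symmetric/SOE branches off and replace either
selective kernel by arithmetic-mean pooling, so the model variants of the
architecture study are pure configurations.

Design decisions where the architecture was genuinely open:

* every unnamed MLP is two affine layers with one GELU, hidden width equal
  to the model width; the feed-forward expansion factor is 2;
* the selective-kernel excitation is a softmax across branches (the
  alternative normalization w/Σexp(w) is not a normalized weighting and
  contradicts the SK-Net construction this module follows);
* input features are projected to model width by one affine layer plus
  layer normalization;
* the squeeze MLP halves the width (reduction 2, floor 8);
* with these choices the default model has ≈7.6 M parameters — the
  parameter count is a pure function of the configuration and is printed by
  `cgdesign describe`.

Masked residues emit NaN sentinel logits; unmasked logits are one-shot
(no autoregression) and exactly invariant to rigid motions of the input
because no operation ever sees absolute coordinates.

## Compute core

The network, its gradients, AdamW and the one-cycle schedule run on a small
reverse-mode automatic-differentiation engine over dense float32 numpy
arrays (`cgdesign.autodiff`), providing exactly the primitives the model
needs (broadcast arithmetic, matmul, gather/segment-sum, segment softmax,
GELU, reductions, concatenation). Gradients flow through the virtual-atom
coefficients via the distance-RBF block, which is rebuilt differentiably in
each forward pass while all geometry-constant feature columns are cached
per structure. Gradient correctness is verified against central-difference
numerics in the test suite.

## Training

Cross-entropy (natural log, no label smoothing) over unmasked residues;
AdamW (lr from the schedule, β = (0.9, 0.999), ε = 1e-8, decoupled weight
decay 0.01); one-cycle schedule with max learning rate 0.004, 30% cosine
warm-up from max/25, cosine decay to max/25/10⁴ (warm-up fraction and
final divisor are unstated upstream; the values used are recorded in the
config echo). Structures are shuffled each epoch and greedily packed into
batches of at most 4096 residues; a batch is processed one graph at a time
with gradient accumulation, which is mathematically identical to joint
processing because no operation crosses graph boundaries. Dropout 0.1 by
default. Optional augmentation adds zero-mean Gaussian coordinate noise
(σ = 0.02 Å mirrors the augmentation studied for generated structures) to
every atom each epoch. Logged epoch losses are recomputed in float64 from
the same logits so that exp(training loss) agrees with the evaluation
module's perplexity to numerical precision.

## Synthetic data

`cgdesign.synthetic` grows single chains from ideal internal coordinates
(N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C–O 1.231 Å, standard bond
angles; helix φ/ψ = −57°/−47°, strand −119°/+113°, coil φ/ψ drawn
uniformly from a broad allowed region, seeded). The default dataset
generator composes random helix/strand/coil segments into chains of 24–48
residues — long enough for contact-rich cores at the 12 Å cutoff, short
enough for desk-scale training. Native sequences come from a deterministic
geometry→sequence rule: residue i gets alphabet index
(contact-graph degree of i at 12 Å) mod 20. The rule is a function of the
same graph the model consumes, so a small model must be able to fit it;
the learnability test trains 2 blocks at width 64 for 300 epochs on 10
structures (dropout off — the fixture measures capacity to fit, so
regularization is disabled) and requires ≥95% training-set recovery.

What this emulates and what it does not: the backbones have realistic local
geometry and contact statistics but no side chains, no packing
optimization, no Ramachandran heterogeneity beyond three idealized states,
and labels that are geometric by construction rather than evolutionary.
Passing tests therefore demonstrate that the pipeline is correct and that
the architecture can learn graph-determined sequence rules; they say
nothing about recovery rates on real protein structures, which require
database-scale training.

## Evaluation battery

* **Perplexity**: exp of the dataset-pooled mean negative log probability
  of native residues (one double sum over structures and residues);
  probabilities are floored at 1e-12 with a warning.
* **Recovery**: percent identity of the argmax design to the native
  sequence; dataset summary is the median across structures (pooled
  recovery is reported alongside).
* **Composition**: per-type relative deviation |X−X′|/X of pooled
  frequencies; types absent from the natives are flagged NaN, never
  divided by; the summary is the median over the 20 types.
* **Substitution matrix**: position-wise native/designed pairs with a
  pseudocount of 1 per cell give a joint distribution; scores are
  log₂ p(x,y)/(q(x)q(y)) and are correlated (Pearson, all 400 cells)
  against the embedded BLOSUM62 matrix.
* **BLOSUM score**: per residue Σ_y P(y)·BLOSUM62(native, y); the relative
  score divides by the native one-hot score, so natives score exactly 1.
* **Low complexity**: two-pass detector with window 12, trigger entropy
  ≤ 2.2 bits, extension ≤ 2.5 bits; pass two minimizes the composition
  probability P0 with ties toward longer then left-most subsequences; LCR%
  is the covered fraction of the sequence.
* **Hydrophobicity conservation**: classes {I,L,M,F,C,W,P,V,A,G} vs
  {S,T,N,Q,D,E,H,R,K,Y}; the headline number is the joint class-match
  percentage, with per-class breakdowns.
* **Burial split**: Shrake-Rupley SASA (probe 1.4 Å) on the present
  backbone atoms, normalized by the residue type's theoretical maximum
  accessibility; RSA < 0.2 is core (boundary exactly 0.2 is surface);
  recovery is reported per class.
* **RMSD**: Kabsch superposition with a proper rotation enforced.
* **GDT-TS**: mean over the 1/2/4/8 Å cutoffs of the best fraction of Cα
  pairs within the cutoff over a family of superpositions — the global fit
  plus every contiguous 7-mer seed iteratively extended (up to three
  rounds) to the residues it brings within 4 Å. This is a documented
  approximation of the exhaustive LGA search, not a reimplementation of it.

## Numerical and degenerate-input conventions

Working precision is float32; invariance tolerances in the tests reflect
that (1e-3 on end-to-end logits, 1e-4 on features). Boundary conventions:
contact cutoff inclusive; KNN ties to the lower index; argmax sampling ties
to the lower alphabet index in ACDEFGHIKLMNPQRSTVWY. Empty shared-neighbor
sets give a zero SOE contribution. Isolated nodes get a zero local-
attention vector but still receive the global branch. A structure whose
residues are all masked is rejected; a single-residue chain zero-fills all
neighbor-dependent angle features.

## Known limitations

No multi-chain complexes, no autoregressive decoding, no side-chain
modeling, first NMR model only, no steric-clash counting, and no external
refolding checks (those require structure-prediction tools outside this
package). Reported headline numbers from database-scale experiments are not
reproducible at desk scale; the test suite instead pins the analytic fixed
points, brute-force graph equivalences, invariances and the synthetic
learnability bar described above.
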