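# cgdesign

Fixed-backbone protein sequence design (inverse folding) with a
contact-map graph neural network, for structural bioinformaticians who
want a self-contained, CPU-friendly implementation of the full design
loop: backbone I/O, graph construction, invariant featurization, a
message-passing network with second-order edge updates and selective
kernels, training, sequence sampling, and a sequence/structure evaluation
battery.

## The model

A backbone is turned into a directed residue graph whose neighborhoods are
*contacts*: residues i and j are connected when their virtual Cβ atoms,

    rCβ = −0.58273431·u + 0.56802827·v − 0.54067466·(u×v) + rCα,
    u = rCα − rN,  v = rC − rCα,

lie within a cutoff (default 12 Å), so dense cores get many neighbors and
loops get few — unlike a k-nearest-neighbor graph's fixed fan-in (also
available, `graph_mode="knn"`). Node features (88-dim) and edge features
(1119-dim) are rotation- and translation-invariant: unit vectors in
per-residue local frames, backbone bond/torsion angles, RBF-encoded
interatomic distances (including three learnable virtual atoms per
residue), relative-orientation quaternions, and sinusoidal encodings of
sequence offsets.

Each of the (default) 10 network blocks updates edges first — basic update
ê = MLP(hᵢ‖e‖hⱼ), enriched by the reverse edge MLP(ê_ij‖ê_ji) and by
second-order edges averaged over shared neighbors n ∈ Nᵢ∩Nⱼ — then nodes,
via single-head graph attention over incoming edges plus a global context
branch. Candidate updates are merged by a selective kernel (dimension-wise
softmax gating across branches). Decoding is one-shot: a single forward
pass yields per-residue 20-way distributions. Training minimizes
cross-entropy with AdamW under a one-cycle schedule (max lr 0.004, batches
of ≤4096 residues).

Everything runs on a small numpy reverse-mode autodiff engine included in
the package, so no deep-learning framework is required.

## Worked example

Train a small model on synthetic backbones whose "native" sequences follow
a deterministic geometric rule (residue identity = contact count mod 20),
then design and evaluate:

```python
from cgdesign import CgnnModel, ModelConfig, TrainConfig, train
from cgdesign.synthetic import make_dataset
from cgdesign.design import sample_sequences, softmax_probabilities
from cgdesign.metrics import evaluate_designs

dataset = make_dataset(6, seed=42)                  # labeled synthetic chains
model = CgnnModel(ModelConfig(width=64, blocks=2, dropout=0.0, seed=7))
result = train(model, dataset, TrainConfig(epochs=60, seed=3))

records = []
for s in dataset:
    logits = model.forward(s)                       # (L, 20), one-shot
    rec = sample_sequences(logits, mode="argmax", structure_id=s.name)
    rec.probabilities = softmax_probabilities(logits)
    records.append(rec)
print(evaluate_designs(dataset, records).summary())
```

Output (abridged):

```
epoch   0  loss 3.2033  accuracy 0.090
epoch  20  loss 1.4817  accuracy 0.500
epoch  40  loss 0.6487  accuracy 0.816
epoch  59  loss 0.4393  accuracy 0.873
{'perplexity': 1.55, 'median_recovery_pct': 90.8,
 'median_composition_rel_dev': 0.108, 'blosum62_pearson_r': 0.37,
 'median_relative_blosum_score': 0.69, 'lcr_pct': 86.2,
 'hydrophobic_conservation_pct': 92.9}
native   : FIIILLLLKKLHIHIHHHKIKIIIGG
designed : FIIILLLLKKLHIHIHHHKIKIIIGG
```

Reading the numbers: the loss falls from the uniform baseline (ln 20 ≈ 3.0)
toward zero as the model learns the geometric labeling rule; perplexity
1.55 means the model concentrates most probability on the correct residue
(1 = certain, 20 = uniform); median recovery 90.8% is the per-structure
identity of the argmax designs to the native labels. The LCR percentages
are high for both native and designed sequences because the synthetic
labeling rule produces repetitive sequences — on real proteins low values
are better. The first chain is recovered exactly.

The same loop is available from the shell:

```bash
cgdesign synth --spec demo.yaml --out out/        # PDB + FASTA pair
cgdesign train --synthetic 10 --width 64 --blocks 2 --epochs 60 \
               --out run/ --seed 1
cgdesign design --structure out/demo.pdb --checkpoint run/checkpoint.npz \
                --out designs/ --probabilities
cgdesign evaluate --structure out/demo.pdb --designed designs/demo.fasta \
                  --out eval/
cgdesign describe --width 128 --blocks 10        # layer table + param count
```

Every command writes a JSON config echo next to its outputs so results can
be regenerated exactly.

## Evaluation battery

`cgdesign.metrics` implements perplexity, per-structure and pooled
recovery, amino-acid composition deviation, a BLOSUM62-referenced
log-odds confusion matrix (Pearson r over all 400 cells),
probability-weighted BLOSUM scores (absolute and native-normalized),
two-pass low-complexity-region detection (window 12, 2.2/2.5-bit cutoffs),
hydrophobicity-class conservation, Shrake-Rupley-based core/surface
recovery (RSA < 0.2 = core), Kabsch RMSD and GDT-TS (1/2/4/8 Å cutoffs).
See `docs/methods.md` for definitions and conventions.

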