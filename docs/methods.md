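# Methods

## Protein representations

Each target carries two per-residue embedding streams of an
`L`-residue protein, 384 features per residue: the Evoformer single
representation and the Structure-module activations of AlphaFold2's
trunk. This package stores them residue-major (`[L × 384]`, residues as
rows) so that averaging over the residue dimension — the operation that
produces fixed-size per-target vectors for clustering and splitting — is
a plain row reduction. All operations state their axes; `L ≤ 1536` is
required for model-eligible targets, matching the selection criterion on
sequence length.

The model consumes the two streams feature-concatenated to `[L × 768]`
by default (`stream_mode="concat"`); single-stream modes are selectable
for ablation. Concatenation was chosen because both streams are
available per target and neither is privileged a priori; it loses no
information and keeps the projection layer the only merge point.

**Shuffle corruption.** The control regime permutes each stream's rows
(residue order) and columns (feature identity) with one fixed
seed-determined permutation per call. This preserves the entry multiset
— so value statistics, norms, and dynamic range are untouched — while
destroying everything the embedding says about the protein. Whether the
original ablation resampled permutations per epoch is unknowable from
the description; one fixed permutation per target is the simplest
reading and is what `shuffle_embedding` implements.

**Stratified split.** Targets are split family-stratified with
largest-remainder quota allocation (per-family quotas stay within one of
`test_fraction × family size` while the total matches the global
quota). After a uniform first draw per family, remaining targets are
drawn with weight `0.05 + max similarity to the already-selected test
targets`, concentrating related targets on the same side of the split.
Similarity is an injected function; the default is cosine similarity of
residue-averaged embeddings mapped to `[0, 1]`, because the embedding
type does not carry amino-acid sequences. When sequences are available,
`sequence_identity_fn` builds a global-alignment identity function
(Biopython `PairwiseAligner`) with the same signature. Orthologue groups
are indivisible: if any member is drawn into test, the whole group
follows, preventing cross-species leakage. Single-member families go to
train, since one target cannot be stratified.

## Ligand data

Records are `(accession, SMILES, pChEMBL)` triples; pChEMBL is
−log10 molar potency pooled over Ki, Kd and IC50. Standardization keeps
the largest organic fragment (most heavy atoms among carbon-containing
fragments; ties by molecular weight, then canonical string — a
deterministic salt-stripping rule), removes stereo descriptors and
explicit hydrogens, and canonicalizes with RDKit. Charges are left as
parsed; no neutralization pass. Duplicate (target, molecule) pairs keep
the **maximum** pChEMBL: the pipeline selects "highly active" compounds,
and the maximum is the aggregation consistent with that intent (the
alternative, mean aggregation, is a one-line configuration change).
The activity filter is inclusive: pChEMBL ≥ 6.5 (≈ sub-315 nM). Target
selection keeps ≥ 10 actives and ≤ 1536 residues.

## Data augmentation

Per-target ligand counts in public corpora follow a power law; an
unweighted corpus would concentrate the training loss on a few rich
targets. Two formulas rebalance it.

**Count quota.** With `n_min` and `n_max` the minimum and maximum ligand
counts across the corpus, a target with `n_i` ligands is brought to

    n_i' = n_max · (ln(n_i / n_min) + 1) / (ln(n_max / n_min) + 1)

rounded half-up and floored at `n_i`. Properties: monotone in `n_i`;
compresses the dynamic range from `n_max/n_min` to
`ln(n_max/n_min) + 1` (590× → 7.4× at the full-scale corpus bounds of
10 and 5,903); guarantees `n_i' ≥ n_i` on its domain with equality
exactly at `n_i = n_max`, so the richest target is left unaugmented.
`n_min`/`n_max` default to corpus-derived values and can be pinned to
(10, 5903) for comparability with the full-scale corpus.

**Potency weights.** Each record's probability of being drawn for
augmentation is `P_j = w_j / Σ_k w_k` with

    w_j = C^(pChEMBL_j − r),      r = 5.5, C = 3

i.e. threefold weight per pChEMBL unit, unit weight at 5.5. The weight
is strictly increasing and positive on the whole plausible pChEMBL
range; `C` sets the strength of the preference for potent ligands and
`r` the potency carrying unit weight. The exact printed forms of the
original count/weight formulas are not recoverable from the available
text, so these forms were fixed from their documented roles, constants
and boundary behavior before implementation; their boundary values are
frozen as symbolic-evaluation oracles in the test suite.

**Corpus building.** Each target emits its originals once plus
`n_i' − n_i` enumerated variants of records drawn **with replacement**
under `P` (oversampling implies replacement). Variants are randomized
SMILES spellings of the same molecule; duplicates are redrawn up to 20
times, then accepted (tiny molecules have few spellings; unbounded
retries would not terminate). Augmentation therefore adds no new
chemistry — every emitted string canonicalizes into its target's
original ligand set — but grows the corpus and shifts its potency
distribution upward. One global seed fans out to per-target seeds via a
CRC32 hash of the accession, so output is independent of target order.

## Tokenization

The standard SMILES regex inventory: bracket atoms as single tokens,
two-character halogens, organic-subset atoms, ring-closure digits and
`%nn`, bond/branch punctuation. Specials PAD/BOS/EOS/UNK take ids 0–3;
the rest are lexicographic, so the vocabulary is corpus-order
independent. Encoding is strict (UNK is an error) and length-bounded by
the decoder context (102 including BOS/EOS); over-length training
strings are dropped with a count rather than truncated, because a
truncated SMILES is not a molecule.

## Model

A Pre-LN encoder-decoder transformer over SMILES tokens. The "encoder"
is deliberately shallow: the conditioning matrix is projected per
residue by one fully connected layer to width `d` and given learned
encoder positional embeddings; no self-attention stack is applied on the
protein side, since the embeddings are already the output of a deep
network. Every decoder block applies causally masked self-attention,
then cross-attention over all `L` residue positions (unmasked), then a
position-wise feed-forward with GELU; layer normalization precedes each
sublayer and dropout is applied before the feed-forward. Positional
embeddings on both sides are learned. The reference configuration is
d=768, 16 blocks, 32 heads, contexts 1536/102, dropout 0.1, batch 96,
learning rate 9e-5; desk-scale runs use d=64, 2 blocks, 4 heads,
learning rate 3e-3.

Training is teacher-forced next-token prediction, mean NLL in nats per
token with padding masked out, Adam with global-norm clipping at 1.0 and
(by default) 5% linear warmup followed by cosine decay to zero — the
schedule is what lets small corpora be driven to the memorization floor;
a constant schedule is selectable. At initialization the output head is
small (σ = 0.01), so the initial loss sits at the uniform-guess floor
`ln V`.

Sampling is plain multinomial from the temperature-scaled distribution,
token by token from BOS until EOS or the 102-position context ends;
`temperature=0` switches to greedy argmax, negative temperatures are
rejected. No nucleus/top-k truncation by default: the simplest faithful
decoder, with the sampler reusable for alternatives.

Because no deep-learning framework is assumed, the model runs on a
small reverse-mode autodiff engine over NumPy (`autograd.py`) with
exactly the primitives a transformer needs; its gradients are verified
against central finite differences in float64 in the test suite.
Checkpoints bundle parameters, configuration and vocabulary in one
archive and reproduce eval-mode outputs bitwise.

## Synthetic fixtures

The generator plants the two structures the method needs, with no
attempt at realism beyond them:

- **Embeddings:** `K` family centroids in 384-dim space (per-coordinate
  spread = `family_separation` × the unit within-family std), per-target
  unit jitter, per-residue unit isotropic noise, the structure stream's
  noise correlated with the evoformer's at 0.5. `L` is uniform on
  `length_range`. At the default separation of 10, k-means on
  residue-averaged vectors recovers families with ARI ≥ 0.9; at
  separation 0 there is no structure — the quantitative stand-in for the
  qualitative observation that averaged embeddings cluster by family.
  Orthologues are simulated by duplicating a target with small noise and
  a changed species label.
- **Ligands:** one decoration template per family, each a distinct ring
  system with three substitution sites filled from a fixed set of
  acyclic substituents. Construction by grammar guarantees validity,
  guarantees every ligand shares its family's Murcko framework, and
  keeps molecules at ~30–44 tokens. Per-target counts follow a truncated
  Pareto (default exponent 2 on [10, 300], emulating the public-corpus
  skew where most targets have few ligands); pChEMBL is a two-component
  Gaussian mixture (means 6.3/7.6, sds 0.5/0.6, weights 0.45/0.55)
  clipped to [5.0, 9.5], so most ligands clear the 6.5 filter while a
  visible low-potency tail exists.

What passing tests on these fixtures shows: the formulas, contracts,
and the *mechanism* of conditioning (the model demonstrably routes
family information from the embedding to the chemistry). What it does
not show: performance on real AlphaFold embeddings or real bioactivity
data, whose noise structure, family overlap, and chemistry are far
richer.

## Desk-scale experiment sizes

The memorization run uses 20 targets (5 families × 4) with exactly 10
ligands each, proteins of 30–60 residues, and 200 epochs; with ~33
tokens per molecule the irreducible loss of a 10-molecules-per-target
corpus is ≈ ln(10)/33 ≈ 0.07 nats/token, and the run lands just above
it. The conditioning ablation trains 120 epochs per seed (family-level
conditioning saturates well before full memorization) and samples 12
molecules per target; with K = 5 balanced families the chance
family-match rate is 0.2, and the shuffled control is assessed against
binomial noise over the 20 targets. These sizes are the package's
default experimental conditions, chosen so every experiment runs in
minutes on one CPU.

## Numerical choices and edge cases

- Quota rounding: half-up, floored at `n_i`; all-zero weight vectors are
  a degenerate-input error; probability normalization is exact to 1e-12.
- Scaffold ranking: descending count, lexicographic tie-break; acyclic
  molecules (empty Murcko framework) are reported as their own bucket,
  never ranked — mixing them into the top-k would distort chemotype
  counts.
- Novelty is exact canonical-SMILES absence from the reference set, the
  unambiguous base definition.
- Invalid generated strings are flagged, excluded from similarity, and
  counted in the validity fraction; lenient decoding of sampled token
  sequences tolerates a missing EOS.
- Chemical-space projection (t-SNE/UMAP) is a presentation device, not
  an assertable computation; the clustering-quality test uses k-means +
  adjusted Rand index instead.
- pChEMBL is written to tables at 6 significant digits, making
  write → read → write a fixed point.

## Known limitations

- The count/weight formula forms are reconstructions constrained by
  documented behavior, not transcriptions of the original equations (see
  above); all downstream properties hold for the implemented forms.
- The NumPy model is single-process and CPU-bound; it is meant for
  desk-scale experiments (10⁵–10⁶ parameters), not the 10⁸-parameter
  reference configuration.
- The fixture chemistry is template-decoration chemistry: drug-like but
  narrow. Validity fractions near 1 on fixtures say nothing about
  validity on open-vocabulary corpora.
- No docking, QSAR scoring, or reinforcement-learning fine-tuning; the
  evaluation here is fingerprint-similarity- and scaffold-based.
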