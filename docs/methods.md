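# Methods

`rnacoding` models the protein-coding potential of RNA transcripts with an
encoder–decoder network and interprets the trained models through
mutation-effect prediction. This note records the model, its assumptions,
the tunable parameters, and the design decisions taken where the design was
genuinely open.

## Problem setting

Distinguishing mRNAs from long noncoding RNAs (lncRNAs) is a recurring step
in genome annotation. Rule-based classifiers lean on engineered features
(ORF length, k-mer composition, homology). Here the classifier is a
sequence-to-sequence network: given a transcript over {A,C,G,U}, it emits a
leading classification token (`<PC>` or `<NC>`) and, for coding calls, the
encoded protein. Forcing the model to learn translation acts as a
regularizer: to predict the protein it must locate a genuine ORF, implicitly
learning start-context, codon structure and reading-frame bookkeeping that a
classification-only objective is free to ignore.

## Architecture

**Encoder.** Nucleotides enter as one-hot rows multiplied by an embedding
matrix (this keeps input gradients well-defined for attribution), plus
sinusoidal position encodings. Two encoder families are provided behind one
interface:

* **Local filter layers** (the default): a short-time Fourier transform
  (periodic Hann window, hop = window/2) is taken along the sequence axis of
  the hidden representation, each frame is multiplied elementwise by a
  learned complex filter bank of shape (window/2+1 bins × hidden dims),
  soft-shrink sparsification is applied to the real and imaginary parts, and
  the inverse transform (plain overlap-add) returns to the position domain;
  the input is added back as a residual. The periodic Hann window at
  half-window hop satisfies the constant-overlap-add identity exactly, so an
  identity filter reconstructs the input to machine precision. The layer's
  inductive bias is spectral: 3-nt codon periodicity lands on one frequency
  bin (window 54 → bin 18; the toy configs use window 18 → bin 6), so a
  single filter weight can amplify or suppress it. Each filter block is
  followed by a position-wise feed-forward residual block (GELU), with
  pre-layer-norm residuals throughout.
* **Residual dilated CNNs**: same-padded 1-D convolutions with optional
  dilation doubling per layer (receptive field 1+(k−1)(2^n−1)).

**Decoder.** A standard transformer decoder stack (causal self-attention,
encoder–decoder attention, feed-forward; sinusoidal positions) produces
next-token logits over {20 amino acids, `<PC>`, `<NC>`, start/end/pad}.
Class tokens are grammatically legal only at the first output position and
decoding enforces this.

**Pointer head.** For start-codon prediction a single linear layer projects
each encoder state to a scalar; a softmax over positions yields a
distribution whose cross-entropy against the true start index (the last
index for noncoding records) is the objective. p(coding) is read off as the
mass on all positions before the last.

All computation is pure-functional NumPy differentiated with `autograd`
(reverse mode), including through the rFFT/irFFT pair. There is no GPU path;
the package targets desk-scale experiments.

## Training objectives

Four tasks share the architecture:

* `seq` — class token + full protein, uniform per-position cross-entropy.
* `seq_wt` — the same targets weighted by a truncated discrete exponential
  pmf p(i, λ) = (1−e^(−λ)) e^(−λi) / (1−e^(−λN)). λ→0 recovers `seq`
  exactly; λ→∞ collapses onto the class token, recovering `class`. Default
  λ = 0.1 for the local-filter encoder and 0.05 for the CNN.
* `class` — cross-entropy on the class token only.
* `start` — pointer cross-entropy.

Batches are length-binned under a padded-token budget (default 9000 input
tokens) with optional gradient accumulation (default 8 steps); Adam with a
constant learning rate (default 3e-3). The best checkpoint by validation F1
is retained. Training is deterministic for a fixed seed on one device.

## Mutation-effect prediction

The score is S = l⟨PC⟩ − l⟨NC⟩, the classification logit difference at the
first decode position. ΔS(variant, wild-type) is estimated four ways:

* **ISM** — exact: rescore all 3L single-nucleotide variants (batched).
* **Taylor** — one gradient: ΔS(i, j→b) ≈ ∂S/∂x_ib − ∂S/∂x_ij.
* **Uniform-baseline IG** — path-averaged input gradients from the one-hot
  input toward uniform [.25,.25,.25,.25] rows, paired like Taylor.
* **MDIG** — per base b, integrated gradients toward the baseline
  X(b,β) = β·poly(b) + (1−β)·x (β ∈ (0,1], default 8 midpoint steps), with
  entries paired as IG_ib + IG_ij. β trades path realism against
  perturbation fidelity and is tuned on validation data by median
  per-transcript Pearson r with ISM (grid {0.05, 0.1, 0.25, 0.5, 1}).

**Sign conventions.** With IG defined with its displacement factor
(x−x′)·∮∇S, a minus-pairing of uniform-baseline attributions cannot reduce
to ISM even for a linear scorer (it yields 0.25·w_ib + 0.75·w_ij), whereas
the plus-pairing of poly(b)-baseline attributions reduces to ISM exactly at
β = 1. The uniform-baseline estimator therefore divides out the displacement
(pairs path-averaged gradients), the unique reading under which its
minus-pairing is exact in the linear limit; MDIG keeps the factor and the
plus sign. `sign_convention_diagnostic` reports which pairing correlates
better with ISM on a given model rather than hiding the ambiguity. On any
linear scorer, ISM = Taylor = uniform-IG = MDIG(β=1) entrywise — the oracle
equivalence asserted in the test suite.

Agreement metrics: Pearson r over flattened L×3 matrices; median per-position
cosine (scale-free); inter-replicate agreement = mean over unordered
replicate pairs; agreement with ISM = mean over matched (intra-replicate)
pairs. Zero-row cosine: two zero rows count as 1, one zero row as 0.

## Interpretation pipeline

* **Counterfactual importance**: position importance under ↑PC is the
  strongest ΔS push toward NC, clipped at zero (symmetric for ↑NC). Masking
  removes the ORF's start and stop codons and every position whose selected
  strongest substitution would create a premature in-frame stop.
* **Metagenes**: per-position series aligned at the start codon (mRNAs) or
  longest-ORF start (lncRNAs), averaged, with relative positions present in
  fewer than 70% of series dropped. Binned metagenes average |ΔS| over the
  three substitutions within 25 equal-width bins spanning the whole
  transcript (ORF boundary bins noted as metadata).
* **Motif windows**: per transcript × region (5'UTR/CDS/3'UTR, or
  upstream/longest-ORF/downstream), a 21-nt window centred on the unmasked
  importance maximum (ties → 5'-most). Windows clip to region bounds;
  regions shorter than 21 nt are skipped so external motif-tool inputs stay
  uniform. Control sets: (1) a uniformly drawn same-region window that does
  not overlap the primary; (2) the corresponding windows from the opposite
  class. Output is FASTA for STREME-style differential discovery (running
  STREME itself is out of scope).
* **Perturbation scans**: dinucleotide-preserving UTR shuffles (Euler-path
  walk on the dinucleotide multigraph, applied to UTRs > 25 nt), internal
  codon shuffles (start/stop fixed), the nine start-codon knockouts, and a
  nonsense scan scoring every substitution that creates a premature in-frame
  stop, binned by fifty codons (bin width configurable; the toy tests use
  ten).
* **Attention summaries**: encoder–decoder attention at the first decode
  step, per head/layer, fed through the metagene machinery.

## Synthetic data

The generator emulates the statistical structure the models must detect,
not any particular transcriptome. mRNAs = 5'UTR (~15%) + AUG-initiated CDS +
in-frame stop + 3'UTR (~20%); coding codons are drawn with a wobble-position
bias (codons ending in C favoured 4:1, ending in U disfavoured — a planted
signal that attribution analyses can recover); G is forced at +1 after the
start codon with probability 0.9 (Kozak-like context). lncRNAs are
composition-matched random sequences with matched lengths; any ORF longer
than 30 codons is broken by an in-frame stop substitution (cheaper than
rejection sampling and length-exact). Defaults: 500 per class, lengths
200–1000 nt (a 1200-nt length filter mirrors the modelling regime the
architecture targets). **Hard mode** plants a long ORF of uniform-random
codons with no start context inside each lncRNA, so ORF length alone stops
separating the classes — a longest-ORF threshold classifier scores >90%
accuracy on the default world and near chance on hard mode.

What the generator does *not* emulate: homology structure between records,
species mixtures, non-AUG initiation, UTR regulatory elements, and realistic
codon autocorrelation. A green qualitative test therefore establishes that
the implementation reproduces an effect *given its planted cause*, not that
the effect would appear in biological data.

## Numerical and scaling choices

* Toy experiment scale: transcripts of 80–240 nt, hidden dim 32, one
  encoder/decoder layer (~20k parameters), sequence targets truncated to a
  20-aa prefix for `seq_wt` training (λ = 0.1 leaves < 14% relative weight
  beyond position 20, so the truncation discards near-zero-weight
  supervision). Task-specific epoch budgets (classification converges in
  ~20 epochs; the position-weighted task needs ~35 because its class-token
  gradient carries ~10% of the loss weight) mirror the per-task tuning the
  full-scale method prescribes.
* STFT edges: the signal is padded with half a window of zeros in front and
  enough zeros behind to complete the frames; this keeps the overlap-add
  identity exact at both boundaries (final-frame padding alone cannot
  reconstruct position 0 under a Hann window).
* Soft-shrink acts on real and imaginary parts independently (acting on the
  magnitude is the documented alternative; flip in `apply_filter`).
* Beam search: length-normalised score raw/len^α, α = 0.6 default; grammar
  enforced (class token first, none later). Alignment-based CDS detection
  uses Needleman–Wunsch global alignment (match 1 / mismatch 0 / gap −1
  defaults; identity = matches / alignment length).
* MCC numerator is TP·TN − FP·FN with a zero-denominator convention of 0.
* Degenerate inputs: empty FASTA → empty list; transcripts with no ORF get
  an empty perturbation result with a reason, and an all-covering "upstream"
  region.

## Known limitations

* autograd on one CPU bounds practical scale to a few thousand short
  transcripts; the package demonstrates and tests method behaviour rather
  than reproducing full-scale benchmark numbers.
* The qualitative orderings (translation task ≥ classification task on
  hard-mode data; tuned MDIG ≥ Taylor; negative start-knockout and early
  nonsense effects) are stochastic properties asserted on a majority of
  three seeds, not point estimates.
* The pointer ("start") task treats the last position as the noncoding
  target; a dedicated "no start" slot one past the end is the untested
  alternative.
* Inter-replicate analyses operate on externally supplied replicate
  matrices; no multi-replicate training orchestration beyond a seed list is
  provided.
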