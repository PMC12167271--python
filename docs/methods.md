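# Methods

## The adaptation model

The package assumes a frozen multimodal encoder pair: an image encoder and a
text encoder mapping into $\mathbb{R}^d$ spaces that are semantically
organized but mutually displaced (the modality gap). Adaptation proceeds in
two trained components:

**Alignment map.** A feed-forward network $f_{\text{MLP}}$ with input width
$d_{\text{image}}$, two hidden layers of 128 rectifier units, and a linear
output of width $d_{\text{text}}$ (widths adapt when the two embedding
dimensionalities differ; the hidden widths stay 128). It is trained on the
$K$ anchor pairs only, minimizing the mean squared error taken **over pairs**
— the squared Euclidean norm is kept whole rather than additionally averaged
over dimensions, i.e. $\frac1K\sum_i\lVert\hat v_i - v_i\rVert^2$. The norm
could also be read as dimension-averaged; the per-pair reading is implemented
and only rescales the loss surface (and effectively the learning rate) by a
constant. All $K$ anchors are training data; no validation split is held
out, because $K$ is tiny by design and the map is evaluated downstream.

**Decoder.** A word-level tokenizer, a linear prefix mapper from
$d_{\text{text}}$ to $P=8$ prefix vectors of model width, and a causal
transformer language model (default 2 layers, 4 heads, width 128, learned
positional embeddings, pre-layer-norm blocks, untied output head). Training
consumes only text: each target text is encoded, mapped to a prefix, and the
model is trained to emit `BOS … text … EOS` with summed token cross-entropy.
The conditioning mechanism (linear map to a short prefix prepended to the
token sequence) follows the text-only captioning lineage; the architecture
is a deliberately small from-scratch backbone so the package carries no
pretrained-weight dependency, and any object implementing the same
`forward` / `loss_and_grad` / `embed_tokens` surface can be substituted.
Whether a pretrained backbone should be fully fine-tuned or only its prefix
mapper trained is left to that substitution; the tiny backbone trains
end-to-end.

All networks are implemented in numpy with hand-derived reverse-mode
gradients, verified against central finite differences in the test suite.
Parameters are float32 end-to-end so that serialized artifacts reproduce
outputs bit-for-bit after a round trip.

## Defaults

| Component | Setting | Default | Note |
|---|---|---|---|
| Alignment | optimizer / lr / epochs / batch | Adam / 0.001 / 15 / 16 | the standard alignment recipe |
| Alignment | hidden widths | 128, 128 | rectifier activations |
| Decoder | optimizer / epochs / batch | AdamW / 10 / 34 | weight decay 0.01 |
| Decoder | learning rate | 3e-4 (from-scratch) | 2e-5 when a pretrained backbone is substituted |
| Decoder | prefix length $P$ | 8 | linear prefix conditioning |
| Decoder | architecture preset | tiny: 2 layers, 4 heads, width 128 | `mini` (1×2×64) for quick tests |
| Decoding | strategy | greedy | deterministic; seeded sampling available |
| Anchors | k-means | k-means++ init, 10 restarts, seeded | lowest-inertia solution kept |
| Anchors | FPS start | dataset medoid | deterministic, seed-free |
| Anchors | distance | Euclidean on raw embeddings | optional per-row L2 flag, off by default |

## Synthetic corpora

`ftda.synth` generates the paired corpora every experiment runs on. The toy
text encoder hashes each token to a fixed random unit vector and returns the
normalized token-vector sum — deterministic, unit-norm, with distinct labels
well separated. A corpus is built as:

* per-task text embeddings $t_i = s\,\mathrm{enc}(\text{text}_i)$, where
  $s$ (default 10) sets the class-center separation;
* an image latent $z_i$ equal to the sum of the sample's per-task text
  embeddings (for a single-task corpus, $z_i = t_i$); caption texts are a
  deterministic template of the sample's (phase, triplet) pair, so $z_i$ is
  determined by the class assignment;
* the image embedding $v_i = Q\,(z_i + \varepsilon_i) + c$ with a seeded
  random orthogonal $Q$, isotropic noise $\varepsilon_i \sim \mathcal N(0,
  \sigma^2 I)$ (default $\sigma=0.3$), and a constant offset with
  $\lVert c\rVert = 5$ by default.

The **standard fixture** is 700 train / 300 test samples at $d=32$ with 7
cholecystectomy phases (balanced to ±1 sample), 12 triplets from 3×2×2
instrument/verb/target vocabularies in the `instrument,verb,target` comma
form, and 50 templated captions; rotation on, seed 0. These problem sizes
keep every study — including the five-seed anchor-count trend — at desk
scale.

What the generator emulates: clustered image embeddings whose paired text
embeddings live in a rotated, offset region of the same space — the geometry
the alignment stage assumes. What it does **not** emulate: the anisotropic,
heavy-tailed statistics of real foundation-model embeddings, label noise,
class imbalance beyond ±1, temporal correlation between video frames, or
open-vocabulary caption diversity (captions are deterministic templates of
the class pair). Passing tests therefore demonstrate the mechanics and the
qualitative behavior of the method — alignment closes the gap, the encoder
swap works, more anchors help, skipping alignment collapses — not absolute
performance on real surgical data.

## Numerical conventions and edge cases

* **Tokenizer.** Whitespace word tokenization. Exact encode→decode
  round-tripping (asserted for every training text) is only possible when
  detokenization is trivial, so texts are kept single-space canonical;
  splitting punctuation would break round-tripping for free-form spacing.
  Triplet labels are single tokens under this scheme, which keeps closed-
  vocabulary reconstruction exactly measurable.
* **Ties.** Nearest-to-centroid and FPS ties break toward the lowest row
  index; duplicate centroid assignments take the next-nearest unused row.
* **Retrieval recall@1** is tie-aware: an image scores a hit when its own
  pair is *a* nearest text row. Classification corpora repeat identical
  text embeddings, so exact ties are the norm.
* **Invalid generations** (strings matching no label after lowercasing,
  trimming and whitespace collapsing) are retained and reported as a rate;
  they count as wrong for accuracy/recall and as a reserved invalid class
  for precision. Macro-F1 is the unweighted mean of per-class F1 (not the F1
  of macro precision/recall — the two differ).
* **BLEU** is corpus-level modified n-gram precision with brevity penalty
  and a 1e-9 floor on zero clipped counts. **CIDEr-D** uses tf-idf n-gram
  cosines ($n\le4$, idf from the reference corpus, candidate counts clipped
  at reference counts, Gaussian length penalty $\sigma=6$, ×10); single
  reference per item throughout.
* **Degenerate inputs.** K-means anchoring refuses all-identical rows for
  $K>1$; CIDEr refuses corpora smaller than 2 (idf undefined); texts longer
  than the decoder's `max_length` raise an explicit truncation error rather
  than being cut silently; empty corpora raise rather than returning empty
  metrics.
* **Projection.** Gap visualization uses principal components of the stacked
  $2n\times d$ matrix — deterministic, unlike stochastic neighbor methods.

## Reference experiments

`ftda.experiments` bundles the canonical studies (the test suite and
`scripts/acceptance.py` execute exactly these):

* **FPS oracle equivalence** on 200 random instances ($n\le12$, $d\le3$)
  against an independent brute-force greedy implementation.
* **K-means coverage** of 7 isotropic blobs with centers ≥ 20σ apart.
* **Affine-gap recovery** at $d=16$, $K=200$, noiseless: the map is trained
  to convergence for this probe (300 epochs at the standard lr/batch, a few
  seconds) because the question is what the estimator can recover, not how
  far the 15-epoch default gets; the closed-form least-squares fit, which
  interpolates exactly on noiseless data, is computed alongside as the
  reference. Package defaults are unchanged, and all fixture studies below
  use them as-is.
* **Anchor-count trend** on the standard fixture over 5 seeds: held-out
  alignment MSE and end-task phase accuracy at K=100 vs K=500 vs the
  explicit identity-map (no-anchor) baseline, plus the decoder's
  label-reconstruction rate.
* **Multi-task parity**: one decoder trained on the concatenated phase and
  triplet texts (concatenated as-is, unbalanced — the phase and triplet
  corpora are the same size here so balancing is moot) versus task-specific
  decoders, routed only by alignment maps.
* **Metric fixtures**: 200-instance agreement with a brute-force
  confusion-matrix oracle, the closed-form BLEU brevity-penalty example, and
  the CIDEr identity corpus.

## Known limitations

* The tiny decoder memorizes closed vocabularies; it is not a language model
  in any generative sense, and captioning quality on open text is untested
  by design.
* Alignment quality degrades gracefully with fewer anchors but the package
  makes no attempt at coreset methods beyond k-means exemplars and FPS.
* Per-frame inference only; no temporal smoothing across a video.
* The no-anchor baseline requires $d_{\text{image}} = d_{\text{text}}$
  (identity map); rectangular no-anchor runs are not defined.
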