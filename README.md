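# ftda — few-shot text-driven adaptation of multimodal encoders

Surgical workflow analysis (phase recognition, instrument–verb–target triplet
recognition, image captioning) normally needs large annotated image–label
datasets. `ftda` implements an adaptation strategy for frozen multimodal
foundation encoders that needs only a **handful of paired samples**: all
supervision beyond a few hundred "data anchors" comes from text alone, and
every downstream task — discriminative or generative — is solved as text
generation.

The pipeline has four stages:

1. **Anchor selection.** From the unlabeled image-embedding cloud
   $V_{\text{image}}^i \in \mathbb{R}^d$, select $K$ representative rows by
   k-means exemplars (the row nearest each centroid) or farthest-point
   sampling (greedily maximizing the minimum distance to the selected set).
2. **Modality alignment.** Contrastively pretrained encoders leave a
   *modality gap*: image and text embeddings form displaced clouds, so
   semantically dissimilar images sit closer to each other than to their own
   captions. A small feed-forward map $f_{\text{MLP}}$ (two hidden layers of
   128 rectifier units) is fit on the $K$ anchor pairs by minimizing

   $$\frac{1}{K}\sum_{i=1}^{K}\left\lVert f_{\text{MLP}}(v_{\text{image}}^{i};\theta) - v_{\text{text}}^{i}\right\rVert_2^2 .$$

3. **Text-only decoder training.** An autoregressive decoder
   $f_{\text{decoder}}$ is trained to reconstruct each target text $T$ from
   its frozen text embedding via a learned prefix, minimizing the summed
   token cross-entropy $\mathcal{L} = \sum_{T\in\mathcal{T}} \ell(\hat T, T)$.
   No image is ever seen in this stage.
4. **Encoder swap.** At inference the text encoder is replaced by the image
   encoder: an image embedding is passed through $f_{\text{MLP}}$ and the
   aligned result drives $f_{\text{decoder}}$, which emits a phase name, a
   triplet, or a caption. Multiple tasks share one decoder; routing is done
   purely by choosing the task's alignment map.

No pretrained weights or datasets are downloaded anywhere: the package ships
a synthetic corpus generator with a controllable modality gap (orthogonal
rotation + constant offset + isotropic noise over clustered embeddings) and a
deterministic toy text encoder, so the full pipeline is testable at desk
scale. The decoder backbone is a from-scratch tiny causal transformer
(numpy, hand-derived gradients, finite-difference-verified); a pretrained
language model can be substituted through the same interface.

## Worked example

`examples/05_encoder_swap.py` runs the full pipeline on the standard
synthetic fixture (700 train / 300 test samples, d=32, 7 surgical phases,
K=500 k-means anchors) and prints:

```
anchored (K=500)     accuracy 1.000  macro-F1 1.000  invalid-output rate 0.000
no-anchor baseline   accuracy 0.007  macro-F1 0.011  invalid-output rate 0.977
```

The decoder was trained on phase-label text only. With alignment, every test
image generates a string inside the 7-label vocabulary and classification is
perfect on this fixture; skipping alignment (the explicit identity-map
baseline) leaves 97.7% of generations outside the vocabulary and accuracy at
chance level — the modality gap, made visible. The other scripts in
`examples/` walk through each stage: corpus simulation, anchor selection,
gap diagnostics (`gap_metrics` reports mean paired distance, centroid
distance, and tie-aware retrieval recall@1, plus a deterministic
principal-component projection for plotting), text-only decoder training,
multi-task routing, and captioning metrics (BLEU@1/@4, CIDEr-D).

A YAML-configured end-to-end run is also available from the shell:

```bash
ftda run --cfg run.yaml          # simulate -> anchors -> align -> decoder -> infer -> evaluate
ftda gap --corpus DIR --map map/ --out-report gap.json --out-fig gap.png
```

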