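"""Simulate a paired image/text corpus with a controllable modality gap.

Builds a small clustered corpus, measures the gap between the image cloud and
the phase-label text embeddings, and shows how the offset/rotation knobs move
that gap.
"""

from ftda import SynthConfig, gap_metrics, simulate_corpus, text_embeddings
from ftda.synth import corpus_encoder

for offset, rotation in ((0.0, False), (5.0, False), (5.0, True)):
    cfg = SynthConfig(n=300, d=32, seed=0, tasks=("phase",),
                      separation=10.0, sigma=0.3,
                      offset_norm=offset, rotation=rotation)
    corpus, truth = simulate_corpus(cfg)
    txt = text_embeddings(corpus, "phase", corpus_encoder(cfg))
    rep = gap_metrics(corpus.image_embeddings, txt)
    print(f"offset {offset:>4.1f}  rotation {str(rotation):5s}  "
          f"mean paired distance {rep.mean_paired_distance:7.3f}  "
          f"retrieval R@1 {rep.recall_at_1:.3f}")

print("\nMean paired distance is the average image-to-paired-text Euclidean")
print("distance; R@1 is how often an image's nearest text embedding is its")
print("own pair. Turning on the offset and rotation opens a modality gap that")
print("collapses cross-modal retrieval, exactly the failure the alignment")
print("stage exists to fix.")
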