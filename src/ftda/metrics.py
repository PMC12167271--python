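"""Task evaluation: macro-averaged classification metrics and captioning
metrics (BLEU@1/@4 and CIDEr-D).

Conventions, spelled out because implementations differ:

* macro-F1 is the unweighted mean of per-class F1 scores (not the F1 of the
  macro precision/recall);
* classes never predicted receive precision 0;
* an invalid prediction (None, i.e. the generated text matched no label)
  counts as wrong for its reference class and is booked under a reserved
  invalid class for precision purposes;
* captioning assumes a single reference per candidate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .errors import ValidationError

__all__ = ["EvalReport", "classification_metrics", "captioning_metrics",
           "bleu", "cider"]

INVALID_CLASS = "<invalid>"
_BLEU_EPS = 1e-9
_CIDER_SIGMA = 6.0


@dataclass
class EvalReport:
    """Metric bundle for one task."""

    task: str
    accuracy: Optional[float] = None
    macro_precision: Optional[float] = None
    macro_recall: Optional[float] = None
    macro_f1: Optional[float] = None
    invalid_rate: Optional[float] = None
    per_class: Optional[pd.DataFrame] = None
    bleu1: Optional[float] = None
    bleu4: Optional[float] = None
    cider: Optional[float] = None

    def to_dict(self) -> dict:
        out = {"task": self.task}
        for key in ("accuracy", "macro_precision", "macro_recall", "macro_f1",
                    "invalid_rate", "bleu1", "bleu4", "cider"):
            val = getattr(self, key)
            if val is not None:
                out[key] = float(val)
        if self.per_class is not None:
            out["per_class"] = self.per_class.to_dict(orient="records")
        return out


def classification_metrics(preds: Sequence[Optional[str]],
                           refs: Sequence[str],
                           label_set: Sequence[str],
                           task: str = "") -> EvalReport:
    """Per-class one-vs-rest precision/recall/F1 over ``label_set``.

    ``preds`` entries may be None (invalid generation); macro averages are
    unweighted means over ``label_set`` only, and accuracy is the exact-match
    rate.
    """
    preds = list(preds)
    refs = [str(r) for r in refs]
    if len(preds) != len(refs):
        raise ValidationError(
            f"length mismatch: {len(preds)} predictions vs {len(refs)} references")
    labels = [str(x) for x in label_set]
    if not labels:
        raise ValidationError("label_set must be non-empty")
    bad = set(refs) - set(labels)
    if bad:
        raise ValidationError(f"references outside label_set: {sorted(bad)[:5]}")

    y_pred = [INVALID_CLASS if p is None else str(p) for p in preds]
    prec, rec, f1, support = precision_recall_fscore_support(
        refs, y_pred, labels=labels, zero_division=0)
    per_class = pd.DataFrame({
        "label": labels, "precision": prec, "recall": rec, "f1": f1,
        "support": support,
    })
    accuracy = float(np.mean([p == r for p, r in zip(y_pred, refs)])) if refs else 0.0
    return EvalReport(
        task=task,
        accuracy=accuracy,
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        invalid_rate=float(np.mean([p is None for p in preds])),
        per_class=per_class,
    )


# ---------------------------------------------------------------------------
# Captioning metrics
# ---------------------------------------------------------------------------

def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1))


def bleu(candidates: Sequence[str], references: Sequence[str],
         max_n: int = 4) -> float:
    """Corpus-level BLEU with brevity penalty, single reference per candidate.

    Modified n-gram precisions for orders 1..``max_n`` are combined by a
    geometric mean; zero clipped counts are floored at 1e-9 so a single
    missing order does not zero the score.
    """
    cands = [str(c).split() for c in candidates]
    refs = [str(r).split() for r in references]
    if not cands:
        raise ValidationError("candidate list must be non-empty")
    if len(cands) != len(refs):
        raise ValidationError(
            f"length mismatch: {len(cands)} candidates vs {len(refs)} references")
    if max_n not in (1, 2, 3, 4):
        raise ValidationError("max_n must be in 1..4")

    log_precisions = []
    for n in range(1, max_n + 1):
        clipped = 0
        total = 0
        for c, r in zip(cands, refs):
            cc = _ngrams(c, n)
            rc = _ngrams(r, n)
            clipped += sum(min(cnt, rc[g]) for g, cnt in cc.items())
            total += max(len(c) - n + 1, 0)
        if total == 0:
            log_precisions.append(np.log(_BLEU_EPS))
        else:
            log_precisions.append(np.log(max(clipped, _BLEU_EPS) / total))
    c_len = sum(len(c) for c in cands)
    r_len = sum(len(r) for r in refs)
    if c_len == 0:
        return 0.0
    brevity = 1.0 if c_len > r_len else float(np.exp(1.0 - r_len / c_len))
    return float(brevity * np.exp(np.mean(log_precisions)))


def _tfidf(counts: Counter, idf: dict) -> dict:
    return {g: cnt * idf.get(g, 0.0) for g, cnt in counts.items()}


def _norm(vec: dict) -> float:
    return float(np.sqrt(sum(v * v for v in vec.values())))


def cider(candidates: Sequence[str], references: Sequence[str]) -> float:
    """CIDEr-D on a single-reference corpus; scores lie in [0, 10].

    tf-idf vectors over n-grams n=1..4 with document frequencies from the
    reference corpus, candidate counts clipped at the reference counts in the
    numerator, a Gaussian length penalty (sigma=6), averaged over n and scaled
    by 10.
    """
    cands = [str(c).split() for c in candidates]
    refs = [str(r).split() for r in references]
    if len(cands) != len(refs):
        raise ValidationError(
            f"length mismatch: {len(cands)} candidates vs {len(refs)} references")
    N = len(refs)
    if N < 2:
        raise ValidationError(
            "CIDEr needs a corpus of >= 2 items (idf is degenerate otherwise)")

    scores = np.zeros(N)
    for n in range(1, 5):
        ref_counts = [_ngrams(r, n) for r in refs]
        cand_counts = [_ngrams(c, n) for c in cands]
        df = Counter()
        for rc in ref_counts:
            df.update(set(rc))
        idf = {g: np.log(N / d) for g, d in df.items()}
        for i, (cc, rc) in enumerate(zip(cand_counts, ref_counts)):
            g_c = _tfidf(cc, idf)
            g_r = _tfidf(rc, idf)
            nc, nr = _norm(g_c), _norm(g_r)
            if nc == 0.0 or nr == 0.0:
                continue
            # numerator clips the candidate *count* at the reference count
            dot = sum(min(cc[g], rc[g]) * idf.get(g, 0.0) ** 2 * rc[g]
                      for g in cc if g in rc)
            delta = len(cands[i]) - len(refs[i])
            penalty = np.exp(-(delta ** 2) / (2.0 * _CIDER_SIGMA ** 2))
            scores[i] += 10.0 * penalty * dot / (nc * nr)
    return float(np.mean(scores / 4.0))


def captioning_metrics(candidates: Sequence[str], references: Sequence[str],
                       task: str = "") -> EvalReport:
    """BLEU@1, BLEU@4 and CIDEr-D bundled into an :class:`EvalReport`."""
    return EvalReport(task=task,
                      bleu1=bleu(candidates, references, max_n=1),
                      bleu4=bleu(candidates, references, max_n=4),
                      cider=cider(candidates, references))
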