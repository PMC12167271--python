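"""End-to-end pipeline: simulate -> anchors -> align -> decoder -> infer -> evaluate.

A :class:`RunConfig` (YAML on disk, validated by pydantic with unknown keys
rejected) fully determines a run; the config is echoed into every output
directory and a manifest of artifact paths and checksums is written at the
end, so each artifact directory records exactly what produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError as PydanticValidationError

from . import io as ftda_io
from .align import AlignmentMap, AlignTrainConfig, fit_alignment
from .anchors import fps_anchors, gather_anchor_pairs, kmeans_anchors
from .decoder import DecoderTrainConfig, train_decoder
from .errors import ConfigurationError, FtdaError, PipelineError
from .infer import TaskSpec, multitask_predict
from .metrics import captioning_metrics, classification_metrics
from .synth import SynthConfig, corpus_encoder, simulate_corpus

log = logging.getLogger("ftda")

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


class _Stage(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthStage(_Stage):
    n_train: int = 700
    n_test: int = 300
    d: int = 32
    tasks: List[str] = ["phase"]
    k_phases: int = 7
    n_instruments: int = 3
    n_verbs: int = 2
    n_targets: int = 2
    separation: float = 10.0
    sigma: float = 0.3
    offset_norm: float = 5.0
    rotation: bool = True


class AnchorStage(_Stage):
    method: Literal["kmeans", "fps"] = "kmeans"
    k: int = 100
    start_index: Optional[int] = None


class AlignStage(_Stage):
    identity: bool = False  # explicit no-anchor baseline flag
    lr: float = 0.001
    epochs: int = 15
    batch_size: int = 16


class DecoderStage(_Stage):
    lr: Optional[float] = None
    epochs: int = 10
    batch_size: int = 34
    prefix_len: int = 8
    preset: str = "tiny"
    max_length: int = 32


class RunConfig(_Stage):
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "ftda-run"
    tasks: List[str] = ["phase"]
    synth: SynthStage = SynthStage()
    anchors: Optional[AnchorStage] = AnchorStage()
    align: Optional[AlignStage] = None
    decoder: DecoderStage = DecoderStage()
    log_level: str = "INFO"


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    try:
        return RunConfig(**raw)
    except PydanticValidationError as exc:
        raise ConfigurationError(f"invalid run config {path}: {exc}") from exc


def _echo_config(cfg: RunConfig, *dirs) -> None:
    text = yaml.safe_dump(json.loads(cfg.model_dump_json()), sort_keys=True)
    for d in dirs:
        d = Path(d)
        if d.is_dir():
            (d / "config.yaml").write_text(text, encoding="utf-8")


def _checksum_tree(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except FtdaError:
                raise
            except Exception as exc:  # noqa: BLE001 - halt with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config) -> dict:
    """Execute all stages from a :class:`RunConfig` (or YAML path).

    Returns ``{task: EvalReport}`` and leaves artifacts (corpora, anchors,
    alignment maps, decoder, predictions, reports, manifest) under
    ``config.outdir``.  A stage failure halts the run with the stage name;
    partial outputs are retained.
    """
    cfg = config if isinstance(config, RunConfig) else load_run_config(config)
    if cfg.align is None:
        raise ConfigurationError(
            "no 'align' stage configured; either configure alignment training "
            "or set align.identity: true for an explicit no-anchor baseline")
    if not cfg.tasks:
        raise ConfigurationError("at least one task must be configured")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _echo_config(cfg, out)

    # --- simulate ---------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        scfg = SynthConfig(
            n=cfg.synth.n_train, d=cfg.synth.d, seed=cfg.seed,
            tasks=tuple(cfg.synth.tasks), k_phases=cfg.synth.k_phases,
            n_instruments=cfg.synth.n_instruments, n_verbs=cfg.synth.n_verbs,
            n_targets=cfg.synth.n_targets, separation=cfg.synth.separation,
            sigma=cfg.synth.sigma, offset_norm=cfg.synth.offset_norm,
            rotation=cfg.synth.rotation)
        train, truth_tr = simulate_corpus(scfg, sample_seed=cfg.seed * 1000 + 1,
                                          id_prefix="tr")
        tcfg = SynthConfig(**{**scfg.__dict__, "n": cfg.synth.n_test})
        test, truth_te = simulate_corpus(tcfg, sample_seed=cfg.seed * 1000 + 2,
                                         id_prefix="te")
        ftda_io.write_corpus(train, out / "corpus_train")
        ftda_io.write_corpus(test, out / "corpus_test")
        truth_tr.to_csv(out / "corpus_train" / "truth.tsv", sep="\t", index=False)
        truth_te.to_csv(out / "corpus_test" / "truth.tsv", sep="\t", index=False)
        return train, test, corpus_encoder(scfg)

    missing = [t for t in cfg.tasks if t not in cfg.synth.tasks]
    if missing:
        raise ConfigurationError(
            f"tasks {missing} are not generated by the synth stage {cfg.synth.tasks}")
    train, test, encoder = _simulate()
    log.info("simulated %d train / %d test samples", train.n, test.n)

    # --- anchors ----------------------------------------------------------
    @_stage("anchors")
    def _anchors():
        if cfg.anchors.method == "kmeans":
            return kmeans_anchors(train.image_embeddings, cfg.anchors.k,
                                  seed=cfg.seed)
        return fps_anchors(train.image_embeddings, cfg.anchors.k,
                           start_index=cfg.anchors.start_index)

    anchors = None
    if not cfg.align.identity:
        if cfg.anchors is None:
            raise ConfigurationError(
                "alignment training requires an 'anchors' stage "
                "(or align.identity: true)")
        anchors = _anchors()
        ftda_io.write_anchors(anchors, out / "anchors.json")
        log.info("selected %d anchors via %s", anchors.K, anchors.method)

    # --- align (one map per task) ----------------------------------------
    @_stage("align")
    def _align(task):
        if cfg.align.identity:
            return AlignmentMap.identity(train.image_embeddings.d)
        img_rows, txt_rows = gather_anchor_pairs(train, anchors, task, encoder)
        acfg = AlignTrainConfig(lr=cfg.align.lr, epochs=cfg.align.epochs,
                                batch_size=cfg.align.batch_size, seed=cfg.seed)
        amap = fit_alignment(img_rows, txt_rows, acfg)
        log.info("aligned task %s: train MSE %.4f -> %.4f", task,
                 amap.meta["initial_loss"], amap.meta["final_loss"])
        return amap

    maps = {}
    for task in cfg.tasks:
        maps[task] = _align(task)
        ftda_io.save_model(maps[task], out / f"map_{task}")

    # --- decoder (joint over all configured tasks) ------------------------
    @_stage("train-decoder")
    def _decoder():
        joint_texts = [t for task in cfg.tasks for t in train.texts[task]]
        dcfg = DecoderTrainConfig(
            lr=cfg.decoder.lr, epochs=cfg.decoder.epochs,
            batch_size=cfg.decoder.batch_size, seed=cfg.seed,
            prefix_len=cfg.decoder.prefix_len, preset=cfg.decoder.preset,
            max_length=cfg.decoder.max_length)
        return train_decoder(joint_texts, encoder, dcfg)

    model = _decoder()
    ftda_io.save_model(model, out / "decoder")
    log.info("decoder trained; final loss %.2f", model.meta["loss_history"][-1])

    # --- infer + evaluate -------------------------------------------------
    @_stage("infer")
    def _infer():
        specs = [TaskSpec(name=task, type=train.tasks[task].type,
                          label_set=train.tasks[task].label_set,
                          alignment=maps[task])
                 for task in cfg.tasks]
        return multitask_predict(test.image_embeddings, specs, model)

    predictions = _infer()
    reports = {}

    @_stage("evaluate")
    def _evaluate(task):
        preds = predictions[task]
        with open(out / f"preds_{task}.tsv", "w", encoding="utf-8") as fh:
            fh.write("id\traw_text\tmatched_label\n")
            for p in preds:
                fh.write(f"{p.id}\t{p.text}\t{p.label if p.label else ''}\n")
        refs = list(test.texts[task])
        if test.tasks[task].type == "classification":
            rep = classification_metrics([p.label for p in preds], refs,
                                         test.tasks[task].label_set, task=task)
        else:
            rep = captioning_metrics([p.text for p in preds], refs, task=task)
        (out / f"report_{task}.json").write_text(
            json.dumps(rep.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8")
        return rep

    for task in cfg.tasks:
        reports[task] = _evaluate(task)
        if reports[task].accuracy is not None:
            log.info("task %s: accuracy %.3f macro-F1 %.3f", task,
                     reports[task].accuracy, reports[task].macro_f1)

    # --- manifest ---------------------------------------------------------
    artifact_dirs = [out / "corpus_train", out / "corpus_test", out / "decoder"]
    artifact_dirs += [out / f"map_{t}" for t in cfg.tasks]
    _echo_config(cfg, *artifact_dirs)
    manifest = {
        "artifacts": {
            str(p.relative_to(out)): (_checksum_tree(p) if p.is_dir()
                                      else hashlib.sha256(p.read_bytes()).hexdigest())
            for p in sorted(out.iterdir())
            if p.name not in ("manifest.json",)
        },
        "seed": cfg.seed,
        "tasks": cfg.tasks,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return reports
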