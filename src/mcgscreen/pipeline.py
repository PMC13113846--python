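"""End-to-end orchestration: simulate -> preprocess -> encode -> train
-> fuse -> evaluate, with reproducible on-disk artifacts.

Every stage function both returns its result and (when given an output
directory) writes an artifact embedding the configuration snapshot and
seed that produced it, so a run can be audited afterwards.  The
evaluation stage refuses to score subjects that were seen in training
(the subject-level leakage guard).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .embedding import EmbeddingParams, delay_embed, select_epsilon
from .encoders import gasf, mtf, recurrence_plot, to_image
from .errors import InvalidInputError
from .fusion import fuse_probabilities, grid_search_weight
from .metrics import metrics_report
from .model import CompactCNN, TrainConfig, predict_proba, train
from .preprocess import (
    FilterSpec,
    bandpass_filter,
    detect_beats,
    notch_filter,
    segment_cycles,
    split_subjects,
    zscore_normalize,
)

__all__ = ["PipelineConfig", "preprocess_cohort", "encode_cycles", "run_experiment"]

MODALITIES = ("rp", "gasf", "mtf")


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their printed defaults."""

    seed: int = 42
    # synthetic cohort
    n_healthy: int = 20
    n_ischemic: int = 20
    cycles_per_subject: int = 20
    fs: float = 1000.0
    noise: synthetic.NoiseSpec = field(default_factory=synthetic.NoiseSpec)
    # preprocessing
    filter: FilterSpec = field(default_factory=FilterSpec)
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    # phase-space encoding
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    mtf_q: int = 8
    # classifier and fusion
    train: TrainConfig = field(default_factory=TrainConfig)
    grid_step: float = 0.05
    threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise InvalidInputError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                setattr(cfg, key, dataclasses.replace(current, **value))
            elif key == "fractions":
                setattr(cfg, key, tuple(value))
            else:
                setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.snapshot(), f, sort_keys=False)

    def snapshot(self) -> dict:
        snap = asdict(self)
        snap["fractions"] = list(self.fractions)
        return snap


def _meta(config: PipelineConfig, inputs: dict[str, str] | None = None) -> dict:
    return {"config": config.snapshot(), "seed": config.seed, "inputs": inputs or {}}


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def preprocess_cohort(cohort, config: PipelineConfig):
    """Filter, normalize, detect beats and segment every recording.

    Returns a list of CardiacCycle; recordings where no beats are found
    are skipped.
    """
    cycles = []
    for rec in cohort:
        x = bandpass_filter(rec.samples, rec.fs, config.filter)
        x = notch_filter(x, rec.fs, config.filter.notch_freq, config.filter.notch_q)
        x = zscore_normalize(x)
        peaks = detect_beats(x, rec.fs)
        if peaks.size < 2:
            continue
        cycles.extend(
            segment_cycles(x, rec.fs, peaks, subject_id=rec.subject_id, label=rec.label)
        )
    return cycles


def encode_cycles(cycles, modality: str, config: PipelineConfig) -> np.ndarray:
    """Encode each cycle into a 224x224 float32 image plane."""
    modality = modality.lower()
    if modality not in MODALITIES:
        raise InvalidInputError(f"modality must be one of {MODALITIES}")
    emb = config.embedding
    planes = np.empty((len(cycles), 224, 224), dtype=np.float32)
    for k, cyc in enumerate(cycles):
        if modality == "rp":
            traj = delay_embed(cyc.x, emb.m, emb.tau)
            eps = emb.epsilon if emb.epsilon is not None else select_epsilon(
                traj, emb.recurrence_rate
            )
            matrix = recurrence_plot(traj, eps)
        elif modality == "gasf":
            matrix = gasf(cyc.x)
        else:
            matrix = mtf(cyc.x, config.mtf_q)
        planes[k] = to_image(matrix, modality.upper()).pixels[:, :, 0]
    return planes


def _split_arrays(cycles, split):
    """Index cycles by partition; returns dict partition -> (indices, labels, subjects)."""
    out = {}
    for part in ("train", "val", "test"):
        idx = [k for k, c in enumerate(cycles) if split[c.subject_id] == part]
        labels = np.array([cycles[k].label for k in idx], dtype=int)
        subjects = {cycles[k].subject_id for k in idx}
        out[part] = (np.array(idx, dtype=int), labels, subjects)
    return out


def run_experiment(
    config: PipelineConfig | None = None,
    modalities: tuple[str, ...] = ("rp", "gasf"),
    outdir: str | Path | None = None,
) -> dict:
    """Run the full synthetic experiment and return a results dict.

    Stages: generate the cohort, preprocess into cycles, split at
    subject level, encode the requested modalities, train one compact
    CNN per modality with best-validation-AUC selection, grid-search the
    fusion weight on the validation set, and evaluate single-modality
    and fused predictions on the held-out test subjects.
    """
    config = config if config is not None else PipelineConfig()
    cohort = synthetic.generate_cohort(
        config.n_healthy,
        config.n_ischemic,
        config.cycles_per_subject,
        config.fs,
        config.noise,
        config.seed,
    )
    cycles = preprocess_cohort(cohort, config)
    subjects = sorted({(c.subject_id, c.label) for c in cycles})
    split = split_subjects(subjects, config.fractions, config.seed)
    parts = _split_arrays(cycles, split)
    (itr, ytr, str_), (iva, yva, sva), (ite, yte, ste) = (
        parts["train"],
        parts["val"],
        parts["test"],
    )
    if str_ & ste or str_ & sva:
        raise InvalidInputError("leakage guard: subject assigned to multiple partitions")

    results: dict = {
        "n_cycles": len(cycles),
        "n_subjects": len(subjects),
        "split_sizes": {p: int(len(parts[p][0])) for p in parts},
        "modalities": {},
    }
    test_probs = {}
    val_probs = {}
    for modality in modalities:
        planes = encode_cycles(cycles, modality, config)
        net = CompactCNN(num_classes=2, seed=config.train.seed)
        net, history = train(net, planes[itr], ytr, planes[iva], yva, config.train)
        p_val = predict_proba(net, planes[iva])
        p_test = predict_proba(net, planes[ite])
        val_probs[modality], test_probs[modality] = p_val, p_test
        report = metrics_report(p_test, yte, config.threshold)
        results["modalities"][modality] = {
            "test_auc": report.auc,
            "report": report.as_dict(),
            "best_val_auc": max(h["val_auc"] for h in history),
            "history": history,
        }
        del planes

    if "rp" in modalities and "gasf" in modalities:
        w, val_auc, table = grid_search_weight(
            val_probs["rp"], val_probs["gasf"], yva, config.grid_step
        )
        fused_test = fuse_probabilities(test_probs["rp"], test_probs["gasf"], w)
        fused_report = metrics_report(fused_test, yte, config.threshold)
        results["fusion"] = {
            "weight": w,
            "val_auc": val_auc,
            "grid": table,
            "test_auc": fused_report.auc,
            "report": fused_report.as_dict(),
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = {"meta": _meta(config), "results": results}
        with open(outdir / "experiment.json", "w") as f:
            json.dump(payload, f, indent=2, default=float)
    return results
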