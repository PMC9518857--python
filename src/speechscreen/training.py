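"""Participant-level splitting, early-stopped SGD training, PSO fitness,
and the end-to-end experiment runner."""

from __future__ import annotations

import csv
import math
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .audio_io import ParticipantRecord, read_manifest, read_wav
from .mfcc import (
    ExtractionParams,
    FeatureDataset,
    extract_mfcc,
    segment_mfcc,
    write_feature_json,
)
from .model import BiLSTMAttentionModel, ModelSpec, build_model, save_model
from .pso import HyperparameterSpace, optimize, write_trace_csv
from .synth import CONTROL_PROFILE, POSITIVE_PROFILE, ClassProfile, CohortSpec, generate_cohort
from .evaluation import EvaluationReport, evaluate_model, write_report

__all__ = [
    "SplitAssignment",
    "TrainingConfig",
    "TrainingHistory",
    "split_participants",
    "extract_features",
    "train_model",
    "pso_fitness",
    "run_experiment",
    "ExperimentResult",
]

PARTITIONS = ("train", "validation", "test")


@dataclass
class SplitAssignment:
    """Disjoint participant -> partition map covering the whole manifest."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0

    def participants(self, partition: str) -> set[str]:
        if partition not in PARTITIONS:
            raise ValueError(f"unknown partition {partition!r}")
        return {pid for pid, p in self.assignment.items() if p == partition}

    def sizes(self) -> dict[str, int]:
        return {p: len(self.participants(p)) for p in PARTITIONS}


@dataclass
class TrainingConfig:
    """Training hyperparameters; defaults follow the tuned values of the
    reference configuration (learning rate 1e-4, batch 128, 89 epochs,
    momentum 0.9)."""

    learning_rate: float = 0.0001
    batch_size: int = 128
    max_epochs: int = 89
    momentum: float = 0.9
    early_stop_patience: int | None = 10
    early_stop_metric: str = "val_loss"

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0  # 1-based

    def write_csv(self, path: str | os.PathLike) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_loss"])
            for e, (tr, vl) in enumerate(zip(self.train_loss, self.val_loss), start=1):
                writer.writerow([e, repr(tr), repr(vl)])
        return path


# ---------------------------------------------------------------------------
# Participant-level splitting
# ---------------------------------------------------------------------------

def _hamilton(total: int, fractions) -> list[int]:
    # largest-remainder apportionment of `total` across the fractions
    ideal = [total * f for f in fractions]
    counts = [math.floor(v) for v in ideal]
    remainder = total - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(ideal[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_participants(
    manifest: list[ParticipantRecord],
    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20),
    seed: int = 0,
) -> SplitAssignment:
    """Stratified random participant partition at nearest-integer fractions.

    Partition totals are the nearest-integer targets on the full cohort
    (46 participants -> 28/9/9); within that constraint members of each
    class are apportioned proportionally by largest remainder. If a class is
    too small to stratify (< 3 members) the split falls back to an
    unstratified random partition with a warning.
    """
    n = len(manifest)
    if n < 5:
        raise ValueError("need at least 5 participants to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = {r.participant_id: r.label for r in manifest}
    by_class: dict[int, list[str]] = {}
    for r in manifest:
        by_class.setdefault(r.label, []).append(r.participant_id)
    if len(by_class) < 2:
        raise ValueError("both classes must be present in the manifest")

    targets = [int(round(n * fractions[0])), int(round(n * fractions[1]))]
    targets.append(n - sum(targets))
    rng = np.random.default_rng(seed)

    if min(len(v) for v in by_class.values()) < 3:
        warnings.warn(
            "a class has fewer than 3 participants; falling back to an "
            "unstratified split", stacklevel=2,
        )
        pids = [r.participant_id for r in manifest]
        order = list(rng.permutation(pids))
        assignment = {}
        start = 0
        for part, size in zip(PARTITIONS, targets):
            for pid in order[start:start + size]:
                assignment[pid] = part
            start += size
        return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)

    # per-class quotas, then reconcile with the global partition targets
    quotas = {c: _hamilton(len(members), fractions) for c, members in by_class.items()}
    class_sizes = {c: len(m) for c, m in by_class.items()}
    for _ in range(3 * n):
        sums = [sum(q[p] for q in quotas.values()) for p in range(3)]
        over = [p for p in range(3) if sums[p] > targets[p]]
        under = [p for p in range(3) if sums[p] < targets[p]]
        if not over:
            break
        p, q = over[0], under[0]
        donor = max(
            (c for c in quotas if quotas[c][p] > 0),
            key=lambda c: quotas[c][p] - class_sizes[c] * fractions[p],
        )
        quotas[donor][p] -= 1
        quotas[donor][q] += 1

    # best effort: no partition empty of a class (feasible when n_c >= 3)
    for c in quotas:
        for p in range(3):
            if quotas[c][p] == 0:
                src = max(range(3), key=lambda r: quotas[c][r])
                others = [c2 for c2 in quotas if c2 != c and quotas[c2][p] >= 2]
                if quotas[c][src] >= 2 and others:
                    c2 = others[0]
                    quotas[c][src] -= 1
                    quotas[c][p] += 1
                    quotas[c2][p] -= 1
                    quotas[c2][src] += 1

    assignment: dict[str, str] = {}
    for c, members in sorted(by_class.items()):
        order = list(rng.permutation(members))
        start = 0
        for part, size in zip(PARTITIONS, quotas[c]):
            for pid in order[start:start + size]:
                assignment[pid] = part
            start += size
    assert len(assignment) == n
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)


# ---------------------------------------------------------------------------
# Feature extraction over a manifest
# ---------------------------------------------------------------------------

def extract_features(
    manifest: list[ParticipantRecord],
    params: ExtractionParams | None = None,
    label_names: tuple[str, str] = ("control", "mtbi"),
) -> FeatureDataset:
    """Read every clip, extract MFCCs, and segment into the dataset."""
    params = params or ExtractionParams()
    segments = []
    for rec in manifest:
        clip = read_wav(rec.clip_path)
        mat = extract_mfcc(clip, params)
        segments.extend(
            segment_mfcc(mat, params.frames_per_segment, rec.label, rec.participant_id)
        )
    if not segments:
        raise ValueError("no clip produced a single full segment; "
                         "reduce frames_per_segment or use longer clips")
    return FeatureDataset(
        segments=segments, label_names=list(label_names), extraction_params=params
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _partition_arrays(dataset: FeatureDataset, pids: set[str]):
    segs = [s for s in dataset.segments if s.participant_id in pids]
    if not segs:
        raise ValueError("partition holds no segments")
    X = np.stack([s.features for s in segs])
    y = np.array([s.label for s in segs], dtype=np.int64)
    return X, y


def train_model(
    model: BiLSTMAttentionModel,
    dataset: FeatureDataset,
    split: SplitAssignment,
    cfg: TrainingConfig | None = None,
    seed: int = 0,
) -> tuple[BiLSTMAttentionModel, TrainingHistory]:
    """SGD-with-momentum training with early stopping on validation loss.

    Features are standardised per coefficient using training-partition
    statistics only (stored on the model). Epoch losses are recorded in
    inference mode so they are invariant to batch order and dropout draws.
    The weights from the best validation epoch are restored before
    returning; no test-partition segment is ever touched.
    """
    cfg = cfg or TrainingConfig()
    train_pids = split.participants("train")
    val_pids = split.participants("validation")
    test_pids = split.participants("test")
    # leakage guard: the partition map must be disjoint by construction,
    # and training must never see validation/test participants
    assert not (train_pids & test_pids) and not (val_pids & test_pids)
    Xtr, ytr = _partition_arrays(dataset, train_pids)
    Xvl, yvl = _partition_arrays(dataset, val_pids)

    mean = Xtr.mean(axis=(0, 1))
    std = np.maximum(Xtr.std(axis=(0, 1)), 1e-8)
    model.set_normalizer(mean, std)

    params = model.parameters()
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    rng = np.random.default_rng(seed)
    history = TrainingHistory()
    best_val = math.inf
    best_weights = model.get_weights()
    stale = 0

    n_train = Xtr.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n_train)
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads = model.loss_and_grads(Xtr[idx], ytr[idx], rng=rng)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={cfg.learning_rate}, batch={len(idx)})"
                )
            for k, g in grads.items():
                velocity[k] = cfg.momentum * velocity[k] - cfg.learning_rate * g
                params[k] += velocity[k]
        train_loss = model.evaluate_loss(Xtr, ytr)
        val_loss = model.evaluate_loss(Xvl, yvl)
        if not (math.isfinite(train_loss) and math.isfinite(val_loss)):
            raise RuntimeError(f"non-finite epoch loss at epoch {epoch}")
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.stopped_epoch = epoch
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if cfg.early_stop_patience is not None and stale > cfg.early_stop_patience:
                break
    model.set_weights(best_weights)
    return model, history


def pso_fitness(
    assignment: dict,
    dataset: FeatureDataset,
    split: SplitAssignment,
    base_spec: ModelSpec,
    base_cfg: TrainingConfig | None = None,
    seed: int = 0,
    max_epochs: int | None = None,
) -> float:
    """Train under a candidate hyperparameter assignment; return the best
    validation loss. Failures (including non-finite losses) return +inf so
    the swarm survives bad regions."""
    base_cfg = base_cfg or TrainingConfig()
    spec_overrides = {k: v for k, v in assignment.items() if hasattr(base_spec, k)}
    cfg_overrides = {k: v for k, v in assignment.items() if hasattr(base_cfg, k)}
    unknown = set(assignment) - set(spec_overrides) - set(cfg_overrides)
    if unknown:
        raise ValueError(f"unknown hyperparameters {sorted(unknown)}")
    try:
        spec = replace(base_spec, **spec_overrides)
        cfg = replace(base_cfg, **cfg_overrides)
        if max_epochs is not None:
            cfg = replace(cfg, max_epochs=max_epochs)
        model = build_model(spec, seed=seed)
        _, history = train_model(model, dataset, split, cfg, seed=seed)
        best = min(history.val_loss)
        return best if math.isfinite(best) else math.inf
    except (RuntimeError, FloatingPointError, ValueError):
        return math.inf


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    model: BiLSTMAttentionModel
    history: TrainingHistory
    report: EvaluationReport
    dataset: FeatureDataset
    split: SplitAssignment
    best_assignment: dict | None
    paths: dict[str, Path]


def _profile_from_config(d: dict | None, default: ClassProfile) -> ClassProfile:
    return replace(default, **(d or {}))


def run_experiment(config: dict, seed: int, out_dir: str | os.PathLike) -> ExperimentResult:
    """Generate (optional) -> extract -> split -> PSO (optional) -> train ->
    evaluate, writing every artifact into ``out_dir``.

    Reproducible end to end from ``seed``; stage sub-seeds are fixed offsets
    of it. See :mod:`speechscreen.config` for the config schema.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cohort_cfg = config.get("cohort", {})
    if cohort_cfg.get("enabled", True):
        spec = CohortSpec(
            n_participants=cohort_cfg.get("n_participants", 46),
            prevalence=cohort_cfg.get("prevalence", 7 / 46),
            effect_size=cohort_cfg.get("effect_size", 1.0),
            clip_duration_s=cohort_cfg.get("clip_duration_s", 10.0),
            sample_rate=cohort_cfg.get("sample_rate", 44100),
            seed=seed,
        )
        control = _profile_from_config(cohort_cfg.get("control_profile"), CONTROL_PROFILE)
        positive = _profile_from_config(cohort_cfg.get("positive_profile"), POSITIVE_PROFILE)
        manifest, manifest_path = generate_cohort(spec, out_dir / "audio", control, positive)
        paths["manifest"] = manifest_path
    else:
        manifest_path = Path(config["data"]["manifest"])
        manifest = read_manifest(manifest_path)
        paths["manifest"] = manifest_path

    extraction = ExtractionParams(**config.get("extraction", {}))
    dataset = extract_features(manifest, extraction)
    paths["features"] = write_feature_json(dataset, out_dir / "features.json")

    split_cfg = config.get("split", {})
    fractions = tuple(split_cfg.get("fractions", (0.60, 0.20, 0.20)))
    split = split_participants(manifest, fractions, seed=seed + 1)

    model_cfg = dict(config.get("model", {}))
    unit_scale = model_cfg.pop("unit_scale", 1.0)
    base_spec = ModelSpec(
        frames_per_segment=extraction.frames_per_segment,
        n_features=extraction.n_mfcc,
        **model_cfg,
    )
    if unit_scale != 1.0:
        base_spec = base_spec.scaled(unit_scale)

    train_cfg = TrainingConfig(**config.get("training", {}))

    best_assignment = None
    pso_cfg = config.get("pso", {})
    if pso_cfg.get("enabled", False):
        space = HyperparameterSpace(list(pso_cfg["space"].items()))
        fitness = lambda a: pso_fitness(
            a, dataset, split, base_spec, train_cfg,
            seed=seed + 2, max_epochs=pso_cfg.get("epochs_per_eval", 5),
        )
        best_assignment, _, trace = optimize(
            space,
            fitness,
            n_particles=pso_cfg.get("particles", 15),
            max_iterations=pso_cfg.get("iterations", 30),
            seed=seed + 3,
            patience=pso_cfg.get("patience", 10),
        )
        paths["pso_trace"] = write_trace_csv(trace, out_dir / "pso_trace.csv")
        base_spec = replace(
            base_spec, **{k: v for k, v in best_assignment.items() if hasattr(base_spec, k)}
        )
        train_cfg = replace(
            train_cfg, **{k: v for k, v in best_assignment.items() if hasattr(train_cfg, k)}
        )

    model = build_model(base_spec, seed=seed + 4)
    model, history = train_model(model, dataset, split, train_cfg, seed=seed + 5)
    paths["history"] = history.write_csv(out_dir / "history.csv")
    paths["checkpoint"] = save_model(model, out_dir / "model.npz")

    eval_cfg = config.get("evaluation", {})
    report = evaluate_model(
        model,
        dataset,
        participant_ids=split.participants("test"),
        granularity=eval_cfg.get("granularity", "segment"),
        threshold=eval_cfg.get("threshold", 0.5),
    )
    paths.update(write_report(report, out_dir))

    import yaml

    resolved = dict(config)
    resolved["seed"] = seed
    with open(out_dir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh)
    paths["config"] = out_dir / "resolved_config.yaml"

    return ExperimentResult(
        model=model,
        history=history,
        report=report,
        dataset=dataset,
        split=split,
        best_assignment=best_assignment,
        paths=paths,
    )
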