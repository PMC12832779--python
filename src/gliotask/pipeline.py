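"""Training and evaluation orchestration.

Covers the full loop on phantom cohorts: augmentation, stratified splitting,
optimization of the mismatch block + adapter-injected encoder + task heads
under the uncertainty-weighted joint loss, metric computation with bootstrap
confidence intervals, and Grad-CAM explanation.

Ablation axes are plain configuration switches: ``bypass_mfeb`` (raw T2-FLAIR
subtraction), ``use_adapters=False`` (plain backbone), and ``tasks`` limited
to a single head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.stats import rankdata

from . import nn
from .nn import Tensor
from .encoder import Encoder, EncoderConfig
from .losses import (LossConfig, TaskHeads, UncertaintyWeights, TASKS,
                     alpha_from_labels, task_losses)
from .mfeb import MismatchExtractor
from .phantom import MODALITIES, PhantomSubject

T2_IDX = MODALITIES.index("t2")
FLAIR_IDX = MODALITIES.index("flair")


# -- configuration ----------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    rotate: bool = True
    flip: bool = True
    noise: bool = True
    intensity: bool = True
    shift: bool = True
    noise_sd: float = 0.05
    max_shift_fraction: float = 0.1

    @property
    def any_on(self) -> bool:
        return self.rotate or self.flip or self.noise or self.intensity or self.shift


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-5
    batch_size: int = 4
    epochs: int = 10
    seed: int = 0
    optimizer: str = "ranger"  # ranger | radam | adam
    schedule: str = "cosine"  # cosine | constant
    train_fraction: float = 0.8
    val_fraction: float = 0.15  # of the training split
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    mfeb_width: int = 8
    mfeb_dropout: float = 0.1
    bypass_mfeb: bool = False
    use_adapters: bool = True
    tasks: str = "both"  # both | idh | grade

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.tasks not in ("both", "idh", "grade"):
            raise ValueError(f"unknown tasks setting {self.tasks!r}")
        if self.optimizer not in ("ranger", "radam", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @property
    def active_tasks(self) -> tuple[str, ...]:
        return TASKS if self.tasks == "both" else (self.tasks,)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "TrainConfig":
        raw = dict(raw)
        if "augment" in raw and isinstance(raw["augment"], dict):
            raw["augment"] = AugmentConfig(**raw["augment"])
        if "loss" in raw and isinstance(raw["loss"], dict):
            raw["loss"] = LossConfig(**raw["loss"])
        if "encoder" in raw and isinstance(raw["encoder"], dict):
            raw["encoder"] = EncoderConfig(**raw["encoder"])
        return cls(**raw)


# -- model ------------------------------------------------------------------

class MultiTaskModel(nn.Module):
    """Mismatch extraction + 5-channel adapter-injected encoder + task heads."""

    def __init__(self, cfg: TrainConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.mfeb = MismatchExtractor(width=cfg.mfeb_width,
                                      dropout_rate=cfg.mfeb_dropout, rng=rng)
        self.encoder = Encoder(cfg.encoder, rng=rng)
        self.heads = TaskHeads(cfg.encoder.embed_dim, rng)
        self.uncertainty = UncertaintyWeights(n_tasks=2)

    def mismatch(self, volumes: Tensor) -> Tensor:
        t2 = volumes[:, T2_IDX:T2_IDX + 1]
        flair = volumes[:, FLAIR_IDX:FLAIR_IDX + 1]
        return self.mfeb(t2, flair, bypass=self.cfg.bypass_mfeb)

    def features(self, volumes: Tensor, tabular: Tensor,
                 capture: list | None = None) -> Tensor:
        if not isinstance(volumes, Tensor):
            volumes = Tensor(volumes)
        if not isinstance(tabular, Tensor):
            tabular = Tensor(tabular)
        x_tf = self.mismatch(volumes)
        x5 = nn.concatenate([volumes, x_tf], axis=1)
        return self.encoder(x5, tabular, use_adapters=self.cfg.use_adapters,
                            capture=capture)

    def forward(self, volumes, tabular) -> dict[str, Tensor]:
        return self.heads(self.features(volumes, tabular))


# -- augmentation -----------------------------------------------------------

def augment(volumes: np.ndarray, mask: np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Randomly transform a (C, D, H, W) stack and its mask.

    Geometric operations (90-degree rotations, flips, integer shifts) are
    applied congruently to volumes and mask; intensity operations (noise,
    scale/offset) touch the volumes only.
    """
    vols = volumes.copy()
    msk = mask.copy()
    if cfg.rotate:
        axes = [(1, 2), (1, 3), (2, 3)][rng.integers(3)]
        k = int(rng.integers(4))
        vols = np.rot90(vols, k=k, axes=axes)
        msk = np.rot90(msk, k=k, axes=(axes[0] - 1, axes[1] - 1))
    if cfg.flip:
        for ax in (1, 2, 3):
            if rng.random() < 0.5:
                vols = np.flip(vols, axis=ax)
                msk = np.flip(msk, axis=ax - 1)
    if cfg.shift:
        max_shift = max(1, int(cfg.max_shift_fraction * volumes.shape[-1]))
        shifts = rng.integers(-max_shift, max_shift + 1, size=3)
        vols = _integer_shift(vols, shifts, spatial_offset=1)
        msk = _integer_shift(msk[None], shifts, spatial_offset=1)[0]
    if cfg.noise:
        vols = vols + rng.normal(0.0, cfg.noise_sd, size=vols.shape)
    if cfg.intensity:
        scale = rng.uniform(0.9, 1.1)
        offset = rng.uniform(-0.1, 0.1)
        vols = vols * scale + offset
    return np.ascontiguousarray(vols), np.ascontiguousarray(msk)


def _integer_shift(arr: np.ndarray, shifts, spatial_offset: int) -> np.ndarray:
    out = np.zeros_like(arr)
    src, dst = [slice(None)] * arr.ndim, [slice(None)] * arr.ndim
    for i, s in enumerate(shifts):
        ax = i + spatial_offset
        n = arr.shape[ax]
        s = int(s)
        if abs(s) >= n:
            return out
        if s >= 0:
            dst[ax], src[ax] = slice(s, n), slice(0, n - s)
        else:
            dst[ax], src[ax] = slice(0, n + s), slice(-s, n)
    out[tuple(dst)] = arr[tuple(src)]
    return out


# -- splitting --------------------------------------------------------------

@dataclass
class Split:
    train: list[int]
    val: list[int]
    test: list[int]


def stratified_split(subjects: list[PhantomSubject], cfg: TrainConfig,
                     rng: np.random.Generator) -> Split:
    """Split stratified jointly on (IDH, grade); 15% of train becomes val."""
    groups: dict[tuple[int, int], list[int]] = {}
    for i, s in enumerate(subjects):
        groups.setdefault((s.idh_label, s.grade_label), []).append(i)
    train, test = [], []
    for key in sorted(groups):
        idxs = np.array(groups[key])
        idxs = idxs[rng.permutation(len(idxs))]
        n_test = int(round(len(idxs) * (1 - cfg.train_fraction)))
        test.extend(idxs[:n_test].tolist())
        train.extend(idxs[n_test:].tolist())
    train = [train[i] for i in rng.permutation(len(train))]
    n_val = int(round(len(train) * cfg.val_fraction))
    val, train = train[:n_val], train[n_val:]
    for name, part in (("train", train), ("test", test)):
        for task in cfg.active_tasks:
            labels = {s for i in part
                      for s in [getattr(subjects[i], f"{task}_label")]}
            if len(labels) < 2:
                raise ValueError(
                    f"class absent from the {name} split for task {task!r}; "
                    f"use a larger cohort")
    return Split(train=sorted(train), val=sorted(val), test=sorted(test))


# -- training ---------------------------------------------------------------

@dataclass
class FeatureStats:
    mean: np.ndarray
    std: np.ndarray

    def transform(self, rows: np.ndarray) -> np.ndarray:
        std = np.where(self.std == 0, 1.0, self.std)
        return (rows - self.mean) / std


@dataclass
class TrainResult:
    model: MultiTaskModel
    split: Split
    stats: FeatureStats
    history: dict[str, list]
    best_state: dict[str, np.ndarray]
    config: TrainConfig


def _batch_arrays(subjects: list[PhantomSubject], idxs: list[int],
                  stats: FeatureStats) -> tuple[np.ndarray, np.ndarray, dict]:
    vols = np.stack([subjects[i].stacked() for i in idxs]).astype(np.float32)
    tab = stats.transform(
        np.stack([subjects[i].features for i in idxs])).astype(np.float32)
    labels = {
        "idh": np.array([subjects[i].idh_label for i in idxs]),
        "grade": np.array([subjects[i].grade_label for i in idxs]),
    }
    return vols, tab, labels


def _joint_objective(model: MultiTaskModel, losses: dict[str, Tensor],
                     cfg: TrainConfig) -> Tensor:
    active = cfg.active_tasks
    if len(active) == 2:
        return model.uncertainty([losses["idh"], losses["grade"]])
    return losses[active[0]]


def _forward_losses(model: MultiTaskModel, vols, tab, labels,
                    loss_cfgs) -> dict[str, Tensor]:
    probs = model(vols, tab)
    return task_losses(probs, labels, loss_cfgs)


def train(subjects: list[PhantomSubject], cfg: TrainConfig) -> TrainResult:
    """Train the multi-task model on a phantom cohort."""
    rng = np.random.default_rng(cfg.seed)
    split = stratified_split(subjects, cfg, rng)

    all_feats = np.stack([s.features for s in subjects])
    train_feats = all_feats[split.train]
    stats = FeatureStats(mean=train_feats.mean(axis=0),
                         std=train_feats.std(axis=0, ddof=0))

    # class-ratio alpha per task, from the training split only
    loss_cfgs = {}
    for task in TASKS:
        labels = np.array([getattr(subjects[i], f"{task}_label")
                           for i in split.train])
        alpha = alpha_from_labels(labels) if task in cfg.active_tasks else 1.0
        loss_cfgs[task] = replace(cfg.loss, alpha=alpha)

    model = MultiTaskModel(cfg, rng=np.random.default_rng(cfg.seed + 1))
    params = [p for p in model.parameters() if p.requires_grad]
    opt_cls = {"ranger": nn.Ranger, "radam": nn.RAdam, "adam": nn.Adam}[cfg.optimizer]
    opt = opt_cls(params, lr=cfg.learning_rate)

    n_train = len(split.train)
    steps_per_epoch = max(1, int(np.ceil(n_train / cfg.batch_size)))
    total_steps = steps_per_epoch * cfg.epochs
    aug_rng = np.random.default_rng(cfg.seed + 2)

    history = {"train_loss": [], "val_loss": [], "gammas": [],
               "task_losses": []}
    best_val, best_state = np.inf, model.state_dict()
    step = 0
    for epoch in range(cfg.epochs):
        model.train()
        order = list(np.array(split.train)[aug_rng.permutation(n_train)])
        epoch_losses = []
        for b0 in range(0, n_train, cfg.batch_size):
            idxs = order[b0:b0 + cfg.batch_size]
            vols, tab, labels = _batch_arrays(subjects, idxs, stats)
            if cfg.augment.any_on:
                for j in range(vols.shape[0]):
                    vols[j], _ = augment(vols[j],
                                         subjects[idxs[j]].roi_mask,
                                         cfg.augment, aug_rng)
            losses = _forward_losses(model, vols, tab, labels, loss_cfgs)
            objective = _joint_objective(model, losses, cfg)
            if cfg.schedule == "cosine":
                opt.lr = nn.cosine_lr(cfg.learning_rate, step, total_steps)
            opt.zero_grad()
            objective.backward()
            opt.step()
            step += 1
            epoch_losses.append(float(objective.data))
        val_loss = _validation_loss(model, subjects, split.val, stats,
                                    loss_cfgs, cfg)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["gammas"].append(model.uncertainty.gammas.tolist())
        # fall back to the train loss for model selection when val is empty
        selection = val_loss if np.isfinite(val_loss) else history["train_loss"][-1]
        if selection < best_val:
            best_val = selection
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return TrainResult(model=model, split=split, stats=stats, history=history,
                       best_state=best_state, config=cfg)


def _validation_loss(model, subjects, val_idx, stats, loss_cfgs,
                     cfg: TrainConfig) -> float:
    if not val_idx:
        return np.inf
    model.eval()
    vols, tab, labels = _batch_arrays(subjects, val_idx, stats)
    with nn.no_grad():
        losses = _forward_losses(model, vols, tab, labels, loss_cfgs)
        return float(_joint_objective(model, losses, cfg).data)


# -- checkpoint I/O ---------------------------------------------------------

def save_training_checkpoint(result: TrainResult, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = dict(result.model.state_dict())
    state["__stats_mean__"] = result.stats.mean
    state["__stats_std__"] = result.stats.std
    np.savez(path, **state)
    sidecar = {"config": asdict(result.config), "history": result.history,
               "split": asdict(result.split)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_training_checkpoint(path) -> tuple[MultiTaskModel, FeatureStats, dict]:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    cfg = TrainConfig.from_dict(sidecar["config"])
    with np.load(path, allow_pickle=False) as archive:
        state = {k: archive[k] for k in archive.files}
    stats = FeatureStats(mean=state.pop("__stats_mean__"),
                         std=state.pop("__stats_std__"))
    model = MultiTaskModel(cfg)
    model.load_state_dict(state)
    return model, stats, sidecar


# -- metrics ----------------------------------------------------------------

def accuracy_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    return (tp + tn) / (tp + tn + fp + fn)


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic (Mann-Whitney) AUC with tie correction."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for a single-class label vector")
    ranks = rankdata(scores)
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def confusion_counts(labels: np.ndarray, scores: np.ndarray,
                     threshold: float = 0.5) -> dict[str, int]:
    pred = (np.asarray(scores) >= threshold).astype(int)
    labels = np.asarray(labels)
    return {
        "tp": int(((pred == 1) & (labels == 1)).sum()),
        "tn": int(((pred == 0) & (labels == 0)).sum()),
        "fp": int(((pred == 1) & (labels == 0)).sum()),
        "fn": int(((pred == 0) & (labels == 1)).sum()),
    }


def _bootstrap_ci(stat_fn, labels, scores, n_boot: int, seed: int,
                  level: float = 0.95) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = len(labels)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lb, sc = labels[idx], scores[idx]
        try:
            vals.append(stat_fn(lb, sc))
        except ValueError:
            continue  # degenerate single-class resample
    lo = (1 - level) / 2
    return (float(np.quantile(vals, lo)), float(np.quantile(vals, 1 - lo)))


@dataclass
class TaskReport:
    auc: float | None
    auc_ci: tuple[float, float] | None
    acc: float
    acc_ci: tuple[float, float]
    f1: float
    f1_ci: tuple[float, float]
    counts: dict[str, int]


@dataclass
class EvalReport:
    tasks: dict[str, TaskReport]
    n_subjects: int

    def to_json(self) -> str:
        return json.dumps({
            "n_subjects": self.n_subjects,
            "tasks": {k: asdict(v) for k, v in self.tasks.items()},
        }, indent=2)


def predict_scores(model: MultiTaskModel, subjects: list[PhantomSubject],
                   idxs: list[int], stats: FeatureStats,
                   batch_size: int = 8) -> dict[str, np.ndarray]:
    """Positive-class probability per task for the given subjects."""
    model.eval()
    out = {task: [] for task in TASKS}
    for b0 in range(0, len(idxs), batch_size):
        chunk = idxs[b0:b0 + batch_size]
        vols, tab, _ = _batch_arrays(subjects, chunk, stats)
        with nn.no_grad():
            probs = model(vols, tab)
        for task in TASKS:
            out[task].append(probs[task].data[:, 1])
    return {task: np.concatenate(v) for task, v in out.items()}


def evaluate(model: MultiTaskModel, subjects: list[PhantomSubject],
             test_idx: list[int], stats: FeatureStats, n_boot: int = 2000,
             seed: int = 0) -> EvalReport:
    scores = predict_scores(model, subjects, test_idx, stats)
    reports = {}
    for t_i, task in enumerate(TASKS):
        labels = np.array([getattr(subjects[i], f"{task}_label")
                           for i in test_idx])
        sc = scores[task]
        counts = confusion_counts(labels, sc)
        acc = accuracy_from_counts(**counts)
        f1 = f1_from_counts(counts["tp"], counts["fp"], counts["fn"])
        boot_seed = seed + 1000 * t_i
        try:
            auc = auc_score(labels, sc)
            auc_ci = _bootstrap_ci(auc_score, labels, sc, n_boot, boot_seed)
        except ValueError:
            auc, auc_ci = None, None
        acc_ci = _bootstrap_ci(
            lambda l, s: accuracy_from_counts(**confusion_counts(l, s)),
            labels, sc, n_boot, boot_seed + 1)
        f1_ci = _bootstrap_ci(
            lambda l, s: (lambda c: f1_from_counts(c["tp"], c["fp"], c["fn"]))(
                confusion_counts(l, s)),
            labels, sc, n_boot, boot_seed + 2)
        reports[task] = TaskReport(auc=auc, auc_ci=auc_ci, acc=acc,
                                   acc_ci=acc_ci, f1=f1, f1_ci=f1_ci,
                                   counts=counts)
    return EvalReport(tasks=reports, n_subjects=len(test_idx))


# -- explanation ------------------------------------------------------------

def gradcam(model: MultiTaskModel, subject: PhantomSubject, stats: FeatureStats,
            task: str = "idh", target_class: int = 1,
            layer: int = -1) -> tuple[np.ndarray, bool]:
    """Grad-CAM attention volume for one subject.

    ``layer`` indexes the captured token grids (0 = patch embedding output,
    -1 = last transformer block). Returns (volume normalized to [0, 1] at
    input resolution, flag set when the map is identically zero).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    model.eval()
    vols = subject.stacked()[None].astype(np.float32)
    tab = stats.transform(subject.features[None]).astype(np.float32)
    capture: list[Tensor] = []
    x_tf = model.mismatch(Tensor(vols))
    x5 = nn.concatenate([Tensor(vols), x_tf], axis=1)
    feat = model.encoder(x5, Tensor(tab),
                         use_adapters=model.cfg.use_adapters, capture=capture)
    logits = model.heads.logits(feat)[task]
    target = logits[0, target_class]
    target.backward()

    act = capture[layer]
    grads = act.grad
    if grads is None:
        grads = np.zeros_like(act.data)
    g = model.cfg.encoder.grid
    weights = grads[0].mean(axis=0)  # (E,) GAP of gradients over tokens
    cam = np.maximum((act.data[0] * weights).sum(axis=-1), 0.0)
    cam = cam.reshape(g, g, g)
    flag_zero = not np.any(cam > 0)
    zoom = subject.roi_mask.shape[0] / g
    cam_full = ndimage.zoom(cam, zoom, order=1)
    cam_full = np.clip(cam_full, 0.0, None)
    if cam_full.max() > 0:
        cam_full = cam_full / cam_full.max()
    return cam_full, flag_zero
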