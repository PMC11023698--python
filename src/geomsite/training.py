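"""Masked multi-task training, cross-validation and threshold calibration.

One protein carries labels for the ligand tasks it is annotated with;
every other task is masked so it contributes neither loss nor gradient.
Epochs draw proteins uniformly with replacement, optimization is Adam
under a one-cycle learning-rate schedule on binary cross-entropy, models
are ensembled across cross-validation folds by averaging sigmoid
outputs, and per-task decision thresholds maximize MCC on pooled
out-of-fold predictions.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .evaluation import matthews_corrcoef, pr_auc, UndefinedMetricError
from .geometry import RBFConfig, featurize_structure
from .network import GPSiteModel, ModelConfig
from .residue_features import (EmbeddingProvider, NormalizationStats,
                               OneHotProvider, minmax_normalize,
                               structural_properties)
from .structure_io import ProteinStructure, build_radius_graph
from .synthetic import SyntheticDataset

logger = logging.getLogger("geomsite")


@dataclass
class TrainConfig:
    samples_per_epoch: int = 25000
    batch_size: int = 16
    max_epochs: int = 25
    patience: int = 4                 # early-stop epochs without val AUPR gain
    folds: int = 5
    lr_max: float = 1e-3
    weight_decay: float = 0.0
    warmup_frac: float = 0.3          # fraction of steps before the LR peak
    div_start: float = 25.0           # lr starts at lr_max / div_start
    div_final: float = 1e4            # lr ends at lr_max / div_final
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.samples_per_epoch, self.batch_size, self.max_epochs) < 1:
            raise ValueError("counts must be positive")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


def toy_train_config(**overrides) -> TrainConfig:
    """Desk-scale schedule used by the synthetic-data experiments."""
    defaults = dict(samples_per_epoch=640, batch_size=16, max_epochs=8,
                    patience=3, folds=5, lr_max=3e-3)
    defaults.update(overrides)
    return TrainConfig(**defaults)


# ---------------------------------------------------------------------------
# encoding: structure -> numeric graph sample
# ---------------------------------------------------------------------------

@dataclass
class EncodedProtein:
    """Featurized protein ready for batching; embedding kept raw so
    normalization statistics can be fitted on training folds only."""

    name: str
    node_geo: np.ndarray       # (n, Dg)
    props: np.ndarray          # (n, 9) RSA + SS8
    embedding: np.ndarray      # (n, De) raw provider output
    edge_feats: np.ndarray
    edge_index: np.ndarray
    labels: np.ndarray         # (n, T) with zeros under masked tasks
    task_mask: np.ndarray      # (T,) bool

    @property
    def n_residues(self) -> int:
        return self.node_geo.shape[0]

    def node_features(self, stats: NormalizationStats) -> np.ndarray:
        emb = minmax_normalize(self.embedding, stats)
        return np.concatenate([self.node_geo, emb, self.props], axis=1)


def encode_protein(structure: ProteinStructure, labels: np.ndarray,
                   task_mask: np.ndarray,
                   provider: EmbeddingProvider | None = None,
                   rbf: RBFConfig | None = None,
                   radius: float = 15.0,
                   name: str = "",
                   sasa_points: int = 240) -> EncodedProtein:
    provider = provider or OneHotProvider()
    graph = build_radius_graph(structure, radius=radius, self_loops=True)
    bundle = featurize_structure(structure, graph, rbf)
    props = structural_properties(structure, n_points=sasa_points)
    return EncodedProtein(
        name=name or "protein",
        node_geo=bundle.node_features,
        props=props.matrix,
        embedding=provider(structure.sequence),
        edge_feats=bundle.edge_features,
        edge_index=bundle.edge_index,
        labels=np.asarray(labels).reshape(structure.n_residues, -1),
        task_mask=np.asarray(task_mask, bool),
    )


def encode_synthetic_dataset(dataset: SyntheticDataset,
                             provider: EmbeddingProvider | None = None,
                             rbf: RBFConfig | None = None,
                             sasa_points: int = 240) -> list[EncodedProtein]:
    return [
        encode_protein(p.structure, p.label_matrix(), p.task_mask,
                       provider=provider, rbf=rbf, name=p.name,
                       sasa_points=sasa_points)
        for p in dataset.proteins
    ]


def fit_embedding_stats(proteins: list[EncodedProtein]) -> NormalizationStats:
    return NormalizationStats.fit(np.concatenate([p.embedding for p in proteins]))


def collate(proteins: list[EncodedProtein], stats: NormalizationStats):
    """Merge proteins into one disjoint graph with per-node protein ids."""
    node_feats, edge_feats, edge_index, labels, mask, pids = [], [], [], [], [], []
    offset = 0
    for pid, p in enumerate(proteins):
        node_feats.append(p.node_features(stats))
        edge_feats.append(p.edge_feats)
        edge_index.append(p.edge_index + offset)
        labels.append(p.labels)
        mask.append(np.broadcast_to(p.task_mask, p.labels.shape))
        pids.append(np.full(p.n_residues, pid))
        offset += p.n_residues
    return (np.concatenate(node_feats), np.concatenate(edge_feats),
            np.concatenate(edge_index), np.concatenate(labels).astype(float),
            np.concatenate(mask).astype(float), np.concatenate(pids))


# ---------------------------------------------------------------------------
# loss, sampling, schedule
# ---------------------------------------------------------------------------

def masked_multitask_loss(logits, labels, mask) -> ad.Tensor:
    """Mean BCE over (residue, task) cells whose task is annotated.

    ``mask`` may be a (T,) task mask or a full (n, T) cell mask; masked
    cells contribute exactly zero to the value and to every gradient.
    """
    labels = np.asarray(labels, float)
    mask = np.asarray(mask, float)
    if mask.ndim == 1:
        mask = np.broadcast_to(mask, labels.shape)
    if mask.sum() == 0:
        raise ValueError("every task is masked for this batch")
    return ad.masked_bce_with_logits(logits, labels, mask)


def epoch_sampler(dataset_size: int, k: int, seed: int) -> np.ndarray:
    """k uniform-with-replacement protein indices; reproducible under seed."""
    if dataset_size < 1:
        raise ValueError("empty dataset")
    return np.random.default_rng(seed).integers(0, dataset_size, size=k)


def one_cycle_lr(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Linear warmup to lr_max, cosine decay to lr_max / div_final."""
    peak = max(int(cfg.warmup_frac * total_steps), 1)
    if step <= peak:
        lo = cfg.lr_max / cfg.div_start
        return lo + (cfg.lr_max - lo) * step / peak
    frac = (step - peak) / max(total_steps - peak, 1)
    lo = cfg.lr_max / cfg.div_final
    return lo + (cfg.lr_max - lo) * 0.5 * (1 + np.cos(np.pi * min(frac, 1.0)))


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def predict_proteins(model, proteins: list[EncodedProtein],
                     stats: NormalizationStats) -> list[np.ndarray]:
    out = []
    for p in proteins:
        out.append(model.predict_proba(p.node_features(stats), p.edge_feats,
                                       p.edge_index))
    return out


def _validation_aupr(probs: list[np.ndarray],
                     proteins: list[EncodedProtein]) -> tuple[float, dict]:
    """Mean AUPR over tasks with at least one annotated positive."""
    n_tasks = proteins[0].labels.shape[1]
    per_task = {}
    for t in range(n_tasks):
        scores, labels = [], []
        for pr, p in zip(probs, proteins):
            if p.task_mask[t]:
                scores.append(pr[:, t])
                labels.append(p.labels[:, t])
        if not scores:
            continue
        s = np.concatenate(scores)
        y = np.concatenate(labels)
        try:
            per_task[t] = pr_auc(s, y)
        except UndefinedMetricError:
            logger.warning("task %d has no positives in validation; skipped", t)
    mean = float(np.mean(list(per_task.values()))) if per_task else float("nan")
    return mean, per_task


@dataclass
class FoldReport:
    fold: int
    val_aupr: float
    per_task_aupr: dict
    epochs_run: int
    history: list


def train_single(train_prots: list[EncodedProtein],
                 val_prots: list[EncodedProtein],
                 model_cfg: ModelConfig, cfg: TrainConfig,
                 fold: int = 0) -> tuple[GPSiteModel, NormalizationStats, FoldReport]:
    """Train one model with early stopping on mean validation AUPR."""
    stats = fit_embedding_stats(train_prots)
    model = GPSiteModel(model_cfg)
    opt = ad.Adam(model.parameters(), lr=cfg.lr_max, weight_decay=cfg.weight_decay)
    steps_per_epoch = int(np.ceil(cfg.samples_per_epoch / cfg.batch_size))
    total_steps = cfg.max_epochs * steps_per_epoch
    best = (-np.inf, None, None, 0)
    history = []
    step = 0
    stale = 0
    for epoch in range(cfg.max_epochs):
        draw = epoch_sampler(len(train_prots), cfg.samples_per_epoch,
                             seed=cfg.seed + 1009 * epoch + 7919 * fold)
        losses = []
        for b in range(steps_per_epoch):
            idx = draw[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            if len(idx) == 0:
                continue
            batch = [train_prots[i] for i in idx]
            nf, ef, ei, y, m, pid = collate(batch, stats)
            logits = model.forward(nf, ef, ei, pid, training=True)
            loss = masked_multitask_loss(logits, y, m)
            opt.zero_grad()
            loss.backward()
            step += 1
            opt.step(lr=one_cycle_lr(step, total_steps, cfg))
            losses.append(float(loss.data))
        val_probs = predict_proteins(model, val_prots, stats)
        val_aupr, per_task = _validation_aupr(val_probs, val_prots)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "val_aupr": val_aupr})
        logger.info("fold %d epoch %d loss %.4f val AUPR %.4f",
                    fold, epoch, np.mean(losses), val_aupr)
        if np.isfinite(val_aupr) and val_aupr > best[0]:
            best = (val_aupr, [p.data.copy() for p in model.parameters()],
                    per_task, epoch)
            stale = 0
        else:
            stale += 1
            if stale > cfg.patience:
                break
    if best[1] is not None:
        for p, data in zip(model.parameters(), best[1]):
            p.data = data
    report = FoldReport(fold=fold, val_aupr=best[0], per_task_aupr=best[2] or {},
                        epochs_run=len(history), history=history)
    return model, stats, report


def assign_folds(proteins: list[EncodedProtein], folds: int, seed: int) -> np.ndarray:
    """Protein-level fold ids, stratified by task-annotation pattern."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(proteins), dtype=int)
    groups: dict[tuple, list[int]] = {}
    for i, p in enumerate(proteins):
        groups.setdefault(tuple(p.task_mask.tolist()), []).append(i)
    counter = 0
    for key in sorted(groups):
        members = np.array(groups[key])
        rng.shuffle(members)
        for i in members:
            fold_of[i] = counter % folds
            counter += 1
    return fold_of


@dataclass
class CrossValResult:
    models: list
    stats: list
    reports: list
    fold_of: np.ndarray
    oof_probs: list            # out-of-fold probabilities per protein
    thresholds: np.ndarray     # (T,) max-MCC thresholds on pooled OOF scores

    def ensemble_stats(self) -> NormalizationStats:
        """Pooled normalization bounds for ensemble inference."""
        v_min = np.min([s.v_min for s in self.stats], axis=0)
        v_max = np.max([s.v_max for s in self.stats], axis=0)
        return NormalizationStats(v_min, v_max)


def crossval_train(proteins: list[EncodedProtein], model_cfg: ModelConfig,
                   cfg: TrainConfig) -> CrossValResult:
    """Five-fold (by default) cross-validation with protein-level splits.

    Each fold's model early-stops on its held-out fold; out-of-fold
    predictions are pooled to calibrate per-task max-MCC thresholds.
    """
    if len(proteins) < cfg.folds:
        raise ValueError("fewer proteins than folds")
    fold_of = assign_folds(proteins, cfg.folds, cfg.seed)
    models, stats_list, reports = [], [], []
    oof = [None] * len(proteins)
    for f in range(cfg.folds):
        train_idx = np.flatnonzero(fold_of != f)
        val_idx = np.flatnonzero(fold_of == f)
        model_cfg_f = dataclasses.replace(model_cfg, seed=model_cfg.seed + f)
        model, stats, report = train_single(
            [proteins[i] for i in train_idx], [proteins[i] for i in val_idx],
            model_cfg_f, cfg, fold=f)
        probs = predict_proteins(model, [proteins[i] for i in val_idx], stats)
        for i, pr in zip(val_idx, probs):
            oof[i] = pr
        models.append(model)
        stats_list.append(stats)
        reports.append(report)

    n_tasks = model_cfg.n_tasks
    thresholds = np.full(n_tasks, 0.5)
    for t in range(n_tasks):
        scores = [oof[i][:, t] for i, p in enumerate(proteins) if p.task_mask[t]]
        labels = [p.labels[:, t] for p in proteins if p.task_mask[t]]
        if scores:
            s, y = np.concatenate(scores), np.concatenate(labels)
            try:
                thresholds[t] = select_threshold_max_mcc(s, y)
            except UndefinedMetricError:
                logger.warning("task %d: single-class OOF labels; threshold 0.5", t)
    return CrossValResult(models=models, stats=stats_list, reports=reports,
                          fold_of=fold_of, oof_probs=oof, thresholds=thresholds)


def select_threshold_max_mcc(scores, labels) -> float:
    """Threshold maximizing MCC over midpoints of adjacent unique scores.

    Binarization downstream uses score >= threshold; ties in MCC resolve
    to the lowest threshold. A single unique score is its own candidate.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise UndefinedMetricError("MCC undefined with a single class")
    u = np.unique(scores)
    candidates = [u[0]] if u.size == 1 else list((u[:-1] + u[1:]) / 2.0)
    best_thr, best_mcc = candidates[0], -np.inf
    for thr in candidates:
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        tn = int(np.sum(~pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        mcc = matthews_corrcoef(tp, fp, tn, fn)
        if mcc > best_mcc + 1e-15:
            best_mcc, best_thr = mcc, thr
    return float(best_thr)


# ---------------------------------------------------------------------------
# sequence-only baseline (for the geometric-ablation comparison)
# ---------------------------------------------------------------------------

def _window_onehot(embedding: np.ndarray, window: int = 2) -> np.ndarray:
    """Stack each residue's one-hot with its +-window neighbors (zero-padded)."""
    n, d = embedding.shape
    cols = []
    for off in range(-window, window + 1):
        shifted = np.zeros((n, d))
        if off < 0:
            shifted[-off:] = embedding[:n + off]
        elif off > 0:
            shifted[:n - off] = embedding[off:]
        else:
            shifted = embedding
        cols.append(shifted)
    return np.concatenate(cols, axis=1)


def train_sequence_baseline(train_prots: list[EncodedProtein],
                            val_prots: list[EncodedProtein],
                            window: int = 2, seed: int = 0):
    """Windowed one-hot logistic regression per task; returns per-protein
    probability matrices for the validation set."""
    from sklearn.linear_model import LogisticRegression
    n_tasks = train_prots[0].labels.shape[1]
    Xtr = {t: [] for t in range(n_tasks)}
    ytr = {t: [] for t in range(n_tasks)}
    for p in train_prots:
        feats = _window_onehot(p.embedding, window)
        for t in range(n_tasks):
            if p.task_mask[t]:
                Xtr[t].append(feats)
                ytr[t].append(p.labels[:, t])
    preds = [np.zeros((p.n_residues, n_tasks)) for p in val_prots]
    for t in range(n_tasks):
        if not Xtr[t]:
            continue
        X = np.concatenate(Xtr[t])
        y = np.concatenate(ytr[t])
        if y.min() == y.max():
            for pr in preds:
                pr[:, t] = float(y[0])
            continue
        clf = LogisticRegression(max_iter=200, random_state=seed)
        clf.fit(X, y)
        for k, p in enumerate(val_prots):
            preds[k][:, t] = clf.predict_proba(_window_onehot(p.embedding, window))[:, 1]
    return preds


def permute_labels(proteins: list[EncodedProtein], seed: int) -> list[EncodedProtein]:
    """Control copy with labels shuffled across the pooled dataset.

    For each task the annotated labels of all proteins are concatenated,
    permuted, and redistributed, so neither residue geometry nor
    per-protein base rates carry information about the permuted labels —
    only the global prevalence survives.
    """
    rng = np.random.default_rng(seed)
    out = [copy.copy(p) for p in proteins]
    for q in out:
        q.labels = q.labels.copy()
    n_tasks = proteins[0].labels.shape[1]
    for t in range(n_tasks):
        annotated = [q for q in out if q.task_mask[t]]
        if not annotated:
            continue
        pooled = np.concatenate([q.labels[:, t] for q in annotated])
        pooled = pooled[rng.permutation(pooled.size)]
        offset = 0
        for q in annotated:
            q.labels[:, t] = pooled[offset:offset + q.n_residues]
            offset += q.n_residues
    return out
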