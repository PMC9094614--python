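"""End-to-end orchestration: DeepSurv-style training of the spherical risk
network, cross-validation and external-cohort evaluation.

Training minimizes the average negative log Cox partial likelihood of the
network's scalar outputs with Adam (decoupled weight decay).  Risk sets are
formed within each mini-batch (the standard stochastic compromise for the
Cox loss; ``full_batch`` restores exactness).  Channel standardization
statistics and model selection (best validation loss) use the training split
only — external cohorts are scored with the stored statistics, never
re-fitted.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .sphnet import NetConfig, RiskModel
from .spherical_mapping import SphericalMap, ChannelStats
from .survival_stats import (
    SurvivalCohort,
    concordance_index,
    kaplan_meier,
    neg_log_partial_likelihood,
    partial_likelihood_gradient,
    stratify_by_median,
)

__all__ = [
    "ExperimentConfig",
    "TrainResult",
    "train",
    "cross_validate",
    "evaluate_external",
    "stratified_folds",
]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a training run; JSON round trips
    bit-exactly.  The seed is mandatory: there is no nondeterministic path."""

    input_config: str = "sphcnn1"
    bandwidth: int = 16
    channels1: int = 16
    channels2: int = 32
    learning_rate: float = 1e-3
    epochs: int = 60
    batch_size: int = 64
    weight_decay: float = 1e-4
    val_fraction: float = 0.2
    n_folds: int = 5
    full_batch: bool = False
    precision: str = "single"
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def net_config(self) -> NetConfig:
        return NetConfig(
            input_config=self.input_config,
            bandwidth=self.bandwidth,
            channels1=self.channels1,
            channels2=self.channels2,
            precision=self.precision,
            seed=self.seed,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            return cls(**json.load(f))


@dataclass
class TrainResult:
    model: RiskModel
    history: list[dict]
    best_epoch: int
    best_val_loss: float


def stratified_folds(event: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Event-stratified fold labels: events and censored subjects are
    permuted separately and dealt round-robin, so every fold sees events."""
    event = np.asarray(event)
    labels = np.empty(len(event), dtype=int)
    for grp in (np.flatnonzero(event == 1), np.flatnonzero(event == 0)):
        perm = rng.permutation(grp)
        labels[perm] = np.arange(len(perm)) % n_folds
    return labels


def _adam_step(params, grads, state, lr, weight_decay, t):
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for k, p in params.items():
        g = np.asarray(grads[k], dtype=float)
        if weight_decay and not k.endswith("_b") and not k.endswith("bias"):
            g = g + weight_decay * p
        m, v = state[k]
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        state[k] = (m, v)
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        params[k] = p - lr * mhat / (np.sqrt(vhat) + eps)


def _batches(n, batch_size, event, rng, max_tries=100):
    """Shuffled mini-batch index lists, each guaranteed to contain an event."""
    for _ in range(max_tries):
        perm = rng.permutation(n)
        batches = [perm[i : i + batch_size] for i in range(0, n, batch_size)]
        if all(event[b].any() for b in batches):
            return batches
    raise RuntimeError(
        "could not form mini-batches with at least one event each; "
        "too few events for this batch size"
    )


def train(
    maps: list[SphericalMap],
    cohort: SurvivalCohort,
    config: ExperimentConfig,
    val_index: np.ndarray | None = None,
) -> TrainResult:
    """Fit the spherical risk network on (maps, cohort).

    A validation split (event-stratified, ``val_fraction``) is carved out for
    model selection on validation loss unless ``val_index`` supplies one
    explicitly.  Returns the best-validation-loss checkpoint and the per-
    epoch history (train/val loss, val C-index).
    """
    n = len(maps)
    if n != len(cohort):
        raise ValueError("maps and cohort must align")
    if cohort.n_events == 0:
        raise ValueError("cannot train: all subjects censored")
    rng = np.random.default_rng(config.seed)

    if val_index is None:
        n_val_folds = max(2, int(round(1.0 / max(config.val_fraction, 1e-9))))
        labels = stratified_folds(cohort.event, n_val_folds, rng)
        val_index = np.flatnonzero(labels == 0)
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_index] = True
    tr_idx = np.flatnonzero(~val_mask)
    va_idx = np.flatnonzero(val_mask)
    if cohort.event[tr_idx].sum() == 0 or cohort.event[va_idx].sum() == 0:
        raise ValueError("train/validation split left a side without events")

    stats = ChannelStats.fit([maps[i] for i in tr_idx])
    model = RiskModel(config.net_config(), stats=stats)
    coeffs = model.input_coeffs(maps)
    tr_cohort = cohort.subset(tr_idx)
    va_cohort = cohort.subset(va_idx)

    state = {k: (np.zeros_like(p), np.zeros_like(p)) for k, p in model.params.items()}
    history = []
    best = (np.inf, -1, None)
    bs = len(tr_idx) if config.full_batch else min(config.batch_size, len(tr_idx))
    t = 0
    for epoch in range(1, config.epochs + 1):
        for batch in _batches(len(tr_idx), bs, tr_cohort.event, rng):
            sub = tr_idx[batch]
            h = model.forward(coeffs[sub], want_grad=True)
            bco = cohort.subset(sub)
            dh = partial_likelihood_gradient(h, bco)
            grads = model.backward(dh)
            t += 1
            _adam_step(
                model.params, grads, state, config.learning_rate,
                config.weight_decay, t,
            )
        h_tr = model.forward(coeffs[tr_idx])
        h_va = model.forward(coeffs[va_idx])
        train_loss = neg_log_partial_likelihood(h_tr, tr_cohort)
        val_loss = neg_log_partial_likelihood(h_va, va_cohort)
        try:
            val_ci = concordance_index(h_va, va_cohort)
        except ValueError:
            val_ci = float("nan")
        history.append(
            dict(epoch=epoch, train_loss=train_loss, val_loss=val_loss, val_cindex=val_ci)
        )
        if val_loss < best[0]:
            best = (val_loss, epoch, copy.deepcopy(model.params))
    if best[2] is not None:
        model.params = best[2]
    return TrainResult(
        model=model, history=history, best_epoch=best[1], best_val_loss=best[0]
    )


def cross_validate(
    maps: list[SphericalMap],
    cohort: SurvivalCohort,
    config: ExperimentConfig,
) -> dict:
    """K-fold cross-validation with event-stratified, seed-fixed splits.

    Folds are disjoint and exhaustive; each fold's model is trained on the
    remaining subjects (with its own internal validation split) and scored on
    the held-out fold.  Returns per-fold C-indices, their mean/sd, the pooled
    out-of-fold C-index, and the split manifest for reuse by other methods.
    """
    n = len(maps)
    if n < config.n_folds:
        raise ValueError("need at least n_folds subjects")
    rng = np.random.default_rng(config.seed)
    labels = stratified_folds(cohort.event, config.n_folds, rng)
    fold_ci = []
    pooled_scores = np.empty(n)
    for k in range(config.n_folds):
        te_idx = np.flatnonzero(labels == k)
        tr_idx = np.flatnonzero(labels != k)
        if cohort.event[te_idx].sum() == 0:
            raise ValueError(
                f"fold {k} has no events; use stratified splitting or fewer folds"
            )
        fold_cfg = copy.deepcopy(config)
        fold_cfg.seed = int(np.random.SeedSequence([config.seed, k]).generate_state(1)[0] % (2**31))
        res = train([maps[i] for i in tr_idx], cohort.subset(tr_idx), fold_cfg)
        h_te = res.model.forward(res.model.input_coeffs([maps[i] for i in te_idx]))
        pooled_scores[te_idx] = h_te
        fold_ci.append(concordance_index(h_te, cohort.subset(te_idx)))
    fold_ci = np.asarray(fold_ci)
    return dict(
        fold_c_indices=fold_ci,
        mean_c_index=float(fold_ci.mean()),
        sd_c_index=float(fold_ci.std(ddof=1)),
        pooled_c_index=concordance_index(pooled_scores, cohort),
        fold_labels=labels,
        manifest={
            str(sid): int(lab) for sid, lab in zip(cohort.subject_id, labels)
        },
    )


def evaluate_external(
    model: RiskModel,
    maps: list[SphericalMap],
    cohort: SurvivalCohort,
) -> dict:
    """Score an external cohort with a fitted model (stored normalization
    statistics; no re-fitting), stratify at the median predicted risk and
    estimate Kaplan-Meier curves per risk group."""
    scores = model.forward(model.input_coeffs(maps))
    ci = concordance_index(scores, cohort)
    groups = stratify_by_median(scores)
    out = dict(c_index=ci, scores=scores, groups=groups)
    for g in ("low", "high"):
        sel = groups == g
        out[f"km_{g}"] = kaplan_meier(cohort.subset(sel)) if sel.any() else None
    return out
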