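"""SVM classification on precomputed kernels with repeated CV and AUC.

The evaluation protocol is stratified k-fold cross-validation repeated
many times (default 5 folds x 50 repeats): per repeat, a seeded
stratified split is drawn, a soft-margin SVM with the precomputed
kernel is trained on each training block, decision values are scored on
the held-out block, and the fold AUCs are averaged; the result
aggregates the per-repeat means.  AUC is the Mann-Whitney rank
statistic P(score_pos > score_neg) + 0.5 P(tie).

Multiple kernels (one per q) can be combined with weights from centered
kernel-target alignment: each kernel's Frobenius alignment with the
label kernel yyᵀ after double-centering, floored at zero and normalized
to sum 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import GlycanError
from .kernels import KernelMatrix


@dataclass
class CVConfig:
    folds: int = 5
    repeats: int = 50
    svm_cost: float = 1.0
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise GlycanError("folds must be >= 2")
        if self.repeats < 1:
            raise GlycanError("repeats must be >= 1")
        if self.svm_cost <= 0:
            raise GlycanError("SVM cost must be positive")


@dataclass
class CVResult:
    per_repeat: np.ndarray
    mean: float
    std: float
    config: CVConfig = field(repr=False)

    def summary(self) -> dict:
        return {
            "mean_auc": float(self.mean),
            "std_auc": float(self.std),
            "folds": self.config.folds,
            "repeats": self.config.repeats,
            "svm_cost": self.config.svm_cost,
            "seed": self.config.seed,
            "per_repeat": [float(a) for a in self.per_repeat],
        }


def auc(scores, labels) -> float:
    """Area under the ROC curve by midrank Mann-Whitney statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    if pos.size == 0 or neg.size == 0:
        raise GlycanError("AUC requires both classes present")
    ranks = scipy.stats.rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = float(ranks[: pos.size].sum())
    u = rank_sum_pos - pos.size * (pos.size + 1) / 2.0
    return u / (pos.size * neg.size)


def _as_matrix(K) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(K, KernelMatrix):
        return K.values, K.ids
    return np.asarray(K, dtype=float), None


def cv_auc(K: KernelMatrix, labels, cfg: CVConfig | None = None) -> CVResult:
    """Repeated stratified cross-validated AUC of a precomputed kernel.

    ``labels`` are ±1 aligned with the kernel's glycan order.  When the
    kernel carries glycan ids, samples are internally reordered by id so
    the result is invariant to a simultaneous permutation of kernel and
    labels.  Fold splits are seeded ``cfg.seed + repeat`` so repeats are
    independent but the whole run is reproducible.
    """
    if cfg is None:
        cfg = CVConfig()
    values, ids = _as_matrix(K)
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != values.shape[0]:
        raise GlycanError("labels are not aligned with the kernel")
    if set(np.unique(y)) - {-1, 1}:
        raise GlycanError("labels must be +1 or -1")
    if ids is not None:
        order = np.argsort(np.asarray(ids, dtype=object))
        values = values[np.ix_(order, order)]
        y = y[order]
    counts = {c: int((y == c).sum()) for c in (-1, 1)}
    if min(counts.values()) < cfg.folds:
        raise GlycanError(
            f"smallest class has {min(counts.values())} members, fewer than "
            f"{cfg.folds} folds"
        )
    per_repeat = np.empty(cfg.repeats)
    for r in range(cfg.repeats):
        splitter = StratifiedKFold(
            n_splits=cfg.folds, shuffle=True, random_state=cfg.seed + r
        )
        fold_aucs = []
        for train, test in splitter.split(values, y):
            svm = SVC(C=cfg.svm_cost, kernel="precomputed")
            svm.fit(values[np.ix_(train, train)], y[train])
            scores = svm.decision_function(values[np.ix_(test, train)])
            fold_aucs.append(auc(scores, y[test]))
        per_repeat[r] = float(np.mean(fold_aucs))
    return CVResult(per_repeat, float(per_repeat.mean()), float(per_repeat.std()), cfg)


def mkl_weights(kernels: dict[int, KernelMatrix], labels) -> dict[int, float]:
    """Kernel combination weights by centered kernel-target alignment.

    Each kernel is scored by its centered Frobenius alignment with the
    label kernel ``y yᵀ``; negative alignments are floored at zero and
    the weights normalized to sum 1.  If no kernel aligns positively,
    uniform weights are returned with a warning.
    """
    if not kernels:
        raise GlycanError("no kernels given")
    y = np.asarray(labels, dtype=float)
    n = y.shape[0]
    target = np.outer(y, y)
    center = np.eye(n) - np.ones((n, n)) / n
    target_c = center @ target @ center
    target_norm = np.linalg.norm(target_c)
    alignments: dict[int, float] = {}
    for q, K in sorted(kernels.items()):
        values, _ = _as_matrix(K)
        if values.shape[0] != n:
            raise GlycanError(f"kernel for q={q} is not aligned with the labels")
        kc = center @ values @ center
        denom = np.linalg.norm(kc) * target_norm
        alignments[q] = float((kc * target_c).sum() / denom) if denom > 0 else 0.0
    floored = {q: max(a, 0.0) for q, a in alignments.items()}
    total = sum(floored.values())
    if total <= 0:
        warnings.warn(
            "no kernel has positive target alignment; using uniform weights",
            UserWarning,
            stacklevel=2,
        )
        return {q: 1.0 / len(kernels) for q in kernels}
    return {q: a / total for q, a in floored.items()}
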