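"""Kernel construction: plain, weighted, and combined q-gram kernels.

Given the count matrix ``X_q`` (q-grams x glycans) the plain q-gram
kernel is the Gram matrix ``K_q = X_qᵀ X_q``; the weighted q-gram
kernel is ``K_wq = X_qᵀ W_q X_q`` where ``W_q`` is a positive
semidefinite inter-q-gram weight matrix derived from a similarity
matrix ``S_q`` (LK, KM or LKM).  Kernels across several q are combined
as ``Σ_q α_q K_q``; with unit weights this is exactly the Q-gram kernel
``K_Q = Σ_q K_q``.

Similarity matrices produced by alignment are not guaranteed positive
semidefinite, so they are revised before use: symmetrize, clip negative
eigenvalues to zero (the nearest PSD matrix in Frobenius norm) and add
a tiny ridge.  A diagonal-shift alternative is available.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .core import GlycanError
from .qgrams import CountMatrix
from .similarity import SimilarityMatrix

#: numerical tolerances for kernel validity checks
SYM_TOL = 1e-10
PSD_TOL = 1e-8


@dataclass
class PSDReport:
    min_eig_before: float
    min_eig_after: float
    ridge: float
    method: str


@dataclass
class WeightMatrix:
    """PSD-corrected inter-q-gram weight matrix ``W_q`` with provenance."""

    q: int
    keys: list[str]
    values: np.ndarray
    method: str
    report: PSDReport


@dataclass
class KernelMatrix:
    """``n × n`` glycan-glycan kernel with its glycan id order."""

    values: np.ndarray
    ids: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, text: str, meta: dict | None = None) -> "KernelMatrix":
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns], meta or {})


def assert_valid_kernel(K: KernelMatrix | np.ndarray) -> None:
    """Check symmetry (1e-10) and positive semidefiniteness (1e-8)."""
    values = K.values if isinstance(K, KernelMatrix) else K
    if not np.all(np.isfinite(values)):
        raise GlycanError("kernel contains non-finite entries")
    asym = float(np.max(np.abs(values - values.T))) if values.size else 0.0
    if asym > SYM_TOL:
        raise GlycanError(f"kernel asymmetry {asym:.3e} exceeds {SYM_TOL}")
    if values.size:
        min_eig = float(scipy.linalg.eigvalsh(values)[0])
        if min_eig < -PSD_TOL:
            raise GlycanError(f"kernel min eigenvalue {min_eig:.3e} < -{PSD_TOL}")


def psd_correct(
    S: SimilarityMatrix, *, method: str = "clip", ridge: float = 1e-9
) -> WeightMatrix:
    """Revise a similarity matrix into a PSD weight matrix ``W_q``.

    ``clip`` (default): eigendecompose the symmetrized matrix and zero
    the negative eigenvalues — the Frobenius-nearest PSD matrix — then
    add ``ridge * I``.  ``shift``: add ``|λ_min| * I`` when the smallest
    eigenvalue is negative, preserving off-diagonal structure exactly.
    """
    values = np.asarray(S.values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise GlycanError("similarity matrix must be square")
    if not np.all(np.isfinite(values)):
        raise GlycanError("similarity matrix contains non-finite entries")
    sym = (values + values.T) / 2.0
    eigvals, eigvecs = scipy.linalg.eigh(sym)
    min_before = float(eigvals[0]) if eigvals.size else 0.0
    if method == "clip":
        if min_before < 0:
            corrected = (eigvecs * np.clip(eigvals, 0.0, None)) @ eigvecs.T
            corrected = (corrected + corrected.T) / 2.0
        else:
            corrected = sym
    elif method == "shift":
        corrected = sym + (abs(min_before) * np.eye(len(sym)) if min_before < 0 else 0.0)
    else:
        raise GlycanError(f"unknown PSD correction method {method!r}")
    corrected = corrected + ridge * np.eye(len(sym))
    min_after = float(scipy.linalg.eigvalsh(corrected)[0]) if corrected.size else 0.0
    return WeightMatrix(
        S.q,
        list(S.keys),
        corrected,
        S.method,
        PSDReport(min_before, min_after, ridge, method),
    )


def qgram_kernel(X: CountMatrix) -> KernelMatrix:
    """Plain q-gram kernel ``K_q = X_qᵀ X_q`` (inner products of counts)."""
    values = np.asarray(X.values, dtype=float)
    K = values.T @ values
    return KernelMatrix(K, list(X.glycan_ids), {"q": X.q, "method": "qgram"})


def weighted_kernel(X: CountMatrix, W: WeightMatrix | np.ndarray) -> KernelMatrix:
    """Weighted q-gram kernel ``K_wq = X_qᵀ W_q X_q``."""
    values = np.asarray(X.values, dtype=float)
    w = W.values if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)
    if w.shape != (values.shape[0], values.shape[0]):
        raise GlycanError(
            f"weight matrix shape {w.shape} does not match "
            f"{values.shape[0]} q-grams"
        )
    K = values.T @ w @ values
    K = (K + K.T) / 2.0
    meta = {"q": X.q, "method": "weighted"}
    if isinstance(W, WeightMatrix):
        meta["similarity"] = W.method
    return KernelMatrix(K, list(X.glycan_ids), meta)


def normalize_weights(weights: dict[int, float]) -> dict[int, float]:
    """Validate kernel combination weights and normalize them to sum 1."""
    if not weights:
        raise GlycanError("no kernel weights given")
    if any(a < 0 for a in weights.values()):
        raise GlycanError("kernel weights must be non-negative")
    total = sum(weights.values())
    if total <= 0:
        raise GlycanError("at least one kernel weight must be positive")
    return {q: a / total for q, a in weights.items()}


def combine_kernels(
    kernels: dict[int, KernelMatrix],
    weights: dict[int, float] | None = None,
    *,
    normalize: bool = False,
) -> KernelMatrix:
    """Weighted sum ``Σ_q α_q K_q`` of kernels over the same glycans.

    With ``weights=None`` every kernel gets weight 1, giving the plain
    Q-gram kernel ``K_Q = Σ_q K_q``.  ``normalize=True`` rescales the
    weights to sum 1 first.
    """
    if not kernels:
        raise GlycanError("no kernels to combine")
    qs = sorted(kernels)
    ids = kernels[qs[0]].ids
    for q in qs:
        if kernels[q].ids != ids:
            raise GlycanError(f"kernel for q={q} has a different glycan order")
    if weights is None:
        weights = {q: 1.0 for q in qs}
    if set(weights) != set(qs):
        raise GlycanError("weights must cover exactly the supplied kernels")
    if normalize:
        weights = normalize_weights(weights)
    total = np.zeros_like(kernels[qs[0]].values)
    for q in qs:
        total = total + weights[q] * kernels[q].values
    return KernelMatrix(
        total, list(ids), {"Q": qs, "alpha": dict(weights), "method": "combined"}
    )


def cosine_normalize(K: KernelMatrix) -> KernelMatrix:
    """Cosine-normalize a kernel: ``K'_st = K_st / sqrt(K_ss K_tt)``.

    Stabilizes scale across q before combining; the output diagonal is
    all ones and the result is invariant to rescaling of the input.
    """
    diag = np.diag(K.values).copy()
    bad = np.nonzero(diag <= 0)[0]
    if bad.size:
        raise GlycanError(
            f"cannot cosine-normalize: zero diagonal for glycan "
            f"{K.ids[bad[0]]!r}"
        )
    inv = 1.0 / np.sqrt(diag)
    values = K.values * np.outer(inv, inv)
    np.fill_diagonal(values, 1.0)
    return KernelMatrix(values, list(K.ids), {**K.meta, "normalized": True})
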