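"""End-to-end pipelines: glycans -> similarity -> kernel.

Thin plumbing over the library modules so the CLI, tests and scripts
share one code path for building each kernel family:

* ``qgram``: plain count-inner-product kernel K_q = XᵀX
* ``lk``:    linkage-weighted kernel, W from layer/mono/bond similarity
* ``km``:    KCaM-weighted kernel, W from exact-match tree alignment
* ``lkm``:   linkage-KCaM kernel, W from linkage-weighted alignment

Similarity matrices are PSD-revised before use.
"""

from __future__ import annotations

from typing import Sequence

from .core import Glycan, GlycanError
from .kcam import AlignParams, km_matrix, lkm_matrix
from .kernels import (
    KernelMatrix,
    WeightMatrix,
    combine_kernels,
    cosine_normalize,
    psd_correct,
    qgram_kernel,
    weighted_kernel,
)
from .qgrams import build_index, count_matrix
from .similarity import LinkageTables, SimilarityMatrix, lk_matrix

METHODS = ("qgram", "lk", "km", "lkm")


def similarity_matrix(
    glycans: Sequence[Glycan],
    q: int,
    method: str,
    tables: LinkageTables | None = None,
    *,
    straight_only: bool = False,
) -> SimilarityMatrix:
    """Inter-q-gram similarity matrix S_q for one weighting method."""
    index = build_index(glycans, q, straight_only=straight_only)
    if method == "lk":
        return lk_matrix(index, tables)
    if method == "km":
        return km_matrix(index)
    if method == "lkm":
        params = AlignParams(node_score="linkage", tables=tables or LinkageTables.default())
        return lkm_matrix(index, params)
    raise GlycanError(f"unknown similarity method {method!r}")


def glycan_kernel(
    glycans: Sequence[Glycan],
    q: int,
    method: str = "qgram",
    tables: LinkageTables | None = None,
    *,
    straight_only: bool = False,
    normalize: bool = False,
    psd_method: str = "clip",
) -> tuple[KernelMatrix, WeightMatrix | None]:
    """Build the n x n kernel for one q and one method.

    Returns the kernel and, for weighted methods, the PSD-corrected
    weight matrix (with its correction report); ``None`` for the plain
    q-gram kernel.
    """
    if method not in METHODS:
        raise GlycanError(f"unknown kernel method {method!r}; choose from {METHODS}")
    index = build_index(glycans, q, straight_only=straight_only)
    X = count_matrix(glycans, index, straight_only=straight_only)
    if method == "qgram":
        K, W = qgram_kernel(X), None
    else:
        if method == "lk":
            S = lk_matrix(index, tables)
        elif method == "km":
            S = km_matrix(index)
        else:
            params = AlignParams(
                node_score="linkage", tables=tables or LinkageTables.default()
            )
            S = lkm_matrix(index, params)
        W = psd_correct(S, method=psd_method)
        K = weighted_kernel(X, W)
    if normalize:
        K = cosine_normalize(K)
    return K, W


def multi_q_kernel(
    glycans: Sequence[Glycan],
    q_set: Sequence[int],
    method: str = "qgram",
    tables: LinkageTables | None = None,
    weights: dict[int, float] | None = None,
    *,
    normalize: bool = False,
    straight_only: bool = False,
) -> KernelMatrix:
    """Combined kernel over a set of q values (K_Q, or α-weighted)."""
    kernels = {
        q: glycan_kernel(
            glycans,
            q,
            method,
            tables,
            normalize=normalize,
            straight_only=straight_only,
        )[0]
        for q in q_set
    }
    return combine_kernels(kernels, weights)
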