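"""Segmentation error metrics: variation of information and adapted Rand error.

Both metrics compare an automatic reconstruction ``S`` against a gold
standard ``T`` voxel-wise, ignoring gold-standard background (``T == 0``).

* ``VI(S, T) = H(S|T) + H(T|S)`` in bits: ``H(S|T)`` measures
  over-segmentation (split errors), ``H(T|S)`` under-segmentation (merge
  errors).  Lower is better; 0 means the partitions agree.
* ``ARE = 1 - F1`` of pair-counting precision and recall (the SNEMI/ISBI
  convention, computed from squared contingency sums): precision penalises
  merge errors in ``S``, recall penalises splits.  Lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Tuple, Union

import numpy as np
from scipy import sparse

from .core import LabelVolume

__all__ = [
    "MetricsReport",
    "variation_of_information",
    "adapted_rand_error",
    "compute_metrics_report",
]

ArrayLike = Union[LabelVolume, np.ndarray]


@dataclass
class MetricsReport:
    """VI with its split/merge decomposition, plus the adapted Rand error."""

    vi: float
    vi_split: float
    vi_merge: float
    are: float

    def as_dict(self) -> dict:
        return asdict(self)


def _as_array(v: ArrayLike) -> np.ndarray:
    return v.data if isinstance(v, LabelVolume) else np.asarray(v)


def _contingency(
    S: ArrayLike,
    T: ArrayLike,
    ignore_background: bool,
    mask: Optional[np.ndarray],
) -> sparse.csr_matrix:
    """Sparse joint count matrix over included voxels (rows: S, cols: T)."""
    s = _as_array(S).ravel()
    t = _as_array(T).ravel()
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: {_as_array(S).shape} vs {_as_array(T).shape}")
    keep = np.ones(s.shape, dtype=bool)
    if ignore_background:
        keep &= t != 0
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool).ravel()
    s, t = s[keep], t[keep]
    if s.size == 0:
        raise ValueError("no foreground voxels to evaluate")
    _, si = np.unique(s, return_inverse=True)
    _, ti = np.unique(t, return_inverse=True)
    data = np.ones(s.size, dtype=np.int64)
    return sparse.coo_matrix((data, (si, ti))).tocsr()


def variation_of_information(
    S: ArrayLike,
    T: ArrayLike,
    ignore_background: bool = True,
    mask: Optional[np.ndarray] = None,
    base: float = 2.0,
) -> Tuple[float, float, float]:
    """``(vi, vi_split, vi_merge)`` between reconstruction ``S`` and gold ``T``.

    ``vi_split = H(S|T)`` (over-segmentation), ``vi_merge = H(T|S)``
    (under-segmentation), ``vi`` their sum, in units of ``log base``
    (bits by default).  Voxels with ``T == 0`` are excluded when
    ``ignore_background`` is set; an optional boolean ``mask`` restricts
    the evaluation further (region-restricted variants).
    """
    c = _contingency(S, T, ignore_background, mask)
    n = c.sum()
    p_ij = c.data / n
    rows, cols = c.nonzero()
    p_s = np.asarray(c.sum(axis=1)).ravel() / n
    p_t = np.asarray(c.sum(axis=0)).ravel() / n
    log = np.log
    scale = 1.0 / np.log(base)
    h_s_given_t = -float(np.sum(p_ij * (log(p_ij) - log(p_t[cols])))) * scale
    h_t_given_s = -float(np.sum(p_ij * (log(p_ij) - log(p_s[rows])))) * scale
    h_s_given_t = max(h_s_given_t, 0.0) + 0.0  # avoid -0.0
    h_t_given_s = max(h_t_given_s, 0.0) + 0.0
    return h_s_given_t + h_t_given_s, h_s_given_t, h_t_given_s


def adapted_rand_error(
    S: ArrayLike,
    T: ArrayLike,
    ignore_background: bool = True,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Adapted Rand error ``1 - F1`` of pair-counting precision and recall.

    With contingency counts ``c_ij`` and marginals ``a_i`` (over ``S``)
    and ``b_j`` (over ``T``): ``precision = sum c_ij^2 / sum a_i^2`` and
    ``recall = sum c_ij^2 / sum b_j^2``.  0 for identical partitions
    (up to label permutation), at most 1.
    """
    c = _contingency(S, T, ignore_background, mask)
    sum_c2 = float(np.sum(c.data.astype(np.float64) ** 2))
    a = np.asarray(c.sum(axis=1), dtype=np.float64).ravel()
    b = np.asarray(c.sum(axis=0), dtype=np.float64).ravel()
    precision = sum_c2 / float(np.sum(a**2))
    recall = sum_c2 / float(np.sum(b**2))
    f1 = 2.0 * precision * recall / (precision + recall)
    return 1.0 - f1


def compute_metrics_report(
    S: ArrayLike,
    T: ArrayLike,
    ignore_background: bool = True,
    mask: Optional[np.ndarray] = None,
) -> MetricsReport:
    """Bundle VI (with decomposition) and ARE into one report."""
    vi, vi_split, vi_merge = variation_of_information(S, T, ignore_background, mask)
    are = adapted_rand_error(S, T, ignore_background, mask)
    return MetricsReport(vi=vi, vi_split=vi_split, vi_merge=vi_merge, are=are)
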