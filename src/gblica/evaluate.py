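"""Recovery metrics against planted ground truth.

Used by the simulation studies: greedy matching of estimated to planted
loading rows by absolute Pearson correlation, and the planted modality
contribution fractions expressed on the standardized scale actually seen
by the factorization.
"""

from __future__ import annotations

import numpy as np

from .errors import DimensionError
from .synthetic import GroundTruth

__all__ = ["match_components", "planted_contributions"]


def match_components(H_est: np.ndarray, H_true: np.ndarray):
    """Greedy one-to-one matching of rows by absolute correlation.

    Returns ``(perm, r)`` where ``perm[c]`` is the estimated row matched to
    true row ``c`` and ``r[c]`` the absolute Pearson correlation of the pair.
    Pairs are claimed in decreasing correlation order.
    """
    H_est = np.asarray(H_est, float)
    H_true = np.asarray(H_true, float)
    if H_est.shape[1] != H_true.shape[1]:
        raise DimensionError("subject counts differ between loading matrices")
    A = H_est - H_est.mean(axis=1, keepdims=True)
    B = H_true - H_true.mean(axis=1, keepdims=True)
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    corr = np.abs(B @ A.T)                     # (C_true, C_est)
    perm = np.full(H_true.shape[0], -1)
    r = np.zeros(H_true.shape[0])
    free_true = set(range(corr.shape[0]))
    free_est = set(range(corr.shape[1]))
    work = corr.copy()
    while free_true and free_est:
        i, j = np.unravel_index(np.argmax(work), work.shape)
        perm[i] = j
        r[i] = corr[i, j]
        free_true.discard(int(i))
        free_est.discard(int(j))
        work[i, :] = -1
        work[:, j] = -1
    return perm, r


def planted_contributions(truth: GroundTruth, scales: np.ndarray) -> np.ndarray:
    """Planted modality contribution fractions on the standardized scale.

    ``scales`` are the per-modality standardization factors (from
    :func:`gblica.lica.standardize_modalities`); the planted weight
    ``lambda_k,c`` becomes ``scales[k] * lambda_k,c`` after standardization,
    and fractions are squared-weight shares per component.
    """
    lam = truth.lambdas * np.asarray(scales, float)[:, None]
    lam2 = lam**2
    totals = lam2.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    return np.where(totals > 0, lam2 / safe, 1.0 / lam2.shape[0])
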