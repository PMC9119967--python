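"""Ranking metrics for active/decoy evaluation."""

from __future__ import annotations

import warnings

import numpy as np


def average_precision(scores, labels) -> float:
    """Average precision of a ranked active/decoy list.

    AP = sum_k (R_k - R_{k-1}) * P_k over the list ranked by descending
    score (step-wise interpolation, equivalently the mean of the precision
    at each positive's rank). Ties are kept in stable input order and
    flagged with a warning. Requires at least one positive label.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positive labels")
    if len(np.unique(scores)) < len(scores):
        warnings.warn("tied scores present; ties broken by stable input order")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    tp = np.cumsum(ranked)
    ranks = np.arange(1, len(ranked) + 1)
    precision = tp / ranks
    return float(precision[ranked == 1].sum() / n_pos)


def mean_average_precision(aps) -> float:
    """Arithmetic mean of per-target average precisions."""
    aps = list(aps)
    if not aps:
        raise ValueError("mean over an empty collection of reports")
    return float(np.mean(aps))
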