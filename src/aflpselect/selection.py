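"""scikit-learn-style transformers wrapping the locus-selection core.

These make the moving and fixed error-rate thresholds composable with
sklearn pipelines: ``X`` is the samples x loci call array (0/1/nan) and
``transform`` drops the columns (loci) flagged by the threshold.  The
replicate pairing that powers the error estimates is an estimator
parameter, given as row-index pairs into ``X``.

The module-level functions in :mod:`aflpselect.threshold` remain the
primary interface; these classes delegate to them.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .error_rates import locus_error_rates
from .exceptions import ValidationError
from .matrix import MarkerMatrix, ReplicateSet
from .threshold import (
    SelectionResult,
    iterate_selection,
    select_fixed,
)

__all__ = ["MovingThresholdSelector", "FixedThresholdSelector"]


def _as_matrix(X: np.ndarray) -> MarkerMatrix:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D (samples x loci)")
    samples = tuple(f"s{i}" for i in range(X.shape[0]))
    loci = tuple(f"l{j}" for j in range(X.shape[1]))
    return MarkerMatrix(X, samples, loci)


def _as_replicates(m: MarkerMatrix, pairs: Sequence[tuple[int, int]]) -> ReplicateSet:
    try:
        idx_pairs = tuple(
            (m.sample_ids[int(a)], m.sample_ids[int(b)]) for a, b in pairs
        )
    except IndexError as exc:
        raise ValidationError(f"replicate pair row index out of range: {exc}") from None
    return ReplicateSet(idx_pairs)


class MovingThresholdSelector(TransformerMixin, BaseEstimator):
    """Select loci under the frequency-dependent quadratic error threshold.

    Parameters
    ----------
    replicate_pairs : sequence of (int, int)
        Row-index pairs of ``X`` that re-genotype the same individual.
    rounds : int, default 2
        Number of fit/select passes.
    min_loci : int, default 50
        Stop early when fewer usable loci remain before a round.

    Attributes
    ----------
    support_ : ndarray of bool, shape (n_loci,)
        True for loci kept after the final round.
    results_ : list of SelectionResult
        One entry per completed round.
    models_ : list of ThresholdModel
        The fitted curve of each round.
    n_features_in_ : int
    """

    def __init__(
        self,
        replicate_pairs: Sequence[tuple[int, int]] = (),
        rounds: int = 2,
        min_loci: int = 50,
    ):
        self.replicate_pairs = replicate_pairs
        self.rounds = rounds
        self.min_loci = min_loci

    def fit(self, X, y=None):
        m = _as_matrix(X)
        reps = _as_replicates(m, self.replicate_pairs)
        if len(reps) == 0:
            raise ValidationError("moving-threshold selection needs replicate pairs")
        self.results_: list[SelectionResult] = iterate_selection(
            m, reps, rounds=self.rounds, min_loci=self.min_loci
        )
        if self.results_:
            kept = set(self.results_[-1].kept)
        else:  # nothing selected: keep everything, curve never fitted
            kept = set(m.locus_ids)
        self.models_ = [r.model for r in self.results_]
        self.support_ = np.array([l in kept for l in m.locus_ids], dtype=bool)
        self.n_features_in_ = m.n_loci
        return self

    def get_support(self, indices: bool = False):
        if indices:
            return np.flatnonzero(self.support_)
        return self.support_

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1] if X.ndim == 2 else '?'} loci, "
                f"selector was fitted on {self.n_features_in_}"
            )
        return X[:, self.support_]


class FixedThresholdSelector(TransformerMixin, BaseEstimator):
    """Select loci whose replicate error rate does not exceed a constant ``tau``."""

    def __init__(
        self,
        replicate_pairs: Sequence[tuple[int, int]] = (),
        tau: float = 0.10,
    ):
        self.replicate_pairs = replicate_pairs
        self.tau = tau

    def fit(self, X, y=None):
        m = _as_matrix(X)
        reps = _as_replicates(m, self.replicate_pairs)
        if len(reps) == 0:
            raise ValidationError("fixed-threshold selection needs replicate pairs")
        stats = locus_error_rates(m, reps)
        self.result_ = select_fixed(stats, self.tau)
        kept = set(self.result_.kept)
        self.support_ = np.array([l in kept for l in m.locus_ids], dtype=bool)
        self.n_features_in_ = m.n_loci
        return self

    def get_support(self, indices: bool = False):
        if indices:
            return np.flatnonzero(self.support_)
        return self.support_

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1] if X.ndim == 2 else '?'} loci, "
                f"selector was fitted on {self.n_features_in_}"
            )
        return X[:, self.support_]
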