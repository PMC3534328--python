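"""Moving error-rate threshold: quadratic regression of error on frequency.

Locus error rates in dominant-marker data rise and fall with the
frequency of the present phenotype: loci near fixation (almost all bands
present or absent) can hardly disagree between replicates, while
intermediate-frequency loci can.  A single fixed error cutoff therefore
preferentially discards exactly the intermediate-frequency loci that
carry most of the information about population differences.  The moving
threshold instead fits ordinary least squares of error rate on
``{1, f, f^2}`` (``f`` = present-allele frequency) and removes the loci
whose error rate exceeds the fitted curve at their own frequency, i.e.
the loci that are unusually error-prone *for their frequency class*.
Re-fitting on the survivors tightens the curve and allows further rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .error_rates import LocusStats, mean_error_rate
from .exceptions import ValidationError
from .matrix import MarkerMatrix, ReplicateSet

__all__ = [
    "ThresholdModel",
    "SelectionResult",
    "fit_threshold_model",
    "predict_threshold",
    "select_by_model",
    "select_fixed",
    "iterate_selection",
]


@dataclass(frozen=True)
class ThresholdModel:
    """Fitted quadratic threshold curve ``y = b0 + b1 f + b2 f^2``.

    Predictions are clamped below at zero when used as a removal
    threshold (see :func:`predict_threshold`), so a fitted curve that
    dips negative at extreme frequencies can never remove an error-free
    locus.
    """

    b0: float
    b1: float
    b2: float
    r_squared: float
    f_pvalue: float
    n_loci_fit: int

    def predict(self, freq: float | np.ndarray) -> float | np.ndarray:
        return predict_threshold(self, freq)

    def raw(self, freq: float | np.ndarray) -> float | np.ndarray:
        """Unclamped polynomial value."""
        f = np.asarray(freq, dtype=float)
        out = self.b0 + self.b1 * f + self.b2 * f * f
        return float(out) if np.isscalar(freq) else out

    @classmethod
    def fixed(cls, tau: float) -> "ThresholdModel":
        """Degenerate constant model representing a fixed threshold."""
        return cls(b0=float(tau), b1=0.0, b2=0.0, r_squared=0.0,
                   f_pvalue=float("nan"), n_loci_fit=0)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one selection round."""

    kept: tuple[str, ...]
    removed: tuple[str, ...]
    model: ThresholdModel
    round_index: int
    mean_error_before: float
    mean_error_after: float
    mean_freq_before: float
    mean_freq_after: float
    removed_undefined: tuple[str, ...] = field(default=())
    clamp_applied: bool = False

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_removed(self) -> int:
        return len(self.removed) + len(self.removed_undefined)


def _usable(stats: Sequence[LocusStats]) -> list[LocusStats]:
    return [s for s in stats if s.defined]


def fit_threshold_model(stats: Sequence[LocusStats]) -> ThresholdModel:
    """OLS of error rate on ``{1, freq, freq^2}`` over usable loci.

    Loci with undefined error rate or frequency are excluded.  Requires
    at least four usable loci spanning at least three distinct
    frequencies (otherwise the quadratic design is rank-deficient).
    """
    usable = _usable(stats)
    if len(usable) < 4:
        raise ValidationError(
            f"need >= 4 loci with defined error rate and frequency, have {len(usable)}"
        )
    x = np.array([s.present_freq for s in usable], dtype=float)
    y = np.array([s.error_rate for s in usable], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValidationError("need >= 3 distinct frequencies to fit a quadratic")
    X = np.column_stack([np.ones_like(x), x, x * x])
    res = sm.OLS(y, X).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= np.finfo(float).eps * len(y):
        # constant response: the curve is flat and explains nothing
        r2, fp = 0.0, float("nan")
    else:
        r2, fp = float(res.rsquared), float(res.f_pvalue)
    b0, b1, b2 = (float(c) for c in res.params)
    return ThresholdModel(b0=b0, b1=b1, b2=b2, r_squared=r2, f_pvalue=fp,
                          n_loci_fit=len(usable))


def predict_threshold(model: ThresholdModel, freq: float | np.ndarray) -> float | np.ndarray:
    """Threshold at frequency ``freq``: ``max(0, b0 + b1 f + b2 f^2)``.

    The clamp guarantees a locus with zero observed error can never
    exceed the threshold.
    """
    raw = model.raw(freq)
    return max(0.0, raw) if np.isscalar(raw) else np.maximum(0.0, raw)


def _means(stats: Sequence[LocusStats]) -> tuple[float, float]:
    usable = _usable(stats)
    if not usable:
        return float("nan"), float("nan")
    err = float(np.mean([s.error_rate for s in usable]))
    frq = float(np.mean([s.present_freq for s in usable]))
    return err, frq


def select_by_model(
    stats: Sequence[LocusStats],
    model: ThresholdModel,
    round_index: int = 1,
) -> SelectionResult:
    """Remove loci whose error rate strictly exceeds the model threshold.

    Ties (error exactly equal to the prediction) are kept.  Loci whose
    error rate is undefined (zero usable comparisons) cannot be certified
    low-error and are removed, reported separately in
    ``removed_undefined``.
    """
    kept, removed, undefined = [], [], []
    clamp_applied = False
    for s in stats:
        if not s.defined:
            undefined.append(s.locus_id)
            continue
        raw = model.raw(s.present_freq)
        thr = predict_threshold(model, s.present_freq)
        if raw < 0.0 and s.error_rate <= 0.0:
            clamp_applied = True  # clamping is what kept this locus
        if s.error_rate > thr:
            removed.append(s.locus_id)
        else:
            kept.append(s.locus_id)
    kept_set = set(kept)
    before_err, before_frq = _means(stats)
    after_err, after_frq = _means([s for s in stats if s.locus_id in kept_set])
    if clamp_applied:
        warnings.warn(
            "threshold clamped at 0 for at least one zero-error locus at very "
            "low/high frequency; the raw fitted curve was negative there",
            stacklevel=2,
        )
    return SelectionResult(
        kept=tuple(kept),
        removed=tuple(removed),
        model=model,
        round_index=round_index,
        mean_error_before=before_err,
        mean_error_after=after_err,
        mean_freq_before=before_frq,
        mean_freq_after=after_frq,
        removed_undefined=tuple(undefined),
        clamp_applied=clamp_applied,
    )


def select_fixed(stats: Sequence[LocusStats], tau: float) -> SelectionResult:
    """Remove loci with error rate strictly greater than the constant ``tau``.

    Reported through the same :class:`SelectionResult` machinery with a
    degenerate constant model, for uniform summaries.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValidationError("tau must be in [0, 1]")
    return select_by_model(stats, ThresholdModel.fixed(tau))


def iterate_selection(
    m: MarkerMatrix,
    reps: ReplicateSet,
    rounds: int = 2,
    min_loci: int = 50,
) -> list[SelectionResult]:
    """Run ``rounds`` alternating fit/select passes.

    Round *k* fits a fresh quadratic on the loci surviving round *k-1*
    and removes the loci above the new curve.  Per-locus error rates and
    frequencies are computed once from the matrix and replicates: they
    describe individual loci and do not change when other loci are
    dropped.  Iteration stops early with a warning when fewer than
    ``min_loci`` loci remain before a round, the same reason one stops
    after a couple of rounds on real data.
    """
    if rounds < 1:
        raise ValidationError("rounds must be >= 1")
    from .error_rates import locus_error_rates  # local: avoid cycle at import

    stats = locus_error_rates(m, reps)
    results: list[SelectionResult] = []
    current = list(stats)
    for k in range(1, rounds + 1):
        if len(_usable(current)) < min_loci:
            warnings.warn(
                f"stopping before round {k}: {len(_usable(current))} usable loci "
                f"< min_loci={min_loci}",
                stacklevel=2,
            )
            break
        model = fit_threshold_model(current)
        result = select_by_model(current, model, round_index=k)
        results.append(result)
        kept_set = set(result.kept)
        current = [s for s in current if s.locus_id in kept_set]
    return results
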