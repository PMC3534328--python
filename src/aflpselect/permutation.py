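"""Permutation null for the mean error rate of a selected locus subset.

Whether a selection procedure genuinely lowered the mean error rate is
judged against the distribution of mean error rates of equally sized
*random* locus subsets: each permutation draws ``n_selected`` loci
without replacement (among loci with a defined error rate) and records
their unweighted mean error.  The p-value is the proportion of null
means at or below the observed mean, with an add-one correction so a
finite number of permutations never yields p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .error_rates import LocusStats
from .exceptions import ValidationError

__all__ = ["PermutationResult", "permute_mean_errors", "permutation_p_value",
           "permutation_test"]


@dataclass(frozen=True)
class PermutationResult:
    null_means: tuple[float, ...]
    observed_mean: float | None
    n_selected: int
    n_perm: int
    p_value: float | None
    seed: int


def permute_mean_errors(
    stats: Sequence[LocusStats],
    n_selected: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Build the null distribution of subset mean error rates.

    Draws are uniform without replacement within a permutation and
    independent across permutations; fully reproducible from ``seed``.
    The returned result has no observed mean or p-value yet (see
    :func:`permutation_test`).
    """
    rates = np.array(
        [s.error_rate for s in stats if s.comparisons > 0], dtype=float
    )
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not 0 < n_selected <= rates.size:
        raise ValidationError(
            f"n_selected must be in 1..{rates.size} (loci with defined error rate), "
            f"got {n_selected}"
        )
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        null[i] = rng.choice(rates, size=n_selected, replace=False).mean()
    return PermutationResult(
        null_means=tuple(float(v) for v in null),
        observed_mean=None,
        n_selected=n_selected,
        n_perm=n_perm,
        p_value=None,
        seed=seed,
    )


def permutation_p_value(null_means: Sequence[float], observed_mean: float) -> float:
    """p = (1 + #{null mean <= observed}) / (n_perm + 1).

    "Equal or lower" null means count against the observed reduction;
    the add-one numerator/denominator keep p in (0, 1] so 1000
    permutations with no null mean at or below the observed value give
    p ≈ 0.001.
    """
    null = np.asarray(null_means, dtype=float)
    if null.size == 0:
        raise ValidationError("null_means must be non-empty")
    return float((1 + np.count_nonzero(null <= observed_mean)) / (null.size + 1))


def permutation_test(
    stats: Sequence[LocusStats],
    n_selected: int,
    observed_mean: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Null distribution plus p-value for an observed subset mean error."""
    base = permute_mean_errors(stats, n_selected, n_perm=n_perm, seed=seed)
    p = permutation_p_value(base.null_means, observed_mean)
    return PermutationResult(
        null_means=base.null_means,
        observed_mean=float(observed_mean),
        n_selected=n_selected,
        n_perm=n_perm,
        p_value=p,
        seed=seed,
    )
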