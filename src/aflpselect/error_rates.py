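"""Replicate-based genotyping-error statistics.

With dominant markers only the band phenotype is observable, so the
genotyping error rate of a locus is estimated by comparing rows that
re-genotype the same individual: the per-locus error rate is the number of
replicate pairs whose calls disagree divided by the number of pairs in
which both calls were scored.  The present-allele frequency of a locus is
the fraction of (uniquely counted) individuals showing the band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .matrix import MarkerMatrix, ReplicateSet

__all__ = [
    "LocusStats",
    "locus_error_rates",
    "present_allele_frequency",
    "mean_error_rate",
    "stats_to_frame",
    "frame_to_stats",
    "read_locus_stats",
    "write_locus_stats",
]


@dataclass(frozen=True)
class LocusStats:
    """Per-locus summary feeding the threshold regression.

    ``present_freq`` is the regression abscissa (frequency of the present
    phenotype among counted individuals); ``error_rate`` the ordinate
    (replicate mismatches / comparisons).  Either is ``None`` when its
    denominator is zero.
    """

    locus_id: str
    present_freq: float | None
    mismatches: int
    comparisons: int

    @property
    def error_rate(self) -> float | None:
        if self.comparisons == 0:
            return None
        return self.mismatches / self.comparisons

    @property
    def defined(self) -> bool:
        return self.comparisons > 0 and self.present_freq is not None


def _pair_indices(m: MarkerMatrix, reps: ReplicateSet) -> tuple[np.ndarray, np.ndarray]:
    reps.validate_against(m)
    ia = np.array([m.sample_index(a) for a, _ in reps.pairs], dtype=int)
    ib = np.array([m.sample_index(b) for _, b in reps.pairs], dtype=int)
    return ia, ib


def locus_error_rates(m: MarkerMatrix, reps: ReplicateSet) -> list[LocusStats]:
    """Per-locus mismatch counts, comparison counts and frequencies.

    A replicate pair contributes a comparison at a locus only when both
    members carry a non-missing call there; pairs with a missing call are
    skipped rather than imputed.  Frequencies come from
    :func:`present_allele_frequency` (each individual counted once).
    """
    ia, ib = _pair_indices(m, reps)
    a = m.calls[ia, :]
    b = m.calls[ib, :]
    both = ~np.isnan(a) & ~np.isnan(b)
    comparisons = both.sum(axis=0)
    mismatches = ((a != b) & both).sum(axis=0)
    freqs = present_allele_frequency(m, reps)
    return [
        LocusStats(l, f, int(mm), int(cc))
        for l, f, mm, cc in zip(m.locus_ids, freqs, mismatches, comparisons)
    ]


def present_allele_frequency(
    m: MarkerMatrix, reps: ReplicateSet | None = None
) -> list[float | None]:
    """Fraction of individuals showing the present phenotype, per locus.

    The second member of each replicate pair is excluded so replicated
    individuals are not double-counted; the frequency at a locus is
    present calls / non-missing calls among the remaining rows.  ``None``
    where no counted call is non-missing.
    """
    if reps is not None:
        reps.validate_against(m)
        partners = set(reps.partners)
        rows = [i for i, s in enumerate(m.sample_ids) if s not in partners]
    else:
        rows = list(range(m.n_samples))
    sub = m.calls[rows, :]
    n_present = (sub == 1.0).sum(axis=0)
    n_called = (~np.isnan(sub)).sum(axis=0)
    return [
        (float(p) / c if c > 0 else None) for p, c in zip(n_present, n_called)
    ]


def mean_error_rate(stats: Sequence[LocusStats]) -> tuple[float, int]:
    """Unweighted mean of the defined per-locus error rates.

    Returns ``(mean, n_excluded)`` where ``n_excluded`` counts loci with
    zero comparisons, which enter neither numerator nor denominator.
    """
    if len(stats) == 0:
        raise ValidationError("mean_error_rate needs at least one locus")
    rates = [s.error_rate for s in stats if s.comparisons > 0]
    n_excluded = len(stats) - len(rates)
    if not rates:
        raise ValidationError("no locus has a defined error rate")
    return float(np.mean(rates)), n_excluded


# ---------------------------------------------------------------------------
# Tabular form
# ---------------------------------------------------------------------------

_COLS = ["locus_id", "present_freq", "mismatches", "comparisons", "error_rate"]


def stats_to_frame(stats: Sequence[LocusStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [s.locus_id for s in stats],
            "present_freq": [s.present_freq for s in stats],
            "mismatches": [s.mismatches for s in stats],
            "comparisons": [s.comparisons for s in stats],
            "error_rate": [s.error_rate for s in stats],
        }
    )


def frame_to_stats(df: pd.DataFrame) -> list[LocusStats]:
    out = []
    for _, r in df.iterrows():
        freq = None if pd.isna(r["present_freq"]) else float(r["present_freq"])
        out.append(
            LocusStats(str(r["locus_id"]), freq, int(r["mismatches"]), int(r["comparisons"]))
        )
    return out


def write_locus_stats(stats: Sequence[LocusStats], path: str | Path) -> None:
    stats_to_frame(stats).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_locus_stats(path: str | Path) -> list[LocusStats]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(_COLS[:-1]) - set(df.columns)
    if missing:
        raise ValidationError(f"locus stats file lacks columns: {sorted(missing)}")
    return frame_to_stats(df)
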