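"""Dominant marker matrices, replicate pairings and sample hierarchies.

A :class:`MarkerMatrix` holds presence/absence calls for dominant markers
(AFLP fragment bins scored 1 = fragment present, 0 = absent) as a float
array with ``nan`` marking missing calls.  All downstream statistics
consume this object.  Replicate re-genotypings of the same individual are
described by a :class:`ReplicateSet`; the population/group structure used
by AMOVA by a :class:`Hierarchy`.

Two on-disk dialects are supported:

``native-tsv``
    First row = locus ids, first column = sample ids, cells ``1``/``0``/
    missing code (default ``NA``).  Diff-able and spreadsheet-friendly.
``genalex-csv``
    The binary (dominant) GenAlEx layout: one header line with counts
    ``n_loci,n_samples,n_pops,<pop sizes...>``, one title line, then one
    row per sample ``sample,population,calls...`` with missing coded as
    ``-1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import StructuralError, ValidationError

__all__ = [
    "MarkerMatrix",
    "ReplicateSet",
    "Hierarchy",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_replicate_pairs",
    "write_replicate_pairs",
    "read_hierarchy",
    "write_hierarchy",
    "filter_rare_loci",
    "filter_monomorphic",
    "screen_negative_controls",
    "drop_replicate_partners",
]

MISSING = np.nan
_NATIVE_MISSING = "NA"
_GENALEX_MISSING = "-1"


@dataclass(frozen=True)
class MarkerMatrix:
    """Samples x loci matrix of dominant-marker calls.

    Parameters
    ----------
    calls
        Float array of shape ``(n_samples, n_loci)`` whose entries are
        0.0 (absent), 1.0 (present) or ``nan`` (missing).
    sample_ids, locus_ids
        Unique ordered labels for rows and columns.
    """

    calls: np.ndarray
    sample_ids: tuple[str, ...]
    locus_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=float)
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "locus_ids", tuple(str(l) for l in self.locus_ids))
        if calls.ndim != 2:
            raise ValidationError("calls must be a 2-D array")
        if calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise StructuralError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise StructuralError("duplicate locus ids")
        finite = calls[~np.isnan(calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0))][0]
            raise ValidationError(f"calls must be 0, 1 or missing; found {bad!r}")

    # -- convenience ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample id {sample_id!r}") from None

    def take_samples(self, ids: Sequence[str]) -> "MarkerMatrix":
        idx = [self.sample_index(s) for s in ids]
        return MarkerMatrix(self.calls[idx, :], tuple(ids), self.locus_ids)

    def take_loci(self, ids: Sequence[str]) -> "MarkerMatrix":
        pos = {l: i for i, l in enumerate(self.locus_ids)}
        try:
            idx = [pos[l] for l in ids]
        except KeyError as exc:
            raise ValidationError(f"unknown locus id {exc.args[0]!r}") from None
        return MarkerMatrix(self.calls[:, idx], self.sample_ids, tuple(ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=list(self.sample_ids), columns=list(self.locus_ids)
        )

    def equals(self, other: "MarkerMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls, equal_nan=True)
        )


@dataclass(frozen=True)
class ReplicateSet:
    """Pairs of matrix rows that independently re-genotype one individual.

    The first member of a pair is treated as the individual's primary row;
    the second is the replicate used only for error estimation.  A sample
    id may appear in at most one pair.
    """

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        pairs = tuple((str(a), str(b)) for a, b in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        seen: set[str] = set()
        for a, b in pairs:
            if a == b:
                raise ValidationError(f"pair ({a!r}, {b!r}) repeats one sample")
            for s in (a, b):
                if s in seen:
                    raise ValidationError(f"sample {s!r} appears in more than one pair")
                seen.add(s)

    def __len__(self) -> int:
        return len(self.pairs)

    def validate_against(self, m: MarkerMatrix) -> None:
        known = set(m.sample_ids)
        for a, b in self.pairs:
            for s in (a, b):
                if s not in known:
                    raise ValidationError(f"replicate pair references unknown sample {s!r}")

    @property
    def partners(self) -> tuple[str, ...]:
        """Second members of all pairs (rows to exclude from per-individual counts)."""
        return tuple(b for _, b in self.pairs)


@dataclass(frozen=True)
class Hierarchy:
    """Sample -> (population, group) assignment for hierarchical AMOVA."""

    assignment: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        assignment = {
            str(s): (str(p), str(g)) for s, (p, g) in dict(self.assignment).items()
        }
        object.__setattr__(self, "assignment", assignment)
        pop_group: dict[str, str] = {}
        for s, (p, g) in assignment.items():
            if pop_group.setdefault(p, g) != g:
                raise ValidationError(
                    f"population {p!r} assigned to groups {pop_group[p]!r} and {g!r}"
                )

    def population_of(self, sample_id: str) -> str:
        return self.assignment[sample_id][0]

    def group_of(self, sample_id: str) -> str:
        return self.assignment[sample_id][1]

    @property
    def populations(self) -> tuple[str, ...]:
        seen = dict.fromkeys(p for p, _ in self.assignment.values())
        return tuple(seen)

    @property
    def groups(self) -> tuple[str, ...]:
        seen = dict.fromkeys(g for _, g in self.assignment.values())
        return tuple(seen)

    def validate_against(self, m: MarkerMatrix, exclude: Iterable[str] = ()) -> None:
        """Every matrix sample outside ``exclude`` must be assigned."""
        excluded = set(exclude)
        for s in m.sample_ids:
            if s not in excluded and s not in self.assignment:
                raise ValidationError(f"sample {s!r} has no hierarchy assignment")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_cell(token: str, missing_code: str, row: str, col: str) -> float:
    token = token.strip()
    if token == missing_code or token == "":
        return MISSING
    if token == "1":
        return 1.0
    if token == "0":
        return 0.0
    raise ValidationError(
        f"unparseable call {token!r} at sample {row!r}, locus {col!r} "
        f"(expected 0, 1 or {missing_code!r})"
    )


def read_marker_matrix(
    path: str | Path,
    dialect: str = "native-tsv",
    missing_code: str | None = None,
) -> MarkerMatrix:
    """Read a marker matrix from disk.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"native-tsv"`` or ``"genalex-csv"`` (see module docstring).
    missing_code
        Token denoting a missing call; defaults to ``"NA"`` for the native
        dialect and ``"-1"`` for GenAlEx.

    Returns
    -------
    MarkerMatrix
        Validated matrix.  For the GenAlEx dialect the population column
        is discarded (populations live in a :class:`Hierarchy`).
    """
    path = Path(path)
    if dialect == "native-tsv":
        return _read_native(path, missing_code or _NATIVE_MISSING)
    if dialect == "genalex-csv":
        return _read_genalex(path, missing_code or _GENALEX_MISSING)
    raise ValidationError(f"unknown dialect {dialect!r}")


def _split_lines(path: Path, sep: str) -> list[list[str]]:
    text = path.read_text()
    rows = [line.split(sep) for line in text.splitlines() if line.strip() != ""]
    if not rows:
        raise StructuralError(f"{path}: empty file")
    return rows


def _read_native(path: Path, missing_code: str) -> MarkerMatrix:
    rows = _split_lines(path, "\t")
    header = rows[0]
    locus_ids = [c.strip() for c in header[1:]]
    if len(rows) < 2:
        raise StructuralError(f"{path}: header only, no sample rows")
    sample_ids: list[str] = []
    data: list[list[float]] = []
    for r in rows[1:]:
        if len(r) != len(locus_ids) + 1:
            raise StructuralError(
                f"{path}: ragged row for sample {r[0]!r} "
                f"({len(r) - 1} cells, expected {len(locus_ids)})"
            )
        sid = r[0].strip()
        sample_ids.append(sid)
        data.append(
            [_parse_cell(tok, missing_code, sid, loc) for tok, loc in zip(r[1:], locus_ids)]
        )
    return MarkerMatrix(np.array(data, dtype=float), tuple(sample_ids), tuple(locus_ids))


def _read_genalex(path: Path, missing_code: str) -> MarkerMatrix:
    rows = _split_lines(path, ",")
    if len(rows) < 3:
        raise StructuralError(f"{path}: GenAlEx file needs 2 header lines plus data")
    counts = rows[0]
    try:
        n_loci, n_samples = int(counts[0]), int(counts[1])
    except (ValueError, IndexError):
        raise StructuralError(f"{path}: first line must start 'n_loci,n_samples,n_pops'")
    title = rows[1]
    locus_ids = [c.strip() for c in title[2 : 2 + n_loci]]
    if len(locus_ids) != n_loci or any(l == "" for l in locus_ids):
        locus_ids = [f"L{i + 1}" for i in range(n_loci)]
    sample_ids: list[str] = []
    data: list[list[float]] = []
    for r in rows[2:]:
        if len(r) != n_loci + 2:
            raise StructuralError(
                f"{path}: ragged row for sample {r[0]!r} "
                f"({len(r) - 2} cells, expected {n_loci})"
            )
        sid = r[0].strip()
        sample_ids.append(sid)
        data.append(
            [_parse_cell(tok, missing_code, sid, loc) for tok, loc in zip(r[2:], locus_ids)]
        )
    if len(sample_ids) != n_samples:
        raise StructuralError(
            f"{path}: header declares {n_samples} samples, found {len(sample_ids)}"
        )
    return MarkerMatrix(np.array(data, dtype=float), tuple(sample_ids), tuple(locus_ids))


def write_marker_matrix(
    m: MarkerMatrix,
    path: str | Path,
    dialect: str = "native-tsv",
    hierarchy: Hierarchy | None = None,
    missing_code: str | None = None,
    title: str = "aflpselect export",
) -> None:
    """Write a marker matrix.

    For ``genalex-csv`` a :class:`Hierarchy` supplies the population
    column; without one every sample is written to population ``pop1``.
    Round-trips through :func:`read_marker_matrix` cell-for-cell.
    """
    path = Path(path)
    if dialect == "native-tsv":
        code = missing_code or _NATIVE_MISSING
        lines = ["\t".join(["sample", *m.locus_ids])]
        for sid, row in zip(m.sample_ids, m.calls):
            cells = [code if np.isnan(v) else str(int(v)) for v in row]
            lines.append("\t".join([sid, *cells]))
    elif dialect == "genalex-csv":
        code = missing_code or _GENALEX_MISSING
        pops = [
            hierarchy.population_of(s) if hierarchy is not None else "pop1"
            for s in m.sample_ids
        ]
        pop_order = list(dict.fromkeys(pops))
        sizes = [str(pops.count(p)) for p in pop_order]
        lines = [
            ",".join([str(m.n_loci), str(m.n_samples), str(len(pop_order)), *sizes]),
            ",".join([title, "", *m.locus_ids]),
        ]
        for sid, pop, row in zip(m.sample_ids, pops, m.calls):
            cells = [code if np.isnan(v) else str(int(v)) for v in row]
            lines.append(",".join([sid, pop, *cells]))
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


def read_replicate_pairs(path: str | Path) -> ReplicateSet:
    """Read a two-column TSV of (primary sample id, replicate sample id)."""
    rows = _split_lines(Path(path), "\t")
    pairs = []
    for r in rows:
        if r and r[0].strip().lower() in {"sample", "sample_a", "primary"}:
            continue  # optional header
        if len(r) != 2:
            raise StructuralError(f"{path}: pairs file rows need exactly 2 columns")
        pairs.append((r[0].strip(), r[1].strip()))
    return ReplicateSet(tuple(pairs))


def write_replicate_pairs(reps: ReplicateSet, path: str | Path) -> None:
    lines = ["\t".join(p) for p in reps.pairs]
    Path(path).write_text("\n".join(lines) + "\n")


def read_hierarchy(path: str | Path) -> Hierarchy:
    """Read a three-column TSV: sample_id, population_id, group_id."""
    rows = _split_lines(Path(path), "\t")
    assignment = {}
    for r in rows:
        if r and r[0].strip().lower() in {"sample", "sample_id"}:
            continue
        if len(r) != 3:
            raise StructuralError(f"{path}: hierarchy rows need exactly 3 columns")
        assignment[r[0].strip()] = (r[1].strip(), r[2].strip())
    return Hierarchy(assignment)


def write_hierarchy(h: Hierarchy, path: str | Path) -> None:
    lines = ["\t".join([s, p, g]) for s, (p, g) in h.assignment.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pre-filters
# ---------------------------------------------------------------------------

def filter_rare_loci(m: MarkerMatrix, min_present: int = 3) -> MarkerMatrix:
    """Drop loci with fewer than ``min_present`` present (=1) calls overall.

    Rare fragment bins carry almost no information and are dominated by
    scoring noise, so they are removed before any error analysis.
    """
    if min_present < 0:
        raise ValidationError("min_present must be >= 0")
    present = np.nansum(m.calls == 1.0, axis=0)
    keep = [l for l, c in zip(m.locus_ids, present) if c >= min_present]
    return m.take_loci(keep)


def filter_monomorphic(m: MarkerMatrix) -> MarkerMatrix:
    """Drop loci whose non-missing calls are all 1 or all 0.

    Loci with no non-missing calls at all are vacuously monomorphic and
    also removed, so every surviving locus has a defined frequency.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
        n_present = (m.calls == 1.0).sum(axis=0)
        n_absent = (m.calls == 0.0).sum(axis=0)
    keep = [
        l
        for l, p, a in zip(m.locus_ids, n_present, n_absent)
        if p > 0 and a > 0
    ]
    return m.take_loci(keep)


def screen_negative_controls(
    m: MarkerMatrix,
    control_ids: Sequence[str],
    min_similarity: float = 0.9,
) -> MarkerMatrix:
    """Remove samples whose banding pattern resembles a negative control.

    Optional screen, off by default in the pipeline.  Similarity is the
    Dice coefficient of the present-call sets (2|A∩B| / (|A|+|B|)); a
    non-control sample is removed when its similarity with *any* control
    exceeds ``min_similarity``.  Control rows themselves are always
    removed.  The criterion is a pragmatic choice of this package, not a
    community standard, and is logged when the screen drops anything.
    """
    if not 0.0 <= min_similarity <= 1.0:
        raise ValidationError("min_similarity must be in [0, 1]")
    known = set(m.sample_ids)
    for c in control_ids:
        if c not in known:
            raise ValidationError(f"control sample {c!r} not in matrix")
    controls = set(control_ids)

    def present_set(sid: str) -> np.ndarray:
        return m.calls[m.sample_index(sid), :] == 1.0

    control_sets = {c: present_set(c) for c in controls}
    kept = []
    dropped = []
    for sid in m.sample_ids:
        if sid in controls:
            continue
        mine = present_set(sid)
        similar = False
        for cset in control_sets.values():
            denom = mine.sum() + cset.sum()
            dice = 2.0 * (mine & cset).sum() / denom if denom else 1.0
            if dice > min_similarity:
                similar = True
                break
        if similar:
            dropped.append(sid)
        else:
            kept.append(sid)
    if dropped:
        warnings.warn(
            f"negative-control screen removed {len(dropped)} sample(s) "
            f"(Dice > {min_similarity}): {', '.join(dropped[:5])}"
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
    return m.take_samples(kept)


def drop_replicate_partners(m: MarkerMatrix, reps: ReplicateSet) -> MarkerMatrix:
    """Return the matrix with the second member of every replicate pair removed,
    so each individual contributes exactly one row (required before AMOVA)."""
    reps.validate_against(m)
    partners = set(reps.partners)
    return m.take_samples([s for s in m.sample_ids if s not in partners])
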