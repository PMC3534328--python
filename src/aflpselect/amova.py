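"""Hierarchical analysis of molecular variance (AMOVA) for binary markers.

Partitions the squared-Euclidean variation among pairwise sample
distances into three nested strata — among groups, among populations
within groups, and among individuals within populations — and expresses
each stratum as a variance component and a Phi-statistic (the
dominant-marker analogue of F-statistics).  Sums of squares come from
the pairwise-distance identity ``SS(S) = sum_{i<j in S} d2(i,j) / |S|``;
variance components are solved from the expected mean squares with
unbalanced-design coefficients derived from the group/population sizes.
Significance is assessed by label permutation.

For complete binary data the squared distance between two samples is the
number of loci at which their calls differ; with missing calls the raw
mismatch count over jointly scored loci is rescaled by
``n_loci / n_jointly_scored`` so heavily missing pairs are not deflated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .matrix import Hierarchy, MarkerMatrix, ReplicateSet

__all__ = [
    "AmovaResult",
    "squared_distance_matrix",
    "amova_three_level",
    "amova_permutation_pvalues",
]


@dataclass(frozen=True)
class AmovaResult:
    """Three-level AMOVA table.

    Variance components are reported raw (``var_raw``) and with negative
    estimates truncated to zero (``var_components``); percentages and
    Phi-statistics use the truncated values, the convention of common
    AMOVA software.  ``phi_rt`` = among-group share of total variance,
    ``phi_pr`` = among-population share of the within-group variance,
    ``phi_pt`` = combined among-strata share.  Degenerate inputs (zero
    total variance) report 100% within populations and NaN Phi.
    """

    ss_among_groups: float
    ss_among_pops_within_groups: float
    ss_within_pops: float
    ss_total: float
    df: tuple[int, int, int]
    var_raw: tuple[float, float, float]
    var_components: tuple[float, float, float]
    pct_variance: tuple[float, float, float]
    phi_rt: float
    phi_pr: float
    phi_pt: float
    p_values: tuple[float, float, float] | None
    n_perm: int
    n_samples: int
    n_populations: int
    n_groups: int
    two_level: bool = False


def squared_distance_matrix(m: MarkerMatrix) -> np.ndarray:
    """Missing-rescaled squared distances between all sample pairs.

    ``d2(i,j) = (# jointly scored loci with differing calls) * L / L_ij``
    with ``L`` the locus count and ``L_ij`` the jointly scored count.
    Raises when a pair shares no scored locus.
    """
    if m.n_samples < 2 or m.n_loci < 1:
        raise ValidationError("need >= 2 samples and >= 1 locus for distances")
    present = (m.calls == 1.0).astype(float)
    absent = (m.calls == 0.0).astype(float)
    scored = (~np.isnan(m.calls)).astype(float)
    mismatch = present @ absent.T + absent @ present.T
    joint = scored @ scored.T
    off = ~np.eye(m.n_samples, dtype=bool)
    if np.any(joint[off] == 0):
        i, j = np.argwhere((joint == 0) & off)[0]
        raise ValidationError(
            f"samples {m.sample_ids[i]!r} and {m.sample_ids[j]!r} share no "
            "jointly scored locus; distance undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = mismatch * (m.n_loci / joint)
    np.fill_diagonal(d2, 0.0)
    return d2


def _ss_within(D: np.ndarray, idx: np.ndarray) -> float:
    """SS of a sample set from the pairwise identity (D is symmetric, zero diag)."""
    n = idx.size
    if n < 2:
        return 0.0
    return float(D[np.ix_(idx, idx)].sum() / (2.0 * n))


def _decompose(
    D: np.ndarray, pop_codes: np.ndarray, pop_group: np.ndarray
) -> tuple[float, float, float, tuple[int, int, int], tuple[float, float, float]]:
    """SS decomposition and raw variance components.

    ``pop_codes``: per-sample population code 0..P-1; ``pop_group``:
    per-population group code 0..G-1.
    """
    N = pop_codes.size
    P = pop_group.size
    G = int(pop_group.max()) + 1
    grp_codes = pop_group[pop_codes]

    ss_total = float(D.sum() / (2.0 * N))
    ss_wp = 0.0
    pop_sizes = np.bincount(pop_codes, minlength=P)
    for p in range(P):
        ss_wp += _ss_within(D, np.flatnonzero(pop_codes == p))
    ss_wg = 0.0
    grp_sizes = np.bincount(grp_codes, minlength=G)
    for g in range(G):
        ss_wg += _ss_within(D, np.flatnonzero(grp_codes == g))
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp

    df_a, df_b, df_c = G - 1, P - G, N - P
    # unbalanced expected-mean-square coefficients
    npg2_over_Ng = sum(
        float((pop_sizes[pop_group == g] ** 2).sum()) / grp_sizes[g] for g in range(G)
    )
    sum_np2 = float((pop_sizes**2).sum())
    sum_Ng2 = float((grp_sizes**2).sum())
    ms_c = ss_wp / df_c if df_c > 0 else 0.0
    sigma_c = ms_c
    if df_b > 0:
        n1 = (N - npg2_over_Ng) / df_b
        sigma_b = (ss_ap / df_b - sigma_c) / n1
    else:
        sigma_b = 0.0
    if df_a > 0:
        n2 = (npg2_over_Ng - sum_np2 / N) / df_a
        n3 = (N - sum_Ng2 / N) / df_a
        sigma_a = (ss_ag / df_a - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0
    return ss_ag, ss_ap, ss_wp, (df_a, df_b, df_c), (sigma_a, sigma_b, sigma_c)


def _codes(
    m: MarkerMatrix, h: Hierarchy
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    h.validate_against(m)
    pops = [h.population_of(s) for s in m.sample_ids]
    pop_order = list(dict.fromkeys(pops))
    pop_index = {p: i for i, p in enumerate(pop_order)}
    pop_codes = np.array([pop_index[p] for p in pops], dtype=int)
    pop_to_group: dict[str, str] = {}
    for s in m.sample_ids:
        p, g = h.assignment[s]
        pop_to_group.setdefault(p, g)
    grp_of_pop = [pop_to_group[p] for p in pop_order]
    group_order = list(dict.fromkeys(grp_of_pop))
    grp_index = {g: i for i, g in enumerate(group_order)}
    pop_group = np.array([grp_index[g] for g in grp_of_pop], dtype=int)
    return pop_codes, pop_group, pop_order, group_order


def amova_three_level(
    m: MarkerMatrix,
    h: Hierarchy,
    n_perm: int = 999,
    seed: int = 0,
    replicates: ReplicateSet | None = None,
) -> AmovaResult:
    """Three-level AMOVA with permutation p-values.

    ``replicates`` is an optional pre-flight check: AMOVA assumes one row
    per individual, so a warning is issued if any replicate pair is still
    fully present in the matrix.  With a single group the analysis falls
    back to a two-level AMOVA (among/within populations) with a warning.
    Set ``n_perm=0`` to skip the permutation test.
    """
    if replicates is not None:
        rows = set(m.sample_ids)
        if any(a in rows and b in rows for a, b in replicates.pairs):
            warnings.warn(
                "matrix still contains both members of a replicate pair; "
                "drop replicate partners before AMOVA",
                stacklevel=2,
            )
    pop_codes, pop_group, pop_order, group_order = _codes(m, h)
    P, G, N = len(pop_order), len(group_order), m.n_samples
    if P < 2:
        raise ValidationError("AMOVA needs at least 2 populations")
    two_level = G < 2
    if two_level:
        warnings.warn(
            "only one group present: falling back to two-level AMOVA "
            "(among/within populations)",
            stacklevel=2,
        )
        # every population its own 'group': among-group stratum vanishes
        pop_group_eff = np.arange(P)
    else:
        pop_group_eff = pop_group

    D = squared_distance_matrix(m)
    if two_level:
        # two-level decomposition: among pops / within pops
        ss_total = float(D.sum() / (2.0 * N))
        ss_wp = sum(_ss_within(D, np.flatnonzero(pop_codes == p)) for p in range(P))
        ss_ap = ss_total - ss_wp
        df = (0, P - 1, N - P)
        pop_sizes = np.bincount(pop_codes, minlength=P)
        sigma_c = ss_wp / df[2] if df[2] > 0 else 0.0
        n_c = (N - float((pop_sizes**2).sum()) / N) / df[1]
        sigma_b = (ss_ap / df[1] - sigma_c) / n_c
        ss_ag, sigma_a = 0.0, 0.0
        raw = (sigma_a, sigma_b, sigma_c)
    else:
        ss_ag, ss_ap, ss_wp, df, raw = _decompose(D, pop_codes, pop_group_eff)
        ss_total = ss_ag + ss_ap + ss_wp

    trunc = tuple(max(0.0, v) for v in raw)
    total_var = sum(trunc)
    if total_var <= 0.0:
        pct = (0.0, 0.0, 100.0)
        phi_rt = phi_pr = phi_pt = float("nan")
    else:
        pct = tuple(100.0 * v / total_var for v in trunc)
        phi_rt = trunc[0] / total_var if not two_level else float("nan")
        phi_pr = (
            trunc[1] / (trunc[1] + trunc[2])
            if (trunc[1] + trunc[2]) > 0
            else float("nan")
        )
        phi_pt = (trunc[0] + trunc[1]) / total_var

    p_values = None
    if n_perm >= 1:
        p_values = amova_permutation_pvalues(
            D, pop_codes, pop_group_eff, raw, n_perm=n_perm, seed=seed,
            two_level=two_level,
        )
    return AmovaResult(
        ss_among_groups=ss_ag,
        ss_among_pops_within_groups=ss_ap,
        ss_within_pops=ss_wp,
        ss_total=ss_total,
        df=df,
        var_raw=tuple(raw),
        var_components=trunc,
        pct_variance=pct,
        phi_rt=phi_rt,
        phi_pr=phi_pr,
        phi_pt=phi_pt,
        p_values=p_values,
        n_perm=n_perm if n_perm >= 1 else 0,
        n_samples=N,
        n_populations=P,
        n_groups=G,
        two_level=two_level,
    )


def _two_level_components(
    D: np.ndarray, pop_codes: np.ndarray
) -> tuple[float, float]:
    N = pop_codes.size
    P = int(pop_codes.max()) + 1
    ss_total = float(D.sum() / (2.0 * N))
    ss_wp = sum(_ss_within(D, np.flatnonzero(pop_codes == p)) for p in range(P))
    ss_ap = ss_total - ss_wp
    pop_sizes = np.bincount(pop_codes, minlength=P)
    sigma_c = ss_wp / (N - P) if N > P else 0.0
    n_c = (N - float((pop_sizes**2).sum()) / N) / (P - 1)
    sigma_b = (ss_ap / (P - 1) - sigma_c) / n_c
    return sigma_b, sigma_c


def amova_permutation_pvalues(
    D: np.ndarray,
    pop_codes: np.ndarray,
    pop_group: np.ndarray,
    observed: tuple[float, float, float],
    n_perm: int = 999,
    seed: int = 0,
    two_level: bool = False,
) -> tuple[float, float, float]:
    """Stratified-permutation p-values for the three variance components.

    Among-group component: whole populations are shuffled among groups
    (population counts per group preserved).  Among-population and
    within-population components: samples are shuffled among populations
    within their group (population sizes preserved).  Each p-value is
    ``(1 + #{permuted >= observed}) / (n_perm + 1)``.
    """
    rng = np.random.default_rng(seed)
    obs_a, obs_b, obs_c = observed
    grp_codes = pop_group[pop_codes]

    # -- within-group sample shuffles test sigma_b and sigma_c ----------
    ge_b = 0
    ge_c = 0
    if two_level:
        # single stratum: samples shuffle among all populations
        group_members = [np.arange(pop_codes.size)]
    else:
        G = int(pop_group.max()) + 1
        group_members = [np.flatnonzero(grp_codes == g) for g in range(G)]
    for _ in range(n_perm):
        perm_pop = pop_codes.copy()
        for idx in group_members:
            perm_pop[idx] = pop_codes[idx[rng.permutation(idx.size)]]
        if two_level:
            sb, sc = _two_level_components(D, perm_pop)
        else:
            *_, (_, sb, sc) = _decompose(D, perm_pop, pop_group)
        ge_b += sb >= obs_b
        ge_c += sc >= obs_c
    p_b = (1 + ge_b) / (n_perm + 1)
    p_c = (1 + ge_c) / (n_perm + 1)

    # -- population shuffles among groups test sigma_a ------------------
    if two_level:
        return (float("nan"), float(p_b), float(p_c))
    ge_a = 0
    for _ in range(n_perm):
        perm_group = pop_group[rng.permutation(pop_group.size)]
        (_, _, _, _, (sa, _, _)) = _decompose(D, pop_codes, perm_group)
        ge_a += sa >= obs_a
    p_a = (1 + ge_a) / (n_perm + 1)
    return (float(p_a), float(p_b), float(p_c))
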