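"""Synthetic replicated dominant-marker datasets with known truth.

The generator emulates a capillary-AFLP diversity study: individuals
nested in populations nested in geographic groups, scored at thousands
of presence/absence loci, with a random subset of individuals
re-genotyped once to allow replicate-based error estimation.

Model, per locus ``l``:

1. a base present-phenotype frequency ``x_l`` is drawn from a Beta
   distribution (most AFLP bands are scarce, so the Beta is
   right-skewed);
2. group- and population-level frequencies are Balding–Nichols-style
   Beta perturbations of ``x_l`` with dispersions set by two Fst-like
   divergence parameters;
3. each individual's true phenotype is Bernoulli(population frequency);
4. every observed call independently flips its true call with a per-call
   probability ``eps_l`` chosen so that the *pair mismatch* probability
   equals a quadratic curve ``q(f) = a + b f + c f^2`` (plus per-locus
   Gaussian noise, clamped to ``[0, q_max]``) evaluated at the locus's
   expected observed frequency ``f`` — the same X the downstream
   estimator measures.  Because flipping itself shifts the observed
   frequency (``f = p + eps (1 - 2 p)`` for realized phenotype frequency
   ``p``), ``f`` and ``eps`` are solved self-consistently per locus;
5. missing calls are sprinkled uniformly at ``missing_rate``.

The pair-mismatch identity ``q = 2 eps (1 - eps)`` inverts to
``eps = (1 - sqrt(1 - 2 q)) / 2`` and requires ``q <= 1/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .matrix import Hierarchy, MarkerMatrix, ReplicateSet

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_dataset",
    "large_study_config",
]

# Frozen by a one-off pilot run (see docs/methods.md): Beta shape of base
# frequencies and the error-noise scale that together give a large study
# dataset with mean present frequency ~0.17 and mean error rate ~0.125
# under the quadratic error curve below.
_PAPER_LIKE_BETA = (0.32, 2.60)
_PAPER_LIKE_NOISE_SD = 0.02


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for :func:`simulate_dataset`."""

    n_groups: int = 3
    pops_per_group: int | tuple[int, ...] = 4
    samples_per_pop: int = 5
    n_loci: int = 500
    replicate_fraction: float = 0.176
    n_replicates: int | None = None
    freq_beta: tuple[float, float] = (0.32, 2.60)
    divergence: tuple[float, float] = (0.03, 0.07)
    error_curve: tuple[float, float, float] = (0.0053, 1.18, -1.11)
    error_noise_sd: float = 0.02
    q_max: float = 0.49
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        ppg = self.pops_per_group
        ppg = (ppg,) * self.n_groups if isinstance(ppg, int) else tuple(ppg)
        object.__setattr__(self, "pops_per_group", ppg)
        if len(ppg) != self.n_groups:
            raise ValidationError("pops_per_group length must equal n_groups")
        if self.n_groups < 1 or min(ppg) < 1 or self.samples_per_pop < 1 or self.n_loci < 1:
            raise ValidationError("counts must be >= 1")
        for name, v in [
            ("replicate_fraction", self.replicate_fraction),
            ("missing_rate", self.missing_rate),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0.0 < self.q_max <= 0.5:
            raise ValidationError("q_max must be in (0, 0.5]")
        if not 0.0 <= min(self.divergence) and max(self.divergence) < 1.0:
            raise ValidationError("divergence parameters must be in [0, 1)")
        if self.error_noise_sd < 0:
            raise ValidationError("error_noise_sd must be >= 0")

    @property
    def n_populations(self) -> int:
        return int(sum(self.pops_per_group))

    @property
    def n_individuals(self) -> int:
        return self.n_populations * self.samples_per_pop


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth emitted alongside the observable dataset."""

    base_freq: np.ndarray          # (n_loci,) Beta draws x_l
    pop_freq: np.ndarray           # (n_populations, n_loci) realized pop frequencies
    expected_obs_freq: np.ndarray  # (n_loci,) fixed-point f_l
    mismatch_prob: np.ndarray      # (n_loci,) true pair-mismatch probability q_l
    flip_prob: np.ndarray          # (n_loci,) per-call flip probability eps_l
    genotypes: np.ndarray          # (n_individuals, n_loci) true 0/1 phenotypes


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    """Beta perturbation of frequencies with dispersion ``fst``."""
    if fst <= 0.0:
        return p.copy()
    scale = (1.0 - fst) / fst
    return rng.beta(np.maximum(p * scale, 1e-9), np.maximum((1.0 - p) * scale, 1e-9))


def _solve_flip_prob(
    p_hat: np.ndarray,
    curve: tuple[float, float, float],
    noise: np.ndarray,
    q_max: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed point of f = p + eps(f)(1 - 2p) with 2 eps (1 - eps) = q(f) + noise."""
    a, b, c = curve
    f = p_hat.copy()
    for _ in range(50):
        q = np.clip(a + b * f + c * f * f + noise, 0.0, q_max)
        eps = 0.5 * (1.0 - np.sqrt(1.0 - 2.0 * q))
        f_new = p_hat + eps * (1.0 - 2.0 * p_hat)
        if np.allclose(f_new, f, atol=1e-12):
            f = f_new
            break
        f = f_new
    q = np.clip(a + b * f + c * f * f + noise, 0.0, q_max)
    if np.any(q > 0.5):
        raise ValidationError("pair-mismatch probability exceeds 0.5; lower q_max")
    eps = 0.5 * (1.0 - np.sqrt(1.0 - 2.0 * q))
    return f, q, eps


def simulate_dataset(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[MarkerMatrix, ReplicateSet, Hierarchy, SimulationTruth]:
    """Draw one complete dataset; reproducible from ``seed`` (default ``cfg.seed``)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    L = cfg.n_loci
    n_ind = cfg.n_individuals

    # (1) base frequencies
    x = np.clip(rng.beta(*cfg.freq_beta, size=L), 1e-6, 1.0 - 1e-6)

    # (2) hierarchical frequency perturbations
    f_group, f_pop = cfg.divergence
    pop_freq = np.empty((cfg.n_populations, L))
    pop_labels: list[tuple[str, str]] = []  # (pop_id, group_id) per population
    p_idx = 0
    for g, npops in enumerate(cfg.pops_per_group):
        g_id = f"G{g + 1}"
        gfreq = _balding_nichols(rng, x, f_group)
        for _ in range(npops):
            pop_id = f"{g_id}-P{p_idx + 1:02d}"
            pop_freq[p_idx] = _balding_nichols(rng, gfreq, f_pop)
            pop_labels.append((pop_id, g_id))
            p_idx += 1

    # (3) true phenotypes
    genotypes = np.empty((n_ind, L))
    ind_pop = np.repeat(np.arange(cfg.n_populations), cfg.samples_per_pop)
    for p in range(cfg.n_populations):
        rows = np.flatnonzero(ind_pop == p)
        genotypes[rows] = (rng.random((rows.size, L)) < pop_freq[p]).astype(float)

    # (4) flip probabilities from the error curve at the expected observed frequency
    p_hat = genotypes.mean(axis=0)
    noise = rng.normal(0.0, cfg.error_noise_sd, size=L) if cfg.error_noise_sd else np.zeros(L)
    f_exp, q, eps = _solve_flip_prob(p_hat, cfg.error_curve, noise, cfg.q_max)

    # replicated individuals
    if cfg.n_replicates is not None:
        n_rep = int(cfg.n_replicates)
    else:
        n_rep = int(round(cfg.replicate_fraction * n_ind))
    if n_rep > n_ind:
        raise ValidationError("more replicates requested than individuals")
    rep_rows = np.sort(rng.choice(n_ind, size=n_rep, replace=False))

    def observe(rows: np.ndarray) -> np.ndarray:
        flips = rng.random((rows.size, L)) < eps
        return np.abs(genotypes[rows] - flips.astype(float))

    observed_primary = observe(np.arange(n_ind))
    observed_rep = observe(rep_rows)

    # (5) missingness
    calls = np.vstack([observed_primary, observed_rep])
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = np.nan

    ind_ids = [
        f"{pop_labels[ind_pop[i]][0]}-I{i + 1:04d}" for i in range(n_ind)
    ]
    rep_ids = [f"{ind_ids[i]}-rep" for i in rep_rows]
    sample_ids = tuple(ind_ids + rep_ids)
    locus_ids = tuple(f"L{j + 1:04d}" for j in range(L))
    matrix = MarkerMatrix(calls, sample_ids, locus_ids)
    reps = ReplicateSet(tuple((ind_ids[i], f"{ind_ids[i]}-rep") for i in rep_rows))
    assignment = {
        sid: pop_labels[ind_pop[i]] for i, sid in enumerate(ind_ids)
    }
    for i, rid in zip(rep_rows, rep_ids):
        assignment[rid] = pop_labels[ind_pop[i]]
    hierarchy = Hierarchy(assignment)
    truth = SimulationTruth(
        base_freq=x,
        pop_freq=pop_freq,
        expected_obs_freq=f_exp,
        mismatch_prob=q,
        flip_prob=eps,
        genotypes=genotypes,
    )
    return matrix, reps, hierarchy, truth


def large_study_config(seed: int = 0) -> SimulationConfig:
    """Frozen configuration emulating a large AFLP diversity study.

    Three geographic groups, 88 populations of 5 plants (440 individuals),
    81 replicated individuals, 2711 loci, and a rise-and-fall quadratic
    error-vs-frequency curve, sized so the emitted matrix has a mean
    present-phenotype frequency near 0.17 and a mean replicate error rate
    near 0.125.
    """
    return SimulationConfig(
        n_groups=3,
        pops_per_group=(30, 29, 29),
        samples_per_pop=5,
        n_loci=2711,
        n_replicates=81,
        freq_beta=_PAPER_LIKE_BETA,
        divergence=(0.03, 0.07),
        error_curve=(0.0053, 1.18, -1.11),
        error_noise_sd=_PAPER_LIKE_NOISE_SD,
        q_max=0.49,
        missing_rate=0.0,
        seed=seed,
    )
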