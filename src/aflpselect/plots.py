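"""Optional plotting helpers (requires matplotlib).

Two diagnostic figures: the error-vs-frequency scatter with fitted
threshold curves, and the permutation-null histogram with the observed
mean marked.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .error_rates import LocusStats
from .threshold import ThresholdModel


def plot_error_vs_frequency(
    stats: Sequence[LocusStats],
    models: Sequence[ThresholdModel] = (),
    ax=None,
):
    """Scatter locus error rate against present-allele frequency, with
    the fitted (clamped) threshold curve of each selection round."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    usable = [s for s in stats if s.defined]
    x = [s.present_freq for s in usable]
    y = [s.error_rate for s in usable]
    ax.scatter(x, y, s=6, alpha=0.4, linewidths=0, color="0.3")
    grid = np.linspace(0, 1, 200)
    for i, mod in enumerate(models, start=1):
        ax.plot(grid, mod.predict(grid), label=f"round {i} (R$^2$={mod.r_squared:.2f})")
    ax.set_xlabel("frequency of present alleles")
    ax.set_ylabel("locus error rate")
    if models:
        ax.legend(frameon=False)
    return ax


def plot_permutation_null(null_means: Sequence[float], observed_mean: float, ax=None):
    """Histogram of random-subset mean error rates with the observed mean."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(np.asarray(null_means), bins=30, color="0.6")
    ax.axvline(observed_mean, color="crimson", label="observed")
    ax.set_xlabel("mean error rate of random locus subset")
    ax.set_ylabel("permutations")
    ax.legend(frameon=False)
    return ax
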