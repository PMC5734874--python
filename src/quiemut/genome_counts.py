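"""Chi-square test of Poisson homogeneity for per-genome mutation counts.

If a single mutational force acts uniformly on all genomes, the number of
mutations per genome is Poisson.  The test fits the mean, bins the counts
(merging the right tail until every expected frequency reaches 5), and
compares observed with expected frequencies by chi-square with one degree of
freedom subtracted for the estimated mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["GenomeCountSet", "poisson_gof"]

_MIN_EXPECTED = 5.0


@dataclass
class GenomeCountSet:
    """Per-genome mutation counts with the Poisson goodness-of-fit result.

    ``bins`` maps a label ('0', '1', ..., '>=j') to (observed, expected).
    ``p_value`` is NaN when the test is degenerate (fewer than 2 bins after
    merging, or zero variance input); ``warning`` then says why.
    """

    counts: list[int]
    lambda_hat: float
    chi2: float = math.nan
    df: int = 0
    p_value: float = math.nan
    bins: dict[str, tuple[int, float]] = field(default_factory=dict)
    warning: str = ""

    @property
    def n(self) -> int:
        return len(self.counts)


def poisson_gof(counts: Sequence[int]) -> GenomeCountSet:
    """Test whether integer counts are consistent with a Poisson distribution.

    lambda is estimated by the sample mean.  Bins 0, 1, 2, ... are kept
    separate while their expected frequency is at least 5 and the remaining
    right tail also expects at least 5; everything beyond is merged into one
    tail bin.  df = #bins - 2 (one for the total, one for the fitted mean).

    Raises
    ------
    ValueError
        On empty input or negative/non-integer counts.
    """
    arr = np.asarray(list(counts))
    if arr.size == 0:
        raise ValueError("empty input: no genome counts")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("counts must be integers")
        arr = arr.astype(int)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    n = arr.size
    if n < 10:
        warnings.warn(f"only {n} genomes; the chi-square approximation is poor")
    lam = float(arr.mean())
    result = GenomeCountSet(counts=arr.tolist(), lambda_hat=lam)
    if lam == 0:
        result.warning = "all counts are zero; single degenerate bin, test undefined"
        result.bins = {"0": (n, float(n))}
        return result

    # Singleton bins from the left while both the bin and the remaining tail
    # expect >= 5; then one merged right-tail bin.
    edges: list[int] = []
    j = 0
    while True:
        exp_j = n * stats.poisson.pmf(j, lam)
        exp_tail = n * stats.poisson.sf(j, lam)
        if exp_j < _MIN_EXPECTED or exp_tail < _MIN_EXPECTED:
            break
        edges.append(j)
        j += 1
    n_bins = len(edges) + 1  # + merged tail ">= j"
    observed = np.array(
        [np.sum(arr == e) for e in edges] + [np.sum(arr >= j)], dtype=float
    )
    expected = np.array(
        [n * stats.poisson.pmf(e, lam) for e in edges] + [n * stats.poisson.sf(j - 1, lam)]
    )
    labels = [str(e) for e in edges] + [f">={j}"]
    result.bins = {
        lab: (int(o), float(e)) for lab, o, e in zip(labels, observed, expected)
    }
    df = n_bins - 2
    if df < 1:
        result.warning = (
            f"only {n_bins} bin(s) after merging; no degrees of freedom left"
        )
        return result
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    result.chi2 = chi2
    result.df = df
    result.p_value = float(stats.chi2.sf(chi2, df))
    return result
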