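import itertools
from collections import Counter

import numpy as np
import pytest

from quiemut.spectrum import MutationRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def enumeration_probability(counts: dict[int, int], k: int) -> float:
    """Independent oracle for the occupancy likelihood.

    Enumerates all k^m equally likely assignments of m labeled hits to k
    labeled targets and returns the fraction whose hits-per-target histogram
    (zeros excluded) equals ``counts``.  Exponential: only for tiny m, k.
    """
    m = sum(i * c for i, c in counts.items())
    target_hist = {i: c for i, c in counts.items() if c > 0}
    matches = 0
    for assignment in itertools.product(range(k), repeat=m):
        tally = Counter(assignment)
        hist = Counter(tally.values())
        if dict(hist) == target_hist:
            matches += 1
    return matches / k**m


def all_k_distributions(max_m: int):
    """Every hits-per-target histogram with total hits m <= max_m."""
    for m in range(1, max_m + 1):
        for partition in _partitions(m):
            yield dict(Counter(partition))


def _partitions(m: int, largest: int | None = None):
    if largest is None:
        largest = m
    if m == 0:
        yield ()
        return
    for first in range(min(m, largest), 0, -1):
        for rest in _partitions(m - first, first):
            yield (first,) + rest


def make_record(
    sample="s1",
    population="pop1",
    day=1.0,
    locus="gene",
    position=1,
    ref="C",
    alt="T",
) -> MutationRecord:
    return MutationRecord(
        sample_id=sample,
        population_id=population,
        day=day,
        locus=locus,
        position=position,
        ref=ref,
        alt=alt,
    )
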