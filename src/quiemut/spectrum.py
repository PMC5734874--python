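"""Mutation records, SNV classification and spectrum summaries.

Observed mutations are represented as :class:`MutationRecord` objects.  The
module classifies single-nucleotide variants into strand-symmetric base-pair
change classes, removes clonal redundancy within populations, and computes the
summary statistics (Ts:Tv, AT bias, indel balance) used throughout the
analysis.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MutationRecord",
    "SNVClass",
    "SpectrumSummary",
    "classify_snv",
    "deduplicate",
    "summarize_spectrum",
    "bin_indel_sizes",
    "PAIR_CLASSES",
    "DEFAULT_INDEL_BINS",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID = frozenset("ACGT")

#: The six strand-symmetric base-pair substitution classes.
PAIR_CLASSES = ("GC>AT", "GC>TA", "GC>CG", "AT>GC", "AT>CG", "AT>TA")

#: Default report bins for signed indel sizes: +-1, +-2-3, +-4-10, +-(>10).
DEFAULT_INDEL_BINS = ((1, 1), (2, 3), (4, 10), (11, None))


def _normalize_allele(seq: str) -> str:
    """Upper-case an allele string and map U to T; '-' means absent."""
    s = seq.strip().upper().replace("U", "T")
    if s == "-":
        return ""
    return s


@dataclass(frozen=True)
class MutationRecord:
    """One observed mutation from a sequenced isolate.

    ``ref`` and ``alt`` are nucleotide strings over {A, C, G, T}; an empty
    ``ref`` denotes a pure insertion and an empty ``alt`` a pure deletion.
    ``position`` is 1-based.  ``(population_id, locus, position, ref, alt)``
    identifies a mutation for redundancy filtering.
    """

    sample_id: str
    population_id: str
    day: float
    locus: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", _normalize_allele(self.ref))
        object.__setattr__(self, "alt", _normalize_allele(self.alt))
        self.validate()

    def validate(self) -> None:
        if self.day < 0:
            raise ValueError(f"negative day: {self.day}")
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive: {self.position}")
        if not self.ref and not self.alt:
            raise ValueError("ref and alt cannot both be empty")
        for side, allele in (("ref", self.ref), ("alt", self.alt)):
            bad = set(allele) - _VALID
            if bad:
                raise ValueError(
                    f"{side} allele {allele!r} contains non-ACGT symbols {sorted(bad)}"
                )

    @property
    def key(self) -> tuple:
        """Identity key for redundancy filtering within a population."""
        return (self.population_id, self.locus, self.position, self.ref, self.alt)

    @property
    def kind(self) -> str:
        """'snv', 'indel', or 'complex' (equal-length multi-nt substitution)."""
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snv"
        if len(self.ref) == len(self.alt):
            return "complex"
        return "indel"

    @property
    def net_size(self) -> int:
        """Signed size change: positive for insertions, negative for deletions."""
        return len(self.alt) - len(self.ref)


@dataclass(frozen=True)
class SNVClass:
    """Strand-symmetric classification of a single-nucleotide substitution."""

    is_transition: bool
    pair_class: str

    @property
    def to_at(self) -> bool:
        """True if the change moves the base pair towards A:T."""
        return self.pair_class in ("GC>AT", "GC>TA")

    @property
    def to_gc(self) -> bool:
        """True if the change moves the base pair towards G:C."""
        return self.pair_class in ("AT>GC", "AT>CG")


def classify_snv(ref: str, alt: str) -> SNVClass:
    """Classify a single-nucleotide substitution.

    Transitions are exactly A<->G and C<->T.  The pair class is
    strand-symmetric: C->T and G->A both map to ``GC>AT``.

    Raises
    ------
    ValueError
        If either base is not a single A/C/G/T or ref equals alt.
    """
    r = _normalize_allele(ref)
    a = _normalize_allele(alt)
    if len(r) != 1 or len(a) != 1 or r not in _VALID or a not in _VALID:
        raise ValueError(f"classify_snv expects single ACGT bases, got {ref!r}->{alt!r}")
    if r == a:
        raise ValueError(f"ref and alt are identical: {ref!r}")
    # Orient onto the strand where the reference base is a purine, then the
    # class label reads off directly (G->A is GC>AT, G->T is GC>TA, ...).
    if r in "CT":
        r, a = _COMPLEMENT[r], _COMPLEMENT[a]
    pair_class = f"{r}{_COMPLEMENT[r]}>{a}{_COMPLEMENT[a]}"
    is_transition = pair_class in ("GC>AT", "AT>GC")
    return SNVClass(is_transition=is_transition, pair_class=pair_class)


def deduplicate(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Collapse clonal redundancy within populations.

    Within each population, records sharing (locus, position, ref, alt) are
    collapsed to a single representative: the one with the earliest day,
    ties broken by input order.  Identical mutations in different populations
    are kept independently.
    """
    best: dict[tuple, tuple[float, int, MutationRecord]] = {}
    for idx, rec in enumerate(records):
        cand = (rec.day, idx, rec)
        prev = best.get(rec.key)
        if prev is None or cand[:2] < prev[:2]:
            best[rec.key] = cand
    kept = sorted(best.values(), key=lambda t: t[1])
    return [rec for _, _, rec in kept]


@dataclass
class SpectrumSummary:
    """Spectrum statistics for a set of mutation records.

    Ratios are NaN when their denominator is zero.  Indel sizes are signed
    (insertions positive).  Equal-length multi-nucleotide substitutions are
    tallied as ``n_complex`` and excluded from both SNV and indel statistics.
    """

    n_snv: int = 0
    n_ts: int = 0
    n_tv: int = 0
    ts_tv_ratio: float = math.nan  # reported as 1:x with x = n_tv / n_ts
    n_to_AT: int = 0
    n_to_GC: int = 0
    at_bias: float = math.nan
    n_indel: int = 0
    n_del: int = 0
    n_ins: int = 0
    bases_lost: int = 0
    bases_gained: int = 0
    net_loss: int = 0
    del_ins_ratio: float = math.nan
    avg_loss_per_event: float = math.nan
    avg_gain_per_event: float = math.nan
    indel_size_histogram: dict[int, int] = field(default_factory=dict)
    class_counts: dict[str, int] = field(default_factory=dict)
    n_complex: int = 0

    def check(self) -> None:
        """Assert internal consistency of the derived fields."""
        assert self.n_ts + self.n_tv == self.n_snv
        assert self.n_to_AT + self.n_to_GC <= self.n_snv
        assert self.n_del + self.n_ins == self.n_indel
        assert self.net_loss == self.bases_lost - self.bases_gained
        assert sum(self.class_counts.values()) == self.n_snv


def _ratio(num: float, den: float) -> float:
    return num / den if den else math.nan


def summarize_spectrum(
    records: Sequence[MutationRecord], *, dedupe: bool = False
) -> SpectrumSummary:
    """Compute the full spectrum summary for ``records``.

    The caller is expected to have removed clonal redundancy already;
    pass ``dedupe=True`` to run :func:`deduplicate` first.

    Raises
    ------
    ValueError
        Naming the offending record index if any record is malformed.
    """
    if dedupe:
        records = deduplicate(records)
    s = SpectrumSummary()
    s.class_counts = {c: 0 for c in PAIR_CLASSES}
    hist: Counter[int] = Counter()
    for idx, rec in enumerate(records):
        try:
            rec.validate()
            kind = rec.kind
            if kind == "snv":
                cls = classify_snv(rec.ref, rec.alt)
            elif kind == "complex":
                if rec.ref == rec.alt:
                    raise ValueError("ref and alt identical")
        except ValueError as exc:
            raise ValueError(f"record {idx} ({rec.sample_id}): {exc}") from exc
        if kind == "snv":
            s.n_snv += 1
            s.class_counts[cls.pair_class] += 1
            if cls.is_transition:
                s.n_ts += 1
            else:
                s.n_tv += 1
            if cls.to_at:
                s.n_to_AT += 1
            elif cls.to_gc:
                s.n_to_GC += 1
        elif kind == "complex":
            s.n_complex += 1
        else:
            size = rec.net_size
            s.n_indel += 1
            hist[size] += 1
            if size < 0:
                s.n_del += 1
                s.bases_lost += -size
            else:
                s.n_ins += 1
                s.bases_gained += size
    s.indel_size_histogram = dict(sorted(hist.items()))
    s.ts_tv_ratio = _ratio(s.n_tv, s.n_ts)
    s.at_bias = _ratio(s.n_to_AT, s.n_to_GC)
    s.net_loss = s.bases_lost - s.bases_gained
    s.del_ins_ratio = _ratio(s.n_del, s.n_ins)
    s.avg_loss_per_event = _ratio(s.bases_lost, s.n_del)
    s.avg_gain_per_event = _ratio(s.bases_gained, s.n_ins)
    s.check()
    return s


def bin_indel_sizes(
    histogram: Mapping[int, int],
    bins: Iterable[tuple[int, int | None]] = DEFAULT_INDEL_BINS,
) -> dict[str, int]:
    """Aggregate a signed size histogram into symmetric report bins.

    Each ``(lo, hi)`` bin covers absolute sizes ``lo..hi`` (``hi=None`` is
    open-ended); deletions and insertions are reported separately with
    '-'/'+' prefixed labels.
    """
    out: dict[str, int] = {}
    for lo, hi in bins:
        label = f"{lo}" if lo == hi else (f"{lo}-{hi}" if hi is not None else f">{lo - 1}")
        for sign, prefix in ((-1, "-"), (1, "+")):
            total = sum(
                n
                for size, n in histogram.items()
                if size * sign > 0 and lo <= abs(size) and (hi is None or abs(size) <= hi)
            )
            out[prefix + label] = total
    return out
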