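"""Codon-level enumeration of potential SNVs and hits-per-target distributions.

Every coding position of a CDS admits three alternative bases; comparing the
mutated codon's translation with the original classifies each potential
substitution as synonymous, non-synonymous or STOP-gain.  The module also
builds the hits-per-target count vectors ("k-distributions") consumed by the
saturation estimators.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Literal, Sequence

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "GeneModel",
    "KDistribution",
    "Effect",
    "enumerate_potential_snvs",
    "classify_observed_snv",
    "build_k_distribution",
    "CODON_TABLE",
    "STOP_CODONS",
]

Effect = Literal["synonymous", "non-synonymous", "STOP"]

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
#: Codon -> amino acid, with '*' for the three stop codons (standard code).
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: "*" for c in STOP_CODONS})

_BASES = "ACGT"


@dataclass(frozen=True)
class GeneModel:
    """Per-gene counts of potential SNVs by codon-level effect."""

    name: str
    n_aa: int
    n_syn: int
    n_ns: int
    n_stop: int

    def __post_init__(self) -> None:
        if self.n_syn + self.n_ns + self.n_stop != 9 * self.n_aa:
            raise ValueError(
                f"{self.name}: potential-SNV counts do not sum to 9 x n_aa "
                f"({self.n_syn}+{self.n_ns}+{self.n_stop} != {9 * self.n_aa})"
            )

    @property
    def n_potential(self) -> int:
        return 9 * self.n_aa

    @property
    def p_syn(self) -> float:
        return self.n_syn / self.n_potential

    @property
    def p_ns(self) -> float:
        return self.n_ns / self.n_potential

    @property
    def p_stop(self) -> float:
        return self.n_stop / self.n_potential


@dataclass(frozen=True)
class KDistribution:
    """Hits-per-target counts: ``counts[i]`` targets were hit exactly i times."""

    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for i, k_i in sorted(self.counts.items()):
            if i < 1 or k_i < 0:
                raise ValueError(f"invalid k-distribution entry {i}: {k_i}")
            if k_i > 0:
                cleaned[int(i)] = int(k_i)
        object.__setattr__(self, "counts", cleaned)

    @classmethod
    def from_hits(cls, hits_per_target: Iterable[int]) -> "KDistribution":
        """Build from a list of per-target hit counts (zeros are dropped)."""
        return cls(dict(Counter(h for h in hits_per_target if h > 0)))

    @classmethod
    def from_vector(cls, k_vector: Sequence[int]) -> "KDistribution":
        """Build from ``(k_1, k_2, ...)`` as printed in summary tables."""
        return cls({i + 1: k for i, k in enumerate(k_vector)})

    @property
    def m(self) -> int:
        """Total number of hits."""
        return sum(i * k for i, k in self.counts.items())

    @property
    def occupied(self) -> int:
        """Number of targets hit at least once."""
        return sum(self.counts.values())

    @property
    def max(self) -> int:
        """Largest observed per-target hit count."""
        return max(self.counts, default=0)

    def to_hits(self) -> list[int]:
        """Expand back to a sorted list of per-target hit counts."""
        out: list[int] = []
        for i, k in sorted(self.counts.items()):
            out.extend([i] * k)
        return out


def _validate_cds(
    cds: str, on_internal_stop: Literal["error", "warn"] = "error"
) -> str:
    seq = cds.strip().upper().replace("U", "T")
    if len(seq) == 0 or len(seq) % 3:
        raise ValueError(f"CDS length {len(seq)} is not a positive multiple of 3")
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValueError(f"CDS contains non-ACGT symbols: {sorted(bad)}")
    # A trailing stop codon is allowed and excluded from the model.
    if seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
        if not seq:
            raise ValueError("CDS consists of a stop codon only")
    internal = [
        i // 3 + 1 for i in range(0, len(seq), 3) if seq[i : i + 3] in STOP_CODONS
    ]
    if internal:
        msg = f"internal stop codon(s) at codon(s) {internal}"
        if on_internal_stop == "error":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=3)
    return seq


def enumerate_potential_snvs(
    cds: str,
    name: str = "gene",
    on_internal_stop: Literal["error", "warn"] = "error",
) -> GeneModel:
    """Count all 9 x n_aa potential single-nucleotide substitutions of a CDS.

    Each coding position has three alternative bases; the mutated codon's
    translation decides the effect: identical amino acid -> synonymous, stop
    codon -> STOP, anything else -> non-synonymous.  An optional trailing stop
    codon is excluded from ``n_aa``.
    """
    seq = _validate_cds(cds, on_internal_stop)
    n_syn = n_ns = n_stop = 0
    for start in range(0, len(seq), 3):
        codon = seq[start : start + 3]
        aa = CODON_TABLE[codon]
        for offset in range(3):
            for alt in _BASES:
                if alt == codon[offset]:
                    continue
                mutated = codon[:offset] + alt + codon[offset + 1 :]
                new_aa = CODON_TABLE[mutated]
                if new_aa == "*":
                    n_stop += 1
                elif new_aa == aa:
                    n_syn += 1
                else:
                    n_ns += 1
    return GeneModel(
        name=name, n_aa=len(seq) // 3, n_syn=n_syn, n_ns=n_ns, n_stop=n_stop
    )


def classify_observed_snv(
    cds: str,
    position: int,
    alt: str,
    on_internal_stop: Literal["error", "warn"] = "error",
) -> Effect:
    """Effect of substituting ``alt`` at 1-based ``position`` of the CDS."""
    seq = _validate_cds(cds, on_internal_stop)
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} outside CDS of length {len(seq)}")
    alt = alt.strip().upper().replace("U", "T")
    if alt not in _BASES:
        raise ValueError(f"alt must be one of ACGT, got {alt!r}")
    if alt == seq[position - 1]:
        raise ValueError(f"alt equals the reference base at position {position}")
    codon_idx = (position - 1) // 3
    offset = (position - 1) % 3
    codon = seq[codon_idx * 3 : codon_idx * 3 + 3]
    mutated = codon[:offset] + alt + codon[offset + 1 :]
    new_aa = CODON_TABLE[mutated]
    if new_aa == "*":
        return "STOP"
    if new_aa == CODON_TABLE[codon]:
        return "synonymous"
    return "non-synonymous"


def build_k_distribution(
    observed: Iterable[tuple[Hashable, Hashable]],
    level: Literal["per_residue_distinct", "per_site_recurrent"],
) -> KDistribution:
    """Build the hits-per-target distribution from (target_id, mutation_id) pairs.

    ``per_residue_distinct``: targets are residues and each *distinct*
    mutation_id at a residue counts once (repeat observations of the same
    mutation collapse).  ``per_site_recurrent``: targets are distinct sites
    (e.g. non-synonymous SNVs) and every observation counts, so recurrences
    accumulate.
    """
    if level == "per_residue_distinct":
        per_target: defaultdict[Hashable, set] = defaultdict(set)
        for target_id, mutation_id in observed:
            per_target[target_id].add(mutation_id)
        hits = [len(v) for v in per_target.values()]
    elif level == "per_site_recurrent":
        tallies: Counter[Hashable] = Counter(t for t, _ in observed)
        hits = list(tallies.values())
    else:
        raise ValueError(f"unknown level {level!r}")
    return KDistribution.from_hits(hits)
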