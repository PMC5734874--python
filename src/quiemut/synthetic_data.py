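"""Simulators reproducing the statistical structure the analysis assumes.

Every generator takes an explicit seed (or an already-constructed
``numpy.random.Generator``) and uses a single PCG64 stream, so identical
seeds give identical outputs on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .accumulation import AccumulationPoint, AccumulationSeries
from .gene_model import KDistribution, _validate_cds, CODON_TABLE
from .spectrum import MutationRecord

__all__ = [
    "SimulationConfig",
    "simulate_target_hits",
    "simulate_phenotypic_assay",
    "simulate_accumulation",
    "simulate_genome_counts",
    "random_cds",
    "records_from_class_counts",
    "records_from_indel_totals",
]

SeedLike = Union[int, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Parameters of a full synthetic dataset (one seed drives everything)."""

    seed: int = 0
    k_true: int = 124
    m: int = 76
    f_true: float = 0.35
    slope_true: float = 0.55e-7
    intercept: float = 1e-7
    days: list[float] = field(default_factory=lambda: [1, 4, 8, 11, 15])
    n_experiments: int = 2
    n_genomes: int = 237
    lambda_true: float = 0.6
    noise_cv: float = 0.05
    cds_codons: int = 300

    def __post_init__(self) -> None:
        if min(self.k_true, self.m, self.n_genomes, self.cds_codons) < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.f_true <= 1:
            raise ValueError("f_true must be in (0, 1]")
        if self.lambda_true < 0 or self.noise_cv < 0:
            raise ValueError("lambda_true and noise_cv must be non-negative")


def simulate_target_hits(k_true: int, m: int, seed: SeedLike) -> KDistribution:
    """Drop m mutations uniformly on k_true targets; return hits-per-target.

    Targets left unhit are excluded, as in real data where only mutated
    targets are observable.
    """
    if k_true < 1 or m < 1:
        raise ValueError("k_true and m must be >= 1")
    rng = _rng(seed)
    hits = np.bincount(rng.integers(0, k_true, size=m), minlength=k_true)
    return KDistribution.from_hits(hits.tolist())


def random_cds(n_codons: int, seed: SeedLike, start_codon: bool = True) -> str:
    """Random CDS of ``n_codons`` sense codons (no internal stops)."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = _rng(seed)
    sense = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
    idx = rng.integers(0, len(sense), size=n_codons)
    codons = [sense[i] for i in idx]
    if start_codon:
        codons[0] = "ATG"
    return "".join(codons)


def simulate_phenotypic_assay(
    cds: str,
    f_true: float,
    m: int,
    seed: SeedLike,
    gene_name: str = "gene",
    day: float = 8.0,
) -> list[MutationRecord]:
    """Draw m candidate SNVs on a CDS and keep those with a phenotype.

    A random subset of round(f_true * n_aa) residues is designated essential.
    Candidates are uniform over all 9 x n_aa potential SNVs; a candidate is
    retained iff it is STOP-gain, or non-synonymous at an essential residue.
    Each retained record gets its own sample and population id so that
    recurrent identical mutations survive redundancy filtering, mimicking
    independently isolated mutant colonies.
    """
    if not 0 <= f_true <= 1:
        raise ValueError("f_true must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = _rng(seed)
    seq = _validate_cds(cds)
    n_aa = len(seq) // 3
    n_essential = round(f_true * n_aa)
    essential = set(rng.choice(n_aa, size=n_essential, replace=False).tolist())

    # All potential SNVs: (position, ref, alt, effect, residue index).
    bases = "ACGT"
    potential: list[tuple[int, str, str, str, int]] = []
    for pos0 in range(len(seq)):
        codon_idx = pos0 // 3
        offset = pos0 % 3
        codon = seq[codon_idx * 3 : codon_idx * 3 + 3]
        aa = CODON_TABLE[codon]
        for alt in bases:
            if alt == seq[pos0]:
                continue
            mutated = codon[:offset] + alt + codon[offset + 1 :]
            new_aa = CODON_TABLE[mutated]
            effect = (
                "STOP" if new_aa == "*" else
                "synonymous" if new_aa == aa else "non-synonymous"
            )
            potential.append((pos0 + 1, seq[pos0], alt, effect, codon_idx))

    draws = rng.integers(0, len(potential), size=m)
    records: list[MutationRecord] = []
    for i, d in enumerate(draws):
        pos, ref, alt, effect, residue = potential[d]
        keep = effect == "STOP" or (
            effect == "non-synonymous" and residue in essential
        )
        if keep:
            sid = f"iso{i:05d}"
            records.append(
                MutationRecord(
                    sample_id=sid,
                    population_id=sid,
                    day=day,
                    locus=gene_name,
                    position=pos,
                    ref=ref,
                    alt=alt,
                )
            )
    return records


def simulate_accumulation(
    slope_true: float,
    intercept: float,
    days: Sequence[float],
    noise_cv: float,
    n_experiments: int,
    seed: SeedLike,
) -> AccumulationSeries:
    """Linear frequency growth with multiplicative Gaussian noise.

    frequency(day) = max(0, (intercept + slope_true * day) * (1 + eps)),
    eps ~ Normal(0, noise_cv), independently per experiment and day.
    """
    if len(days) == 0:
        raise ValueError("days must be nonempty")
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    rng = _rng(seed)
    points = []
    for e in range(n_experiments):
        eps = rng.normal(0.0, noise_cv, size=len(days)) if noise_cv > 0 else np.zeros(len(days))
        for day, ep in zip(days, eps):
            freq = max(0.0, (intercept + slope_true * day) * (1.0 + ep))
            points.append(AccumulationPoint(float(day), freq, f"exp{e + 1}"))
    return AccumulationSeries(points=points)


#: Representative ordered substitution for each strand-symmetric pair class.
_CLASS_REPRESENTATIVE = {
    "GC>AT": ("C", "T"),
    "GC>TA": ("C", "A"),
    "GC>CG": ("C", "G"),
    "AT>GC": ("A", "G"),
    "AT>CG": ("A", "C"),
    "AT>TA": ("A", "T"),
}


def records_from_class_counts(
    class_counts: dict[str, int],
    population_id: str = "pop1",
    locus: str = "gene",
    day: float = 1.0,
    start_position: int = 1,
) -> list[MutationRecord]:
    """Deterministic SNV records realizing given per-class marginal counts.

    Useful for reconstructing a dataset from published summary tables: each
    requested pair class is materialized by its representative substitution
    at consecutive distinct positions.
    """
    records: list[MutationRecord] = []
    pos = start_position
    for cls, n in class_counts.items():
        if cls not in _CLASS_REPRESENTATIVE:
            raise ValueError(f"unknown pair class {cls!r}")
        ref, alt = _CLASS_REPRESENTATIVE[cls]
        for _ in range(n):
            records.append(
                MutationRecord(
                    sample_id=f"s{pos}",
                    population_id=population_id,
                    day=day,
                    locus=locus,
                    position=pos,
                    ref=ref,
                    alt=alt,
                )
            )
            pos += 1
    return records


def records_from_indel_totals(
    n_del: int,
    bases_lost: int,
    n_ins: int,
    bases_gained: int,
    population_id: str = "pop1",
    locus: str = "gene",
    day: float = 8.0,
    start_position: int = 1,
) -> list[MutationRecord]:
    """Deterministic indel records with given event and base totals.

    Base totals are spread as evenly as possible over the events (sizes
    differ by at most 1), which is all the spectrum statistics depend on.
    """
    if (n_del == 0) != (bases_lost == 0) or (n_ins == 0) != (bases_gained == 0):
        raise ValueError("base totals require at least one event and vice versa")
    if (n_del and bases_lost < n_del) or (n_ins and bases_gained < n_ins):
        raise ValueError("each event must change at least one base")
    records: list[MutationRecord] = []
    pos = start_position
    for n, total, is_del in ((n_del, bases_lost, True), (n_ins, bases_gained, False)):
        if n == 0:
            continue
        q, r = divmod(total, n)
        sizes = [q + 1] * r + [q] * (n - r)
        for size in sizes:
            allele = "A" * size
            records.append(
                MutationRecord(
                    sample_id=f"i{pos}",
                    population_id=population_id,
                    day=day,
                    locus=locus,
                    position=pos,
                    ref=allele if is_del else "",
                    alt="" if is_del else allele,
                )
            )
            pos += 1
    return records


def simulate_genome_counts(
    lambda_true: float, n_genomes: int, seed: SeedLike
) -> list[int]:
    """i.i.d. Poisson(lambda_true) mutation counts for n_genomes genomes."""
    if lambda_true < 0:
        raise ValueError("lambda_true must be non-negative")
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rng = _rng(seed)
    return rng.poisson(lambda_true, size=n_genomes).astype(int).tolist()
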