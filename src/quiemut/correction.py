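"""Phenotypic-to-total mutation rate correction and genome extrapolation.

A loss-of-function reporter only reveals the mutations that break it: all
STOP-gains, a fraction f of non-synonymous SNVs, and all frame-shifting
indels.  These routines divide an observed phenotypic rate by the phenotypic
share to recover the total rate on the reporter, and rescale it by sequence
length to a genome-wide rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = [
    "CorrectionParams",
    "snv_phenotypic_fraction",
    "correct_snv_rate",
    "indel_inflation_factor",
    "correct_indel_rate",
    "extrapolate_genome",
]


@dataclass(frozen=True)
class CorrectionParams:
    """Inputs of the rate correction.

    f: phenotype-causing share of non-synonymous SNVs.
    p_stop/p_ns/p_syn: fractions of all potential SNVs by effect (sum to 1).
    p_3nt/p_6nt: fractions of observed indels with absolute size 3 / 6 nt.
    target_len/genome_len: reporter and genome lengths in nucleotides.
    """

    f: float
    p_stop: float
    p_ns: float
    p_syn: float
    p_3nt: float = 0.0
    p_6nt: float = 0.0
    target_len: int = 1400
    genome_len: int = 14_000_000

    def __post_init__(self) -> None:
        for name in ("f", "p_stop", "p_ns", "p_syn", "p_3nt", "p_6nt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.p_syn + self.p_ns + self.p_stop - 1.0) > 1e-6:
            raise ValueError("p_syn + p_ns + p_stop must sum to 1")
        if self.p_3nt + self.p_6nt > 1.0 + 1e-12:
            raise ValueError("p_3nt + p_6nt exceeds 1")
        if not 0 < self.target_len <= self.genome_len:
            raise ValueError("need 0 < target_len <= genome_len")


def snv_phenotypic_fraction(params: CorrectionParams) -> float:
    """Share of all potential SNVs that produce the phenotype:
    phi = p_stop + f * p_ns."""
    return params.p_stop + params.f * params.p_ns


def correct_snv_rate(observed_rate: float, params: CorrectionParams) -> float:
    """Total SNV rate on the reporter: observed / (p_stop + f * p_ns)."""
    if observed_rate < 0:
        raise ValueError("observed rate must be non-negative")
    phi = snv_phenotypic_fraction(params)
    if phi <= 0:
        raise ValueError("phenotypic fraction is zero; correction undefined")
    return observed_rate / phi


def indel_inflation_factor(
    f: float,
    p_3nt: float,
    p_6nt: float,
    mode: Literal["as_published", "observed_only"] = "as_published",
) -> float:
    """Multiplier converting the observed indel rate into the total rate.

    Frame-shifting indels always produce the phenotype; in-frame 3 nt and
    6 nt events do so only when an essential residue (share f) is disrupted:
    a 3 nt event is seen with probability f and a 6 nt event with
    probability 1 - (1 - f)^2.  The default ``as_published`` multiplier is

        1 + p_3nt / f + p_6nt / (1 - (1 - f)^2)

    which matches the published correction.  ``observed_only`` inflates only
    the unseen complement of each observed in-frame class,
    1 + p_3nt*(1/f - 1) + p_6nt*(1/(1-(1-f)^2) - 1), an alternative reading
    retained for comparison.
    """
    if not 0 < f <= 1:
        raise ValueError(f"f={f} must be in (0, 1]")
    if p_3nt < 0 or p_6nt < 0 or p_3nt + p_6nt > 1 + 1e-12:
        raise ValueError("in-frame fractions must be >= 0 and sum to <= 1")
    w6 = 1.0 - (1.0 - f) ** 2
    if mode == "as_published":
        return 1.0 + p_3nt / f + p_6nt / w6
    if mode == "observed_only":
        return 1.0 + p_3nt * (1.0 / f - 1.0) + p_6nt * (1.0 / w6 - 1.0)
    raise ValueError(f"unknown mode {mode!r}")


def correct_indel_rate(
    observed_rate: float,
    params: CorrectionParams,
    mode: Literal["as_published", "observed_only"] = "as_published",
) -> float:
    """Total indel rate on the reporter: observed x inflation factor."""
    if observed_rate < 0:
        raise ValueError("observed rate must be non-negative")
    return observed_rate * indel_inflation_factor(
        params.f, params.p_3nt, params.p_6nt, mode=mode
    )


def extrapolate_genome(
    total_rate_on_target: float, target_len: int, genome_len: int
) -> float:
    """Rescale a per-target rate to the whole genome by sequence length."""
    if target_len <= 0 or genome_len <= 0:
        raise ValueError("lengths must be positive")
    return total_rate_on_target / target_len * genome_len
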