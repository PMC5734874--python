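"""Maximum-likelihood estimation of the number of hidden mutational targets.

The model: m mutations fall uniformly and independently on k exchangeable
targets; only targets hit at least once are observed.  Given the
hits-per-target distribution (k_1, ..., k_max) with k_0 = k - occupied unseen
targets, the probability of the observed configuration is

    P(k_1, ..., k_max | k) = m! * k! / (prod_i k_i! * (i!)^{k_i}) * k^{-m}

The integer k maximizing this likelihood estimates the total target count;
normalizing the likelihood over integers (flat prior) yields a 95%
credibility interval.  A third, saturation-equating route converts observed
vs potential STOP counts into the phenotypic fraction directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .gene_model import KDistribution

__all__ = [
    "SaturationEstimate",
    "FractionEstimate",
    "log_likelihood",
    "likelihood_profile",
    "mle_k",
    "method1_f",
    "method2_f",
    "method3_f",
]

#: Normalized likelihood mass allowed beyond the search bound.
_TAIL_TOL = 1e-6


@dataclass
class SaturationEstimate:
    """Result of the integer ML scan over the target count k."""

    method: str
    k_hat: Optional[int]
    ci95: tuple[Optional[int], Optional[int]]
    f: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def unbounded(self) -> bool:
        return bool(self.diagnostics.get("unbounded", False))


@dataclass(frozen=True)
class FractionEstimate:
    """A phenotypic fraction with its transformed credibility interval."""

    f: float
    ci95: tuple[float, float]


def _kd_constant(kd: KDistribution) -> float:
    """Log of the k-independent part of the likelihood (kept so that
    exp(log_likelihood) equals the closed form exactly)."""
    out = gammaln(kd.m + 1)
    for i, k_i in kd.counts.items():
        out -= gammaln(k_i + 1) + k_i * gammaln(i + 1)
    return float(out)


def log_likelihood(kd: KDistribution, k: int) -> float:
    """Natural log of P(k_1, ..., k_max | k) for an integer target count k.

    Computed with log-gamma so large factorials never overflow.  All
    constant-in-k terms are included.
    """
    occ = kd.occupied
    if occ < 1:
        raise ValueError("k-distribution is empty")
    if k < occ:
        raise ValueError(f"k={k} < occupied targets {occ} (k0 would be negative)")
    return (
        _kd_constant(kd)
        + float(gammaln(k + 1) - gammaln(k - occ + 1))
        - kd.m * math.log(k)
    )


def _log_likelihood_grid(kd: KDistribution, ks: np.ndarray) -> np.ndarray:
    occ = kd.occupied
    return _kd_constant(kd) + gammaln(ks + 1) - gammaln(ks - occ + 1) - kd.m * np.log(ks)


#: Tail fraction accepted when the strict target is provably unreachable.
_SOFT_TAIL = 1e-3
#: Hard ceiling on the integer search grid.
_MAX_BOUND = 4_000_000


def likelihood_profile(
    kd: KDistribution, k_max: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Integer grid [occupied, bound] and the normalized likelihood over it.

    The bound (default 200 x occupied) is extended automatically until the
    likelihood mass it truncates falls below 1e-6 of the total, so intervals
    are never silently clipped.  Beyond the grid the weights decay like
    k^-(m - occupied); the truncated mass is estimated by the corresponding
    power-law integral and folded into the normalization.  For slowly
    decaying profiles (m - occupied = 2) the strict 1e-6 target can require
    an astronomically large grid; the profile is then returned once the
    estimated tail drops below 1e-3, still tail-normalized.  Raises if even
    that is impossible within the grid ceiling (improper interval).
    """
    occ = kd.occupied
    if occ < 1 or kd.m < 1:
        raise ValueError("k-distribution is empty")
    p = kd.m - occ  # power-law decay index of the far tail
    bound = k_max if k_max is not None else 200 * occ
    bound = max(bound, occ + 1)
    while True:
        ks = np.arange(occ, bound + 1, dtype=float)
        ll = _log_likelihood_grid(kd, ks)
        w = np.exp(ll - ll.max())
        total = w.sum()
        # Integral estimate of the truncated mass: sum_{k>B} w(B) (B/k)^p.
        tail = w[-1] * bound / max(p - 1, 1)
        frac = tail / (total + tail)
        if frac < _TAIL_TOL:
            return ks.astype(int), w / (total + tail)
        # Bound needed to hit a tail target scales like frac^(-1/(p-1)).
        stretch = 1.0 / max(p - 1, 1)
        projected = bound * (frac / _TAIL_TOL) ** stretch
        if projected > _MAX_BOUND:
            if frac < _SOFT_TAIL:
                return ks.astype(int), w / (total + tail)
            # Aim for the soft target instead of overshooting to the ceiling.
            projected = 1.5 * bound * (frac / _SOFT_TAIL) ** stretch
        if bound >= _MAX_BOUND:
            raise RuntimeError(
                "likelihood mass does not decay within the search bound; the "
                "credibility interval is improper for this distribution "
                f"(m={kd.m}, occupied={occ})"
            )
        bound = min(max(2 * bound, int(projected) + 1), _MAX_BOUND)


def mle_k(
    kd: KDistribution, k_max: Optional[int] = None, method: str = "aa_saturation"
) -> SaturationEstimate:
    """Integer maximum-likelihood estimate of the total target count.

    Scans k over [occupied, k_max] (bound auto-extended), returning the
    argmax (smallest k on ties), the central 95% credibility interval of the
    flat-prior normalized likelihood, and diagnostics.  When every target was
    hit exactly once the likelihood increases without bound and the estimate
    is flagged ``unbounded`` instead of reporting an artifact.
    """
    if kd.m < 1:
        raise ValueError("k-distribution has no hits (m = 0)")
    if kd.max <= 1:
        return SaturationEstimate(
            method=method,
            k_hat=None,
            ci95=(None, None),
            diagnostics={"unbounded": True, "reason": "no target hit more than once"},
        )
    if kd.m - kd.occupied < 2:
        # Tail weights decay like k^(occupied - m), so with fewer than two
        # excess hits the flat-prior mass diverges and no interval exists.
        return SaturationEstimate(
            method=method,
            k_hat=None,
            ci95=(None, None),
            diagnostics={
                "unbounded": True,
                "reason": "fewer than two recurrent hits; credibility interval improper",
            },
        )
    try:
        ks, w = likelihood_profile(kd, k_max)
    except RuntimeError as exc:
        return SaturationEstimate(
            method=method,
            k_hat=None,
            ci95=(None, None),
            diagnostics={"unbounded": True, "reason": str(exc)},
        )
    idx = int(np.argmax(w))  # first occurrence -> smallest k on ties
    cdf = np.cumsum(w)
    lo = int(ks[np.searchsorted(cdf, 0.025)])
    hi = int(ks[np.searchsorted(cdf, 0.975)])
    k_hat = int(ks[idx])
    return SaturationEstimate(
        method=method,
        k_hat=k_hat,
        ci95=(lo, hi),
        diagnostics={
            "log_likelihood": log_likelihood(kd, k_hat),
            "k_max": int(ks[-1]),
            "unbounded": False,
        },
    )


def _fraction(est: SaturationEstimate, denominator: int, what: str) -> FractionEstimate:
    if est.unbounded or est.k_hat is None:
        raise ValueError("cannot derive a fraction from an unbounded estimate")
    if est.k_hat > denominator:
        raise ValueError(
            f"estimated {est.k_hat} targets exceeds the {denominator} {what}"
        )
    lo, hi = est.ci95
    return FractionEstimate(
        f=est.k_hat / denominator,
        ci95=(lo / denominator, min(hi / denominator, 1.0)),
    )


def method1_f(est: SaturationEstimate, n_aa: int) -> FractionEstimate:
    """Fraction of residues whose mutation causes the phenotype: k_hat / n_aa.

    ``est`` must come from a per-residue distinct-mutation k-distribution.
    """
    return _fraction(est, n_aa, "residues")


def method2_f(est: SaturationEstimate, n_ns_potential: int) -> FractionEstimate:
    """Fraction of potential non-synonymous SNVs that are phenotypic:
    k_hat / n_ns_potential, from a per-site recurrence k-distribution."""
    return _fraction(est, n_ns_potential, "potential non-synonymous SNVs")


def method3_f(
    obs_stops: int, pot_stops: int, obs_ns: int, pot_ns: int
) -> tuple[float, float]:
    """Saturation-equating estimate of the phenotypic fraction.

    The observed fraction of potential STOP-gain SNVs, s = obs/pot, is taken
    as the saturation level of *all* phenotype-causing SNVs; the implied
    total of phenotypic non-synonymous SNVs is obs_ns / s, giving
    f = obs_ns / (s * pot_ns).  Returns ``(s, f)``.
    """
    if min(pot_stops, pot_ns) <= 0:
        raise ValueError("potential counts must be positive")
    if obs_stops <= 0:
        raise ValueError(
            "no observed STOP-gain mutations: the saturation level is undefined"
        )
    if obs_stops > pot_stops:
        raise ValueError("observed STOPs exceed potential STOPs")
    if obs_ns < 0:
        raise ValueError("negative observed non-synonymous count")
    s = obs_stops / pot_stops
    f = obs_ns / (s * pot_ns)
    return s, f
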