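"""Closed-form moments of the two-locus Wright-Fisher model with recombination
and plan-II temporal sampling.

These are the building blocks of the temporal method for contemporary effective
population size (Ne): the drift covariance between allele frequencies at two
linked loci, the variance/covariance of the standardized allele-frequency
changes ``delta_i = (x_it - x_i0) / sqrt(x_i0 (1 - x_i0))`` under binomial
sampling of ``2*S`` haplotypes at each time point, the expected temporal F
statistic, and its (approximate and exact) inversion for Ne.

All functions accept scalars or numpy arrays and broadcast; ``ne=numpy.inf``
is a valid drift-free limit throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TemporalDesign",
    "DriftModel",
    "PairLinkage",
    "GeneticMapConfig",
    "haldane_c",
    "simulated_pair_c",
    "drift_covariance",
    "expected_d_decay",
    "delta_variance",
    "delta_covariance",
    "delta_correlation",
    "expected_f",
    "estimate_ne",
    "estimate_ne_exact",
]


@dataclass(frozen=True)
class TemporalDesign:
    """Sampling design of a two-time-point temporal study.

    Parameters
    ----------
    s0, st : int
        Diploid sample sizes at generation 0 and generation t (so ``2*s0``
        and ``2*st`` haplotypes are observed). Sampling plan II is assumed:
        individuals are sampled with replacement (or after reproduction), so
        sampling does not perturb the breeding population and the cross-time
        sampling covariance is zero.
    t : int
        Number of (non-overlapping) generations between the two samples.
    """

    s0: int
    st: int
    t: int

    def __post_init__(self) -> None:
        for name in ("s0", "st", "t"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")

    @property
    def sampling_floor(self) -> float:
        """The pure-sampling contribution ``1/(2*s0) + 1/(2*st)`` to F."""
        return 1.0 / (2 * self.s0) + 1.0 / (2 * self.st)


@dataclass(frozen=True)
class DriftModel:
    """Wright-Fisher drift model parameterized by the diploid effective size."""

    ne: float

    def __post_init__(self) -> None:
        if not self.ne > 0:
            raise ValueError(f"ne must be > 0, got {self.ne!r}")


@dataclass(frozen=True)
class PairLinkage:
    """Linkage state of one unordered pair of loci.

    ``c`` is the per-generation recombination fraction (0.5 = unlinked),
    ``r0`` the standardized LD in the first temporal sample, and ``d0`` the
    optional unstandardized LD coefficient.
    """

    c: float
    r0: float
    d0: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 0.5:
            raise ValueError(f"recombination fraction c must be in [0, 0.5], got {self.c!r}")
        if not -1.0 <= self.r0 <= 1.0:
            raise ValueError(f"r0 must be in [-1, 1], got {self.r0!r}")


@dataclass(frozen=True)
class GeneticMapConfig:
    """Uniform genetic map used to convert physical to recombination distance.

    Parameters
    ----------
    rate_cm_per_mb : float
        Uniform recombination rate in centimorgan per megabase.
    inter_arm_rule : {"unlinked", "through-map"}
        How to treat pairs of loci on different chromosomes/arms:
        ``"unlinked"`` assigns c = 0.5; ``"through-map"`` applies the mapping
        function to the coordinate difference (requires genome-cumulative
        coordinates to be meaningful).
    per_bp_rate : float, optional
        If given, pairwise recombination fractions are computed by exact
        per-base-pair geometric compounding (:func:`simulated_pair_c`)
        instead of Haldane's function. This mirrors the crossover process of
        the built-in simulator.
    """

    rate_cm_per_mb: float = 1.4
    inter_arm_rule: str = "unlinked"
    per_bp_rate: float | None = None

    def __post_init__(self) -> None:
        if not self.rate_cm_per_mb > 0:
            raise ValueError("rate_cm_per_mb must be > 0")
        if self.inter_arm_rule not in ("unlinked", "through-map"):
            raise ValueError(f"unknown inter_arm_rule {self.inter_arm_rule!r}")
        if self.per_bp_rate is not None and not 0.0 <= self.per_bp_rate <= 0.5:
            raise ValueError("per_bp_rate must be in [0, 0.5]")

    def recomb_fraction(self, distance_bp):
        """Recombination fraction for a same-arm pair ``distance_bp`` apart."""
        if self.per_bp_rate is not None:
            return simulated_pair_c(distance_bp, self.per_bp_rate)
        return haldane_c(distance_bp, self.rate_cm_per_mb)


def haldane_c(distance_bp, rate_cm_per_mb: float = 1.4):
    """Haldane's mapping function: physical distance -> recombination fraction.

    ``c = 0.5 * (1 - exp(-2 d))`` with map distance ``d`` in Morgans,
    ``d = distance_bp * rate_cm_per_mb * 1e-8``. Assumes no crossover
    interference. Monotone increasing, 0 at zero distance, asymptote 0.5.
    """
    distance_bp = np.asarray(distance_bp, dtype=float)
    if np.any(distance_bp < 0):
        raise ValueError("distance_bp must be non-negative")
    d = distance_bp * rate_cm_per_mb * 1e-8
    out = 0.5 * (1.0 - np.exp(-2.0 * d))
    return float(out) if out.ndim == 0 else out


def simulated_pair_c(distance_bp, per_bp_rate: float):
    """Recombination fraction from geometric compounding of a per-bp rate.

    ``c = 0.5 * (1 - (1 - 2*per_bp_rate)**y)`` for two loci ``y`` bp apart,
    i.e. the probability of an odd number of crossovers when each of the
    ``y`` unit intervals recombines independently with the given rate.
    """
    if not 0.0 <= per_bp_rate <= 0.5:
        raise ValueError("per_bp_rate must be in [0, 0.5]")
    y = np.asarray(distance_bp, dtype=float)
    if np.any(y < 0):
        raise ValueError("distance_bp must be non-negative")
    out = 0.5 * (1.0 - (1.0 - 2.0 * per_bp_rate) ** y)
    return float(out) if out.ndim == 0 else out


def _a_pow_t(ne, t):
    """``(1 - 1/(2 Ne))**t``, the per-generation drift retention factor."""
    ne = np.asarray(ne, dtype=float)
    return (1.0 - 1.0 / (2.0 * ne)) ** np.asarray(t, dtype=float)


def _check_c(c):
    c = np.asarray(c, dtype=float)
    if np.any((c < 0) | (c > 0.5)):
        raise ValueError("recombination fraction c must be in [0, 0.5]")
    return c


def drift_covariance(d0, c, ne, t):
    """Covariance of true allele frequencies at two linked loci after t generations.

    ``cov(p_it, p_jt | D0) = D0 (1-c) [1 - (1 - 1/(2Ne))^t (1-c)^t] / (2 Ne c + 1 - c)``.

    At ``c = 0`` this reduces to the single-locus drift variance formula
    ``D0 [1 - (1 - 1/(2Ne))^t]`` (with ``D0 = p0 (1-p0)``), and at ``t = 0``
    it is zero.
    """
    c = _check_c(c)
    d0 = np.asarray(d0, dtype=float)
    ne = np.asarray(ne, dtype=float)
    decay = _a_pow_t(ne, t) * (1.0 - c) ** np.asarray(t, dtype=float)
    out = d0 * (1.0 - c) * (1.0 - decay) / (2.0 * ne * c + 1.0 - c)
    return float(out) if np.ndim(out) == 0 else out


def expected_d_decay(d0, c, ne, t):
    """Expected LD coefficient after t generations of drift and recombination.

    ``E[D_t] = (1 - 1/(2Ne))^t (1-c)^t D0``.
    """
    c = _check_c(c)
    out = np.asarray(d0, dtype=float) * _a_pow_t(ne, t) * (1.0 - c) ** np.asarray(t, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def delta_variance(ne, s0, st, t):
    """Variance of the standardized frequency change delta at one locus.

    ``var(delta) = 1/(2 S0) + 1 - (1 - 1/(2Ne))^t (1 - 1/(2 St))``

    combining drift over t generations with plan-II binomial sampling noise
    at both time points. In the drift-free limit (``ne = inf``) it collapses
    to the pure sampling floor ``1/(2 S0) + 1/(2 St)``.
    """
    st_arr = np.asarray(st, dtype=float)
    out = 1.0 / (2.0 * np.asarray(s0, dtype=float)) + 1.0 - _a_pow_t(ne, t) * (
        1.0 - 1.0 / (2.0 * st_arr)
    )
    return float(out) if np.ndim(out) == 0 else out


def _linked_b(c, ne):
    """``B = (1-c) / (2 Ne c + 1 - c)``, the linked-pair drift kernel."""
    c = np.asarray(c, dtype=float)
    ne = np.asarray(ne, dtype=float)
    with np.errstate(invalid="ignore"):
        b = (1.0 - c) / (2.0 * ne * c + 1.0 - c)
    # ne = inf limit: B -> 0 for c > 0, B = 1 at c = 0.
    if np.ndim(b) == 0:
        if np.isnan(b):
            b = 1.0 if float(c) == 0.0 else 0.0
    else:
        bad = np.isnan(b)
        if np.any(bad):
            b = np.where(bad, np.where(np.broadcast_to(c, b.shape) == 0.0, 1.0, 0.0), b)
    return b


def delta_covariance(c, r0, ne, s0, st, t):
    """Covariance of standardized frequency changes at two linked loci.

    ``cov(delta_i, delta_j) = r0 { 1/(2 S0) + B - (1 - 1/(2Ne))^t (1-c)^t [B - 1/(2 St)] }``

    with ``B = (1-c)/(2 Ne c + 1 - c)``. Substituting ``c = 0, r0 = 1``
    (the covariance of a locus with itself) recovers :func:`delta_variance`
    exactly.
    """
    c = _check_c(c)
    r0 = np.asarray(r0, dtype=float)
    b = _linked_b(c, ne)
    decay = _a_pow_t(ne, t) * (1.0 - c) ** np.asarray(t, dtype=float)
    out = r0 * (
        1.0 / (2.0 * np.asarray(s0, dtype=float))
        + b
        - decay * (b - 1.0 / (2.0 * np.asarray(st, dtype=float)))
    )
    return float(out) if np.ndim(out) == 0 else out


def delta_correlation(c, r0, ne, s0, st, t):
    """Correlation of standardized changes at two linked loci.

    Quotient of :func:`delta_covariance` and :func:`delta_variance`; the
    variance of delta is treated as identical across loci (it depends only on
    Ne, S0, St and t). Equals ``r0`` at ``c = 0`` and shrinks toward 0 as c
    approaches 0.5.
    """
    out = delta_covariance(c, r0, ne, s0, st, t) / delta_variance(ne, s0, st, t)
    return float(out) if np.ndim(out) == 0 else out


def expected_f(ne, s0, st, t):
    """Expected value of the temporal F statistic, ``E[F] = var(delta)``."""
    return delta_variance(ne, s0, st, t)


def estimate_ne(f_hat, s0, st, t):
    """Moment point estimate of Ne from an observed temporal F statistic.

    ``Ne = t / (2 (F - 1/(2 S0) - 1/(2 St)))``, the small-drift inversion of
    the expected-F formula. When the observed F does not exceed the sampling
    floor there is no detectable drift signal and ``+inf`` is returned
    (never a negative estimate).
    """
    f_hat = np.asarray(f_hat, dtype=float)
    floor = 1.0 / (2.0 * np.asarray(s0, dtype=float)) + 1.0 / (2.0 * np.asarray(st, dtype=float))
    denom = f_hat - floor
    with np.errstate(divide="ignore"):
        out = np.where(denom > 0, np.asarray(t, dtype=float) / (2.0 * denom), np.inf)
    return float(out) if np.ndim(out) == 0 else out


def estimate_ne_exact(f_hat, s0, st, t):
    """Exact inversion of the expected-F formula for Ne.

    Solves ``F = 1/(2 S0) + 1 - (1 - 1/(2Ne))^t (1 - 1/(2 St))`` for Ne.
    Agrees with :func:`estimate_ne` to first order in ``1/Ne``; returns
    ``+inf`` when F is at or below the sampling floor.
    """
    f_hat = np.asarray(f_hat, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    st = np.asarray(st, dtype=float)
    t = np.asarray(t, dtype=float)
    ratio = (1.0 / (2.0 * s0) + 1.0 - f_hat) / (1.0 - 1.0 / (2.0 * st))
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where((ratio > 0) & (ratio < 1), ratio, np.nan) ** (1.0 / t)
        ne = 1.0 / (2.0 * (1.0 - a))
    ne = np.where(ratio >= 1, np.inf, ne)
    if np.any(np.asarray(ratio) <= 0):
        # F so large that even one generation of maximal drift cannot explain
        # it under the model; the strongest admissible drift is Ne -> smallest.
        ne = np.where(np.asarray(ratio) <= 0, 0.5, ne)
    return float(ne) if np.ndim(ne) == 0 else ne
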