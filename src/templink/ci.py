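"""Linkage-adjusted confidence intervals for the temporal F and Ne.

With K linked loci the scaled statistic ``K F_hat / F`` is no longer
chi-square with K degrees of freedom: the correlation among the standardized
changes ``delta_i`` widens its distribution. Writing R for the K x K
correlation matrix of the deltas, ``K F_hat / F`` is approximately
distributed as the quadratic form

    Q^2 = sum_i lambda_i Z_i^2,

a mixture of independent one-degree chi-squares weighted by the eigenvalues
``lambda_i`` of R (or of ``K W^{1/2} R W^{1/2}`` for the heterozygosity
weighted statistic F_b). Confidence intervals for F come from empirical
Monte-Carlo quantiles of Q^2 and map anti-monotonically onto Ne bounds.
When R = I the mixture collapses to the classical chi-square interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .moments import delta_correlation, estimate_ne

__all__ = [
    "CorrelationModel",
    "EigenSpectrum",
    "QSquaredSample",
    "NeEstimate",
    "build_R",
    "weighted_eigen_input",
    "eigen_spectrum",
    "eigen_spectrum_blocks",
    "sample_q2",
    "ci_for_f",
    "chisq_ci",
    "ci_for_ne",
    "effective_num_loci",
]


@dataclass(frozen=True)
class CorrelationModel:
    """Symmetric unit-diagonal correlation matrix of the standardized changes."""

    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("R must be square")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("R entries must lie in [-1, 1]; upstream r0 is broken")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("R must have unit diagonal")
        object.__setattr__(self, "r", r)

    @property
    def k(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class EigenSpectrum:
    """Non-negative eigenvalues, descending; their sum equals the trace K."""

    lambdas: np.ndarray

    @property
    def k(self) -> int:
        return len(self.lambdas)

    @property
    def sum(self) -> float:
        return float(self.lambdas.sum())

    @property
    def sum_sq(self) -> float:
        return float((self.lambdas**2).sum())


@dataclass(frozen=True)
class QSquaredSample:
    """Monte-Carlo draws of the eigenvalue mixture Q^2."""

    draws: np.ndarray
    seed: int | None = None

    def quantile(self, q) -> float:
        return float(np.quantile(self.draws, q))


@dataclass
class NeEstimate:
    """Point and interval estimates for F and Ne from one panel."""

    point: float
    ci_low: float
    ci_high: float
    f_hat: float
    f_ci_low: float
    f_ci_high: float
    k: int
    k_prime: float
    variant: str = "a"
    alpha: float = 0.05
    n_draws: int = 0
    seed: int | None = None
    spectrum_sum: float = float("nan")
    spectrum_sum_sq: float = float("nan")
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "K": self.k,
            "K_prime": self.k_prime,
            "F_hat": self.f_hat,
            "F_ci": [self.f_ci_low, self.f_ci_high],
            "Ne": self.point,
            "Ne_ci": [self.ci_low, self.ci_high],
            "alpha": self.alpha,
            "M": self.n_draws,
            "seed": self.seed,
            "spectrum": {"sum": self.spectrum_sum, "sum_sq": self.spectrum_sum_sq},
            **self.extra,
        }

    def to_json(self, **kwargs) -> str:
        def _enc(x):
            if isinstance(x, float) and np.isinf(x):
                return "inf"
            raise TypeError(x)

        return json.dumps(self.to_dict(), default=_enc, **kwargs)


def build_R(c_mat: np.ndarray, r0_mat: np.ndarray, ne: float, s0: int, st: int, t: int) -> np.ndarray:
    """K x K correlation matrix of the standardized changes.

    Off-diagonals follow the linked-pair correlation formula evaluated at the
    plug-in Ne (normally the moment point estimate; the resulting intervals
    are robust to order-of-magnitude mis-specification of this value).
    Diagonal is exactly 1.
    """
    r = delta_correlation(c_mat, r0_mat, ne, s0, st, t)
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, 1.0)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlation entries exceed 1 in magnitude; r0 input is broken")
    return 0.5 * (r + r.T)


def weighted_eigen_input(r: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """The matrix ``K W^{1/2} R W^{1/2}`` whose eigenvalues drive the F_b
    interval; trace is conserved at K because the weights sum to 1."""
    r = np.asarray(r, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(w) != r.shape[0]:
        raise ValueError("weight length must match R dimension")
    sw = np.sqrt(w)
    return r.shape[0] * (sw[:, None] * r * sw[None, :])


def eigen_spectrum(matrix: np.ndarray, repair: bool = False) -> EigenSpectrum:
    """Eigenvalues of a symmetric matrix, clipped and sorted descending.

    With ``repair=False`` (the strict contract for model-derived matrices):
    tiny negative values (> -1e-8 * K) are numerical noise and are clipped
    to zero; anything more negative signals a non-positive-semidefinite
    correlation model (i.e. a broken r0 correction) and raises.

    With ``repair=True`` (used on *estimated* correlation matrices): the
    sampling-bias correction of r0 zeroes sub-noise-floor entries, which can
    push a few per cent of the eigenvalue mass slightly negative even though
    the underlying population matrix is positive definite. Negative
    eigenvalues are then estimation artifacts: they are clipped to zero and
    the spectrum is rescaled to restore the trace (so E[Q^2] = K is
    preserved).
    """
    m = np.asarray(matrix, dtype=float)
    k = m.shape[0]
    lam = np.linalg.eigvalsh(m)
    trace = float(lam.sum())
    if not repair:
        tol = 1e-8 * k
        if lam[0] < -tol:
            raise ValueError(
                f"matrix is not positive semidefinite (min eigenvalue {lam[0]:.3e}); "
                "the correlation model is invalid"
            )
        lam = np.clip(lam, 0.0, None)
    else:
        lam = np.clip(lam, 0.0, None)
        s = float(lam.sum())
        if s > 0 and trace > 0:
            lam = lam * (trace / s)
    return EigenSpectrum(lambdas=lam[::-1].copy())


def eigen_spectrum_blocks(blocks: list[np.ndarray], repair: bool = False) -> EigenSpectrum:
    """Spectrum of a block-diagonal matrix as the union of block spectra.

    The large-K strategy: when cross-chromosome entries are dropped
    (c = 0.5 pairs contribute nearly nothing), R is block-diagonal per
    chromosome arm and each block can be solved independently.
    """
    lams = np.concatenate([eigen_spectrum(b, repair=repair).lambdas for b in blocks])
    return EigenSpectrum(lambdas=np.sort(lams)[::-1])


def sample_q2(
    spectrum: EigenSpectrum,
    n_draws: int,
    rng: np.random.Generator | int | None,
    chunk: int = 2_000_000,
) -> QSquaredSample:
    """Monte-Carlo draws of ``Q^2 = sum_i lambda_i Z_i^2``.

    ``E[Q^2] = sum lambda = K`` and ``var(Q^2) = 2 sum lambda^2``. Work is
    chunked over eigenvalues so memory stays bounded for large K.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lam = spectrum.lambdas
    draws = np.zeros(n_draws)
    block = max(1, chunk // n_draws)
    for start in range(0, len(lam), block):
        lam_b = lam[start : start + block]
        z = rng.standard_normal((n_draws, len(lam_b)))
        draws += (z * z) @ lam_b
    return QSquaredSample(draws=draws, seed=seed)


def ci_for_f(f_hat: float, q2: QSquaredSample, k: int, alpha: float = 0.05) -> tuple[float, float]:
    """Linkage-adjusted CI for F from empirical quantiles of Q^2:
    ``[K F_hat / q_{1-alpha/2}, K F_hat / q_{alpha/2}]``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    hi_q = q2.quantile(1 - alpha / 2)
    lo_q = q2.quantile(alpha / 2)
    return k * f_hat / hi_q, k * f_hat / lo_q


def chisq_ci(f_hat: float, k: int, alpha: float = 0.05) -> tuple[float, float]:
    """Classical independence-assuming CI for F from chi-square quantiles:
    ``[K F_hat / chi2_{K,1-alpha/2}, K F_hat / chi2_{K,alpha/2}]``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return (
        k * f_hat / stats.chi2.ppf(1 - alpha / 2, df=k),
        k * f_hat / stats.chi2.ppf(alpha / 2, df=k),
    )


def ci_for_ne(f_low: float, f_high: float, s0: int, st: int, t: int) -> tuple[float, float]:
    """Map an F interval onto an Ne interval (anti-monotone): the lower F
    bound gives the upper Ne bound (possibly +inf) and vice versa."""
    if f_low > f_high:
        raise ValueError("f_low must not exceed f_high")
    return estimate_ne(f_high, s0, st, t), estimate_ne(f_low, s0, st, t)


def effective_num_loci(spectrum: EigenSpectrum) -> float:
    """Effective number of independent loci,
    ``K' = 2 K^2 / var(Q^2) = K^2 / sum lambda^2``.

    Equals K for uncorrelated loci and 1 when all loci are perfectly
    correlated (rank-1 R): the pseudoreplication discount.
    """
    return spectrum.k**2 / spectrum.sum_sq
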