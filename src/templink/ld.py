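"""Pairwise standardized LD (r) in the first temporal sample.

The correlation matrix of standardized frequency changes needs, for every
pair of loci, the initial LD ``r0`` and the recombination fraction ``c``.
This module estimates ``r0`` from phased haplotypes (direct counting) or
unphased genotypes (EM maximum likelihood under Hardy-Weinberg, with a
Burrows-style composite fallback), applies a sampling-bias correction, and
attaches recombination fractions from a genetic map.

Raw r estimates are inflated by finite sampling: for weak LD,
``E[r_hat^2] ~ r^2 + 1/n`` with ``n`` sampled haplotypes. The correction
subtracts that expected sampling contribution on the r^2 scale and
back-transforms preserving sign, truncating at zero.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .fstats import LocusPanel
from .moments import GeneticMapConfig, PairLinkage

__all__ = [
    "r0_phased",
    "r0_unphased",
    "r_matrix_phased",
    "r_matrix_unphased",
    "composite_r",
    "bias_correct_r0",
    "recomb_fraction_matrix",
    "pairwise_linkage",
]


def _check_poly(freqs: np.ndarray, what: str) -> None:
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError(f"monomorphic locus in {what}; filter before LD estimation")


def r0_phased(haplotypes: np.ndarray, i: int, j: int) -> float:
    """Standardized LD between loci i and j from phased 0/1 haplotypes.

    ``r = D / sqrt(p_i (1-p_i) p_j (1-p_j))`` with ``D = p_AB - p_A p_B``
    from direct haplotype counting (maximum likelihood for phased data).
    """
    h = np.asarray(haplotypes)
    hi, hj = h[:, i].astype(float), h[:, j].astype(float)
    pi, pj = hi.mean(), hj.mean()
    _check_poly(np.array([pi, pj]), "haplotype block")
    d = (hi * hj).mean() - pi * pj
    return float(d / np.sqrt(pi * (1 - pi) * pj * (1 - pj)))


def r_matrix_phased(haplotypes: np.ndarray) -> np.ndarray:
    """All-pairs phased r as a K x K matrix (unit diagonal).

    Identical to the Pearson correlation matrix of the 0/1 haplotype columns,
    since the haplotype-count D equals the sample covariance (MLE scaling)
    and the normalization cancels.
    """
    h = np.asarray(haplotypes, dtype=float)
    _check_poly(h.mean(axis=0), "haplotype block")
    r = np.corrcoef(h, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def composite_r(genotypes: np.ndarray, i: int | None = None, j: int | None = None):
    """Burrows-style composite LD correlation from diploid dosages.

    The correlation of 0/1/2 allele dosages; under Hardy-Weinberg its
    expectation matches the gametic r, but it does not assume HWE. Used as
    the fallback when the EM estimator fails to converge.
    """
    g = np.asarray(genotypes, dtype=float)
    if i is not None:
        g = g[:, [i, j]]
    p = g.mean(axis=0) / 2.0
    _check_poly(p, "genotype block")
    r = np.corrcoef(g, rowvar=False)
    if i is not None:
        return float(np.clip(r[0, 1], -1.0, 1.0))
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _em_update(p11, pa, pb, n11, n_dh, two_n):
    """One EM step for the cis haplotype frequency given fixed margins.

    ``n11`` is the deterministic haplotype-11 count from unambiguous
    genotypes, ``n_dh`` the double-heterozygote count whose cis/trans split
    is latent.
    """
    p10 = pa - p11
    p01 = pb - p11
    p00 = 1.0 - pa - pb + p11
    cis = p11 * p00
    trans = p10 * p01
    denom = cis + trans
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_cis = np.where(denom > 0, cis / denom, 0.5)
    return (n11 + n_dh * pi_cis) / two_n


def r0_unphased(
    genotypes: np.ndarray,
    i: int,
    j: int,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> float:
    """Maximum-likelihood r between loci i and j from unphased genotypes.

    EM over the double-heterozygote phase ambiguity under Hardy-Weinberg,
    on complete cases. Missing entries may be coded as negative or NaN.
    Falls back to the composite estimator if EM does not converge.
    """
    g = np.asarray(genotypes, dtype=float)
    gi, gj = g[:, i], g[:, j]
    ok = ~(np.isnan(gi) | np.isnan(gj) | (gi < 0) | (gj < 0))
    gi, gj = gi[ok], gj[ok]
    if len(gi) < 2:
        raise ValueError("need at least 2 complete-case individuals")
    r, converged = _em_r(gi.reshape(-1, 1), gj.reshape(-1, 1), max_iter=max_iter, tol=tol)
    if not bool(np.all(converged)):
        return composite_r(np.column_stack([gi, gj]), 0, 1)
    return float(np.ravel(r)[0])


def _em_r(gi, gj, max_iter: int = 200, tol: float = 1e-9):
    """Vectorized EM for haplotype frequencies of genotype column pairs.

    ``gi``/``gj`` are (n_individuals, m) dosage arrays; pair p is column p of
    each. Returns (r array of shape (m, m is 1-D here...), converged mask).
    Internal: used by both the scalar and the all-pairs interfaces.
    """
    n = gi.shape[0]
    two_n = 2.0 * n
    # deterministic haplotype-11 contributions per pair:
    #   hom-alt/hom-alt -> 2; hom-alt/het and het/hom-alt -> 1
    i2 = (gi == 2).astype(float)
    i1 = (gi == 1).astype(float)
    j2 = (gj == 2).astype(float)
    j1 = (gj == 1).astype(float)
    n11 = 2.0 * (i2 * j2).sum(axis=0) + (i2 * j1).sum(axis=0) + (i1 * j2).sum(axis=0)
    n_dh = (i1 * j1).sum(axis=0)
    pa = gi.mean(axis=0) / 2.0
    pb = gj.mean(axis=0) / 2.0
    p11 = pa * pb  # linkage-equilibrium start
    converged = np.zeros(p11.shape, dtype=bool)
    for _ in range(max_iter):
        new = _em_update(p11, pa, pb, n11, n_dh, two_n)
        # respect the frequency simplex margins
        lo = np.maximum(0.0, pa + pb - 1.0)
        hi = np.minimum(pa, pb)
        new = np.clip(new, lo, hi)
        converged = np.abs(new - p11) < tol
        p11 = new
        if np.all(converged):
            break
    d = p11 - pa * pb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = d / np.sqrt(pa * (1 - pa) * pb * (1 - pb))
    return np.clip(r, -1.0, 1.0), converged


def r_matrix_unphased(genotypes: np.ndarray, max_iter: int = 200, tol: float = 1e-9) -> np.ndarray:
    """All-pairs unphased r as a K x K matrix via vectorized EM.

    Requires complete (non-missing) dosages; loci with missing calls should
    be handled upstream. Non-converged pairs fall back to the composite
    estimator.
    """
    g = np.asarray(genotypes, dtype=float)
    n, k = g.shape
    p = g.mean(axis=0) / 2.0
    _check_poly(p, "genotype block")
    i2 = (g == 2).astype(float)
    i1 = (g == 1).astype(float)
    # pairwise counts via matrix products over individuals
    n22 = i2.T @ i2
    n21 = i2.T @ i1
    n12 = i1.T @ i2
    n11_dh = i1.T @ i1
    det11 = 2.0 * n22 + n21 + n12
    pa = p[:, None]
    pb = p[None, :]
    two_n = 2.0 * n
    p11 = pa * pb
    lo = np.maximum(0.0, pa + pb - 1.0)
    hi = np.minimum(pa, pb)
    converged = np.zeros_like(p11, dtype=bool)
    for _ in range(max_iter):
        new = np.clip(_em_update(p11, pa, pb, det11, n11_dh, two_n), lo, hi)
        converged = np.abs(new - p11) < tol
        p11 = new
        if np.all(converged):
            break
    d = p11 - pa * pb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip(d / np.sqrt(pa * (1 - pa) * pb * (1 - pb)), -1.0, 1.0)
    if not np.all(converged):
        comp = composite_r(g)
        r = np.where(converged, r, comp)
    np.fill_diagonal(r, 1.0)
    return r


def bias_correct_r0(r_hat, n_units: int):
    """Shrink a raw r estimate for its finite-sampling inflation.

    ``r0 = sign(r_hat) sqrt(max(0, r_hat^2 - 1/n_units))`` with ``n_units``
    the number of sampled haplotypes (2 S0). Sign-preserving, magnitude
    non-increasing, and exactly zero at or below the sampling noise floor.
    """
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    r_hat = np.asarray(r_hat, dtype=float)
    out = np.sign(r_hat) * np.sqrt(np.maximum(0.0, r_hat**2 - 1.0 / n_units))
    return float(out) if np.ndim(out) == 0 else out


def recomb_fraction_matrix(
    chrom: np.ndarray, pos: np.ndarray, map_config: GeneticMapConfig
) -> np.ndarray:
    """K x K recombination fractions from genomic coordinates.

    Same-chromosome pairs go through the map's mapping function on the
    absolute bp distance; cross-chromosome pairs follow the map's
    inter-arm rule (default: unlinked, c = 0.5). Diagonal is 0.
    """
    pos = np.asarray(pos, dtype=float)
    dist = np.abs(pos[:, None] - pos[None, :])
    c = np.asarray(map_config.recomb_fraction(dist), dtype=float)
    chrom = np.asarray(chrom).astype(str)
    if map_config.inter_arm_rule == "unlinked":
        same = chrom[:, None] == chrom[None, :]
        c = np.where(same, c, 0.5)
    np.fill_diagonal(c, 0.0)
    return c


def pairwise_linkage(
    panel: LocusPanel,
    block: np.ndarray,
    map_config: GeneticMapConfig,
    phased: bool = True,
    bias_correct: bool = True,
    n_units: int | None = None,
) -> Iterator[tuple[int, int, PairLinkage]]:
    """Iterate over all K(K-1)/2 locus pairs as (i, j, PairLinkage).

    Convenience view over :func:`linkage_matrices` for modest K; the matrix
    interface is what the pipeline itself consumes.
    """
    c_mat, r_mat = linkage_matrices(
        panel, block, map_config, phased=phased, bias_correct=bias_correct, n_units=n_units
    )
    k = panel.n_loci
    for i in range(k):
        for j in range(i + 1, k):
            yield i, j, PairLinkage(c=float(c_mat[i, j]), r0=float(r_mat[i, j]))


def linkage_matrices(
    panel: LocusPanel,
    block: np.ndarray,
    map_config: GeneticMapConfig,
    phased: bool = True,
    bias_correct: bool = True,
    n_units: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Recombination-fraction and corrected-r0 matrices for a locus panel.

    ``block`` is the first temporal sample: a (2*S0, K) haplotype matrix when
    ``phased`` else an (S0, K) dosage matrix. ``n_units`` defaults to the
    number of sampled haplotypes (2*S0) for both data types.
    """
    block = np.asarray(block)
    if block.shape[1] != panel.n_loci:
        raise ValueError("block columns must match panel loci")
    c_mat = recomb_fraction_matrix(panel.chrom, panel.pos, map_config)
    r_raw = r_matrix_phased(block) if phased else r_matrix_unphased(block)
    if n_units is None:
        n_units = block.shape[0] if phased else 2 * block.shape[0]
    r0 = bias_correct_r0(r_raw, n_units) if bias_correct else r_raw
    np.fill_diagonal(r0, 1.0)
    return c_mat, r0
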