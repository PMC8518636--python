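"""Forward Wright-Fisher simulation with recombination and plan-II sampling.

Two layers:

* a vectorized **two-locus** simulator (haplotype-frequency state, multinomial
  drift) used as the Monte-Carlo oracle for the closed-form drift moments;
* a **chromosome** simulator tracking a population of ``2*Ne`` haplotypes over
  K marker columns, with crossovers between adjacent markers, used to drive
  the replicate coverage study and to generate end-to-end VCF fixtures.

Only retained marker columns are simulated; recombination between adjacent
retained markers compounds the per-bp rate over their bp gap, which is
exactly equivalent for pairwise LD dynamics. Crossovers are realized as a
sparse event process whose per-interval switch indicators are independent
Bernoulli(c_interval) (see docs for the parity argument), so pairwise
recombination fractions between any two markers obey the geometric
compounding formula exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ci as ci_mod
from .fstats import LocusPanel, f_a, f_b, maf_filter
from .ld import bias_correct_r0, r_matrix_phased, r_matrix_unphased
from .moments import estimate_ne, expected_f, simulated_pair_c

try:  # numba accelerates the gamete-assembly inner loop; numpy path is exact too
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "SimConfig",
    "TwoLocusState",
    "step_two_locus",
    "simulate_two_locus",
    "simulate_chromosome",
    "ChromosomeSim",
    "sample_plan_ii",
    "unphase",
    "run_replicate_study",
]


@dataclass(frozen=True)
class TwoLocusState:
    """Haplotype frequencies of a two-locus biallelic system.

    ``p11, p10, p01, p00`` are the frequencies of haplotypes carrying
    (allele-1, allele-1), (1, 0), (0, 1) and (0, 0); they sum to 1 and
    ``D = p11 p00 - p10 p01``.
    """

    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must be non-negative and sum to 1")

    @classmethod
    def from_freqs(cls, p_i: float, p_j: float, d: float) -> "TwoLocusState":
        """Build from marginal allele frequencies and the LD coefficient D."""
        probs = np.array(
            [p_i * p_j + d, p_i * (1 - p_j) - d, (1 - p_i) * p_j - d, (1 - p_i) * (1 - p_j) + d]
        )
        if np.any(probs < -1e-12):
            raise ValueError("inconsistent (p_i, p_j, D): negative haplotype frequency")
        return cls(*np.clip(probs, 0.0, 1.0))

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p10, self.p01, self.p00])


def _gamete_freqs(state: np.ndarray, c: float) -> np.ndarray:
    """Deterministic recombination: shift each haplotype frequency by -+ c D."""
    d = state[..., 0] * state[..., 3] - state[..., 1] * state[..., 2]
    shift = c * d[..., None] * np.array([-1.0, 1.0, 1.0, -1.0])
    return np.clip(state + shift, 0.0, 1.0)


def step_two_locus(state, c: float, ne: float, rng: np.random.Generator):
    """One Wright-Fisher generation: recombination then multinomial(2 Ne) drift.

    ``state`` is a length-4 array (or a batch with trailing axis 4) of
    haplotype frequencies; returns frequencies in the next generation.
    """
    arr = state.as_array() if isinstance(state, TwoLocusState) else np.asarray(state, dtype=float)
    gam = _gamete_freqs(arr, c)
    gam = gam / gam.sum(axis=-1, keepdims=True)
    counts = rng.multinomial(int(round(2 * ne)), gam)
    out = counts / (2.0 * ne)
    if isinstance(state, TwoLocusState):
        return TwoLocusState(*out)
    return out


def simulate_two_locus(
    p0: TwoLocusState,
    c: float,
    ne: float,
    t: int,
    reps: int,
    seed=None,
) -> np.ndarray:
    """Replicate two-locus trajectories; returns haplotype frequencies at
    generation t as a (reps, 4) array.

    The Monte-Carlo oracle for the closed-form drift covariance and LD decay:
    empirical ``cov(p_it, p_jt)`` and ``E[D_t]`` across replicates match the
    formulas within Monte-Carlo error.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    state = np.broadcast_to(p0.as_array(), (reps, 4)).copy()
    for _ in range(t):
        state = step_two_locus(state, c, ne, rng)
    return state


# ---------------------------------------------------------------------------
# chromosome-scale forward simulation


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the chromosome simulator.

    Defaults are the simulation protocol used throughout the validation
    study: a 1e5 bp chromosome, per-adjacent-bp recombination 1e-5 per
    generation, mutation 1e-6 per bp per generation (in the equilibrium
    initialization; off during the short sampling interval), samples of 50
    diploids taken t = 10 generations apart from a population of Ne = 1000
    diploids, and loci filtered at 5% MAF.
    """

    ne: int = 1000
    length_bp: int = 100_000
    per_bp_rate: float = 1e-5
    mu: float = 1e-6
    t: int = 10
    s0: int = 50
    st: int = 50
    k_target: int = 500
    k_init: int | None = None  # forward mode only; default 3 * k_target
    maf: float = 0.05
    initialization: str = "coalescent"  # "coalescent" | "forward"
    burn_in: int | None = None  # forward mode; default max(4 / median pairwise c, 200)
    dtwf_generations: int = 100  # coalescent mode: recent history simulated exactly
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.ne >= 1 and self.length_bp >= 2 and self.t >= 0):
            raise ValueError("ne, length_bp must be positive; t >= 0")
        if not 0.0 <= self.per_bp_rate <= 0.5:
            raise ValueError("per_bp_rate must be in [0, 0.5]")
        if self.initialization not in ("coalescent", "forward"):
            raise ValueError("initialization must be 'coalescent' or 'forward'")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass
class ChromosomeSim:
    """Population truth produced by :func:`simulate_chromosome`."""

    config: SimConfig
    positions: np.ndarray  # 1-based bp coordinates of retained loci
    hap0: np.ndarray  # (2 Ne, K) population haplotypes at generation 0
    hap_t: np.ndarray  # (2 Ne, K) population haplotypes at generation t

    @property
    def k(self) -> int:
        return len(self.positions)

    @property
    def p0(self) -> np.ndarray:
        return self.hap0.mean(axis=0)

    @property
    def p_t(self) -> np.ndarray:
        return self.hap_t.mean(axis=0)

    def pair_c(self) -> np.ndarray:
        """True pairwise recombination fractions between retained loci."""
        dist = np.abs(self.positions[:, None] - self.positions[None, :])
        c = simulated_pair_c(dist, self.config.per_bp_rate)
        np.fill_diagonal(c, 0.0)
        return c


if _HAVE_NUMBA:

    @njit(cache=False)
    def _assemble_gametes(hap, p1, p2, ev_g, ev_iv, out):  # pragma: no cover - jit
        n, k = out.shape
        idx = 0
        m = ev_g.shape[0]
        for g in range(n):
            cur = p1[g]
            other = p2[g]
            start = 0
            while idx < m and ev_g[idx] == g:
                stop = ev_iv[idx] + 1
                for col in range(start, stop):
                    out[g, col] = hap[cur, col]
                cur, other = other, cur
                start = stop
                idx += 1
            for col in range(start, k):
                out[g, col] = hap[cur, col]

else:  # pragma: no cover - exercised only without numba

    def _assemble_gametes(hap, p1, p2, ev_g, ev_iv, out):
        n, k = out.shape
        bounds = np.searchsorted(ev_g, np.arange(n + 1))
        for g in range(n):
            cur, other = p1[g], p2[g]
            start = 0
            for e in range(bounds[g], bounds[g + 1]):
                stop = ev_iv[e] + 1
                out[g, start:stop] = hap[cur, start:stop]
                cur, other = other, cur
                start = stop
            out[g, start:k] = hap[cur, start:k]


def _next_generation(hap: np.ndarray, cum_d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One generation of random union of gametes with crossover.

    ``cum_d`` holds cumulative map intensities ``d_k = -0.5 ln(1 - 2 c_k)``
    over the K-1 adjacent-marker intervals. Crossover events form a Poisson
    process on this map, whose per-interval parity is an independent
    Bernoulli(c_k) switch — the interference-free crossover model.
    """
    n = hap.shape[0]
    p1 = rng.integers(0, n, n)
    p2 = rng.integers(0, n, n)
    total = cum_d[-1] if len(cum_d) else 0.0
    if total > 0:
        n_ev = rng.poisson(n * total)
        ev_g = rng.integers(0, n, n_ev)
        ev_iv = np.searchsorted(cum_d, rng.random(n_ev) * total, side="right").astype(np.int64)
        order = np.lexsort((ev_iv, ev_g))
        ev_g = np.ascontiguousarray(ev_g[order])
        ev_iv = np.ascontiguousarray(ev_iv[order])
    else:
        ev_g = np.empty(0, dtype=np.int64)
        ev_iv = np.empty(0, dtype=np.int64)
    out = np.empty_like(hap)
    _assemble_gametes(hap, p1, p2, ev_g, ev_iv, out)
    return out


def _mutate(hap: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    """Symmetric allele flips at rate mu per marker column per haplotype."""
    if mu <= 0:
        return
    n_mut = rng.poisson(mu * hap.size)
    if n_mut:
        rows = rng.integers(0, hap.shape[0], n_mut)
        cols = rng.integers(0, hap.shape[1], n_mut)
        hap[rows, cols] ^= 1


def _interval_intensities(positions: np.ndarray, per_bp_rate: float) -> np.ndarray:
    gaps = np.diff(positions)
    c = simulated_pair_c(gaps, per_bp_rate)
    return np.cumsum(-0.5 * np.log1p(-2.0 * np.asarray(c)))


def _default_burn_in(positions: np.ndarray, per_bp_rate: float) -> int:
    dist = np.abs(positions[:, None] - positions[None, :])
    c = np.asarray(simulated_pair_c(dist, per_bp_rate))
    c_med = float(np.median(c[np.triu_indices(len(positions), 1)]))
    if c_med <= 0:
        return 200
    return int(max(4.0 / c_med, 200.0))


def _coalescent_population(cfg: SimConfig, rng: np.random.Generator):
    """Generation-0 population at mutation-drift-recombination equilibrium.

    The whole population (2 Ne haplotypes) is generated by a coalescent
    simulation (msprime): discrete-time Wright-Fisher for the most recent
    ``dtwf_generations`` generations (exact when the sample size equals the
    population size) switching to the standard coalescent deeper in time,
    with binary mutations at rate ``mu`` per bp. Returns (positions, hap)
    for candidate segregating sites.
    """
    import msprime

    seed1, seed2 = (int(s) for s in rng.integers(1, 2**31 - 1, 2))
    models = [
        msprime.DiscreteTimeWrightFisher(duration=cfg.dtwf_generations),
        msprime.StandardCoalescent(),
    ]
    ts = msprime.sim_ancestry(
        samples=cfg.ne,
        population_size=cfg.ne,
        ploidy=2,
        sequence_length=float(cfg.length_bp),
        recombination_rate=cfg.per_bp_rate,
        model=models,
        random_seed=seed1,
    )
    ts = msprime.sim_mutations(
        ts, rate=cfg.mu, model=msprime.BinaryMutationModel(), random_seed=seed2
    )
    if ts.num_sites == 0:
        raise ValueError("no segregating sites; increase mu or length_bp")
    hap = ts.genotype_matrix().T.astype(np.uint8)  # (2 Ne, sites)
    positions = ts.tables.sites.position.astype(np.int64) + 1  # 1-based bp
    return positions, hap


def _forward_population(cfg: SimConfig, rng: np.random.Generator):
    """Forward-only initialization: independent loci with a truncated-1/x
    frequency spectrum, followed by a drift/recombination/mutation burn-in.

    Without recurrent mutation at meaningful rates the conditional LD level
    keeps growing with burn-in length (there is no stationary state), so
    this mode is a diagnostic tool; the coalescent initialization is the
    study default.
    """
    k_init = cfg.k_init if cfg.k_init is not None else 3 * cfg.k_target
    positions = np.sort(rng.choice(np.arange(1, cfg.length_bp + 1), size=k_init, replace=False))
    two_ne = 2 * cfg.ne
    lo, hi = 1.0 / two_ne, 1.0 - 1.0 / two_ne
    u = rng.random(k_init)
    freqs = lo * (hi / lo) ** u
    hap = (rng.random((two_ne, k_init)) < freqs).astype(np.uint8)

    cum_d = _interval_intensities(positions, cfg.per_bp_rate)
    burn_in = cfg.burn_in if cfg.burn_in is not None else _default_burn_in(positions, cfg.per_bp_rate)
    for _ in range(burn_in):
        hap = _next_generation(hap, cum_d, rng)
        _mutate(hap, cfg.mu, rng)
    return positions, hap


def simulate_chromosome(cfg: SimConfig, rng: np.random.Generator | None = None) -> ChromosomeSim:
    """Simulate a chromosome of biallelic markers through the study design.

    The generation-0 population (2 Ne haplotypes) is initialized at
    equilibrium — by coalescent simulation with recombination and mutation
    (default), or by the forward truncated-1/x + burn-in scheme
    (``initialization="forward"``). Of the candidate sites, up to
    ``k_target`` whose population MAF at generation 0 passes the configured
    threshold are retained (a shortfall simply yields fewer loci). The
    population then evolves ``t`` further generations of random union of
    gametes with crossovers between adjacent retained markers (mutation off:
    the sampling horizon is short) to the second time point.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.initialization == "coalescent":
        positions, hap = _coalescent_population(cfg, rng)
    else:
        positions, hap = _forward_population(cfg, rng)

    p = hap.mean(axis=0)
    seg = np.minimum(p, 1 - p) >= cfg.maf
    idx = np.flatnonzero(seg)
    if len(idx) > cfg.k_target:
        idx = np.sort(rng.choice(idx, size=cfg.k_target, replace=False))
    hap0 = np.ascontiguousarray(hap[:, idx])
    positions = positions[idx]

    cum_d = _interval_intensities(positions, cfg.per_bp_rate)
    hap_t = hap0
    for _ in range(cfg.t):
        hap_t = _next_generation(hap_t, cum_d, rng)
    return ChromosomeSim(config=cfg, positions=positions, hap0=hap0, hap_t=hap_t)


def sample_plan_ii(population: np.ndarray, s: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``2 s`` haplotypes with replacement from the population gamete
    pool (sampling plan II: the population itself is untouched)."""
    if s < 1:
        raise ValueError("s must be >= 1")
    rows = rng.integers(0, population.shape[0], 2 * s)
    return population[rows].copy()


def unphase(haplotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Collapse a haplotype sample to unphased dosages by random disjoint
    pairing: genotype of each synthetic diploid is the sum of its two
    haplotypes. Allele frequencies are preserved exactly."""
    n = haplotypes.shape[0]
    if n % 2:
        raise ValueError("need an even number of haplotypes to pair")
    perm = rng.permutation(n)
    h = haplotypes[perm]
    return (h[0::2].astype(np.int16) + h[1::2]).astype(np.int16)


# ---------------------------------------------------------------------------
# replicate coverage study


def _estimate_one(
    sim: ChromosomeSim,
    rng: np.random.Generator,
    statistic: str,
    n_draws: int,
    alpha: float,
    unphased: bool,
):
    """Sample, filter, and run the full estimation path on one simulated
    population; returns a per-replicate result row (dict)."""
    cfg = sim.config
    samp0 = sample_plan_ii(sim.hap0, cfg.s0, rng)
    sampt = sample_plan_ii(sim.hap_t, cfg.st, rng)
    x0 = samp0.mean(axis=0)
    xt = sampt.mean(axis=0)
    panel = LocusPanel(
        chrom=np.repeat("1", sim.k), pos=sim.positions, x0=x0, xt=xt
    )
    panel, keep = maf_filter(panel, cfg.maf)
    k = panel.n_loci
    est = f_b(panel) if statistic == "b" else f_a(panel)
    ne_hat = estimate_ne(est.value, cfg.s0, cfg.st, cfg.t)

    if unphased:
        geno0 = unphase(samp0[:, keep], rng)
        r_raw = r_matrix_unphased(geno0)
    else:
        r_raw = r_matrix_phased(samp0[:, keep])
    r0 = bias_correct_r0(r_raw, 2 * cfg.s0)
    np.fill_diagonal(r0, 1.0)
    c_mat = sim.pair_c()[np.ix_(keep.nonzero()[0], keep.nonzero()[0])]
    big_r = ci_mod.build_R(c_mat, r0, ne_hat, cfg.s0, cfg.st, cfg.t)
    mat = ci_mod.weighted_eigen_input(big_r, est.weights) if statistic == "b" else big_r
    spectrum = ci_mod.eigen_spectrum(mat, repair=True)
    q2 = ci_mod.sample_q2(spectrum, n_draws, rng)
    f_lo, f_hi = ci_mod.ci_for_f(est.value, q2, k, alpha)
    chi_lo, chi_hi = ci_mod.chisq_ci(est.value, k, alpha)
    return {
        "K": k,
        "F_hat": est.value,
        "Ne_hat": ne_hat,
        "F_lo": f_lo,
        "F_hi": f_hi,
        "chi_lo": chi_lo,
        "chi_hi": chi_hi,
        "K_prime": ci_mod.effective_num_loci(spectrum),
    }


def run_replicate_study(
    cfg: SimConfig,
    n_reps: int,
    statistic: str = "a",
    n_draws: int = 10_000,
    alpha: float = 0.05,
    phased: bool = True,
    unphased: bool = False,
    seed=None,
    progress: bool = False,
) -> dict:
    """Replicate the simulation study: per replicate, simulate a population,
    draw plan-II samples, compute the temporal F and Ne, the
    linkage-adjusted CI (phased and/or unphased LD path) and the naive
    chi-square CI, and score each CI against the true F.

    Returns a dict with the per-replicate table (pandas DataFrame) and
    summary rows: mean and SD of F_hat, the corresponding Ne, and coverage
    fractions for each CI flavour.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    true_f = expected_f(cfg.ne, cfg.s0, cfg.st, cfg.t)
    ss = np.random.SeedSequence(seed)
    rows = []
    paths = []
    if phased:
        paths.append(False)
    if unphased:
        paths.append(True)
    if not paths:
        raise ValueError("at least one of phased/unphased must be requested")
    for rep, child in enumerate(ss.spawn(n_reps)):
        rng = np.random.default_rng(child)
        sim = simulate_chromosome(replace(cfg, seed=None), rng=rng)
        for unph in paths:
            res = _estimate_one(sim, rng, statistic, n_draws, alpha, unph)
            res["rep"] = rep
            res["ld_data"] = "unphased" if unph else "phased"
            res["covered_adj"] = bool(res["F_lo"] <= true_f <= res["F_hi"])
            res["covered_chisq"] = bool(res["chi_lo"] <= true_f <= res["chi_hi"])
            rows.append(res)
        if progress and (rep + 1) % 10 == 0:  # pragma: no cover
            print(f"  replicate {rep + 1}/{n_reps}", flush=True)
    table = pd.DataFrame(rows)
    summary = {"true_F": true_f, "n_reps": n_reps, "statistic": statistic}
    for name, grp in table.groupby("ld_data"):
        summary[name] = {
            "mean_F_hat": float(grp["F_hat"].mean()),
            "sd_F_hat": float(grp["F_hat"].std(ddof=1)) if len(grp) > 1 else float("nan"),
            "ne_of_mean_F": estimate_ne(float(grp["F_hat"].mean()), cfg.s0, cfg.st, cfg.t),
            "mean_K": float(grp["K"].mean()),
            "mean_K_prime": float(grp["K_prime"].mean()),
            "coverage_adjusted": float(grp["covered_adj"].mean()),
            "coverage_chisq": float(grp["covered_chisq"].mean()),
        }
    return {"table": table, "summary": summary}
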