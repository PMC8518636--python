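"""VCF ingestion, panel construction and the end-to-end pipeline.

Reads biallelic SNPs for two temporal samples from one VCF with two
sample-ID lists (or two separate VCFs, intersected on chrom/pos/ref/alt),
builds the frequency panel plus the generation-0 LD block, applies the MAF
and window-pruning filters, and fits the temporal Ne model per chromosome
arm and for all arms combined. A minimal text-VCF writer lets the simulator
exercise the same path end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fstats import LocusPanel, maf_filter, standardized_delta, window_prune
from .model import TemporalNe, TemporalNeResults
from .moments import GeneticMapConfig, TemporalDesign

logger = logging.getLogger("templink")

__all__ = ["RunConfig", "read_panel", "run_pipeline", "write_two_sample_vcf"]


@dataclass
class RunConfig:
    """Configuration of one estimation run (the CLI surface mirrors this)."""

    vcf: str
    samples0: list[str]
    samples_t: list[str]
    t: int
    vcf_t: str | None = None  # second VCF holding the later sample
    map_config: GeneticMapConfig = field(default_factory=GeneticMapConfig)
    maf: float = 0.05
    window_bp: int | None = 1000
    statistic: str = "a"
    phased: bool = False
    n_draws: int = 50_000
    alpha: float = 0.05
    seed: int | None = None
    chroms: list[str] | None = None
    max_dense_k: int = 20_000
    missing_max: float = 0.10

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if self.vcf_t is None and set(self.samples0) & set(self.samples_t):
            raise ValueError("sample lists must be disjoint")


def _read_vcf(
    path: str,
    samples: list[str],
    chroms: list[str] | None,
    want_block: bool,
    phased: bool,
    missing_max: float,
):
    """One pass over a VCF for one sample subset.

    Returns (keys, freqs, block, counts): per-locus (chrom, pos, ref, alt)
    keys, ALT allele frequencies over non-missing calls, optionally the
    haplotype (phased) or dosage matrix, and skip counters.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, samples=samples)
    found = set(vcf.samples)
    missing_ids = [s for s in samples if s not in found]
    if missing_ids:
        raise ValueError(f"sample IDs absent from {path}: {missing_ids}")
    keys, freqs, cols = [], [], []
    counts = {"records": 0, "non_biallelic_snp": 0, "too_missing": 0, "unphased_dropped": 0}
    chromset = set(chroms) if chroms else None
    for v in vcf:
        counts["records"] += 1
        if chromset is not None and v.CHROM not in chromset:
            continue
        if len(v.REF) != 1 or len(v.ALT) != 1 or len(v.ALT[0]) != 1:
            counts["non_biallelic_snp"] += 1
            continue
        g = np.array(v.genotypes, dtype=np.int16)  # (n, 3): allele, allele, phased
        alleles = g[:, :2]
        ok = alleles >= 0
        n_ok = ok.sum()
        if n_ok == 0 or (alleles.size - n_ok) / alleles.size > missing_max:
            counts["too_missing"] += 1
            continue
        freq = alleles[ok].sum() / n_ok
        if want_block:
            if phased:
                if not np.all(g[:, 2] == 1) or not np.all(ok):
                    counts["unphased_dropped"] += 1
                    continue
                cols.append(alleles.reshape(-1).astype(np.int8))
            else:
                dose = alleles.astype(float)
                dose[~ok] = np.nan
                d = np.nansum(dose, axis=1)
                both_missing = ~ok.any(axis=1)
                # mean-impute missing dosages for LD estimation only
                half = ok.sum(axis=1) == 1
                d[half] += freq
                d[both_missing] = 2 * freq
                cols.append(d)
        keys.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        freqs.append(freq)
    block = np.column_stack(cols) if cols else None
    return keys, np.array(freqs), block, counts


def read_panel(config: RunConfig):
    """Build the locus panel and the generation-0 LD block from VCF input.

    Returns (panel, block0, log dict). Loci are intersected on
    (chrom, pos, ref, alt) when two VCFs are used, and sorted by (chrom, pos).
    """
    keys0, x0, block0, c0 = _read_vcf(
        config.vcf, config.samples0, config.chroms, True, config.phased, config.missing_max
    )
    path_t = config.vcf_t or config.vcf
    keys_t, xt, _, ct = _read_vcf(
        path_t, config.samples_t, config.chroms, False, config.phased, config.missing_max
    )
    index_t = {k: i for i, k in enumerate(keys_t)}
    pairs = [(i, index_t[k]) for i, k in enumerate(keys0) if k in index_t]
    if not pairs:
        raise ValueError("no loci shared between the two time points after filters")
    i0 = np.array([p[0] for p in pairs])
    it = np.array([p[1] for p in pairs])
    chrom = np.array([keys0[i][0] for i in i0])
    pos = np.array([keys0[i][1] for i in i0])
    ids = np.array([f"{keys0[i][0]}:{keys0[i][1]}_{keys0[i][2]}>{keys0[i][3]}" for i in i0])
    panel = LocusPanel(chrom=chrom, pos=pos, x0=x0[i0], xt=xt[it], ids=ids)
    block0 = block0[:, i0] if block0 is not None else None
    order = panel.argsort()
    panel = panel.subset(order)
    if block0 is not None:
        block0 = block0[:, order]
    log = {"time0": c0, "time_t": ct, "loci_intersected": panel.n_loci}
    logger.info("read %d shared biallelic loci (%s)", panel.n_loci, log)
    return panel, block0, log


def _fit(panel, block, config: RunConfig, design: TemporalDesign, seed) -> TemporalNeResults:
    kwargs = {"haplotypes0": block} if config.phased else {"genotypes0": block}
    model = TemporalNe(panel, design, map_config=config.map_config, **kwargs)
    return model.fit(
        statistic=config.statistic,
        n_draws=config.n_draws,
        alpha=config.alpha,
        seed=seed,
        max_dense_k=config.max_dense_k,
        keep_draws=False,
    )


def run_pipeline(config: RunConfig, s0: int | None = None, st: int | None = None) -> dict:
    """Full estimation pipeline: read, filter, prune, fit per arm + combined.

    Diploid sample sizes default to the lengths of the sample-ID lists.
    Returns a dict with stage-by-stage locus counts, the per-locus report
    table, per-chromosome results and — when several chromosomes are
    present — the combined estimate.
    """
    design = TemporalDesign(
        s0=s0 or len(config.samples0), st=st or len(config.samples_t), t=config.t
    )
    panel, block0, log = read_panel(config)
    n_read = panel.n_loci

    panel_f, keep = maf_filter(panel, config.maf)
    removed_maf = int((~keep).sum())
    block_f = block0[:, keep] if block0 is not None else None

    if config.window_bp:
        ss = np.random.SeedSequence(config.seed)
        prune_seed, *fit_seeds = ss.spawn(2 + len(np.unique(panel_f.chrom.astype(str))))
        panel_p, keep_p = window_prune(
            panel_f, config.window_bp, np.random.default_rng(prune_seed)
        )
        block_p = block_f[:, keep_p] if block_f is not None else None
    else:
        ss = np.random.SeedSequence(config.seed)
        fit_seeds = list(ss.spawn(1 + len(np.unique(panel_f.chrom.astype(str)))))
        panel_p, block_p = panel_f, block_f
    logger.info(
        "loci: %d read, %d removed by MAF, %d after pruning",
        n_read, removed_maf, panel_p.n_loci,
    )

    chroms = list(dict.fromkeys(panel_p.chrom.astype(str)))
    per_chrom: dict[str, TemporalNeResults] = {}
    for ch, seed_i in zip(chroms, fit_seeds):
        mask = panel_p.chrom.astype(str) == ch
        sub_block = block_p[:, mask] if block_p is not None else None
        rng_seed = int(seed_i.generate_state(1)[0] % (2**31))
        per_chrom[ch] = _fit(panel_p.subset(mask), sub_block, config, design, rng_seed)

    combined = None
    if len(chroms) > 1:
        rng_seed = int(fit_seeds[len(chroms)].generate_state(1)[0] % (2**31))
        combined = _fit(panel_p, block_p, config, design, rng_seed)

    report = panel_p.to_frame()
    report["delta"] = standardized_delta(panel_p.x0, panel_p.xt)
    return {
        "design": {"S0": design.s0, "St": design.st, "t": design.t},
        "counts": {
            "loci_read": n_read,
            "maf_removed": removed_maf,
            "prune_survivors": panel_p.n_loci,
            **log,
        },
        "per_chrom": {ch: r.to_dict() for ch, r in per_chrom.items()},
        "combined": combined.to_dict() if combined is not None else None,
        "results": per_chrom,
        "combined_results": combined,
        "report": report,
    }


def write_two_sample_vcf(
    path: str,
    chrom,
    positions: np.ndarray,
    sample0: np.ndarray,
    sample_t: np.ndarray,
    phased: bool = True,
    prefix0: str = "T0",
    prefix_t: str = "T1",
) -> None:
    """Write two temporal haplotype samples as one plain-text VCF.

    ``sample0``/``sample_t`` are (2*S, K) haplotype matrices; consecutive row
    pairs form diploid individuals named ``<prefix>_<i>``. Phased genotypes
    use '|', unphased '/'. REF/ALT are fixed placeholders (A/T): the panel
    semantics only need biallelic 0/1 coding.
    """
    for arr in (sample0, sample_t):
        if arr.shape[0] % 2:
            raise ValueError("haplotype matrices need an even number of rows")
    n0 = sample0.shape[0] // 2
    nt = sample_t.shape[0] // 2
    names = [f"{prefix0}_{i}" for i in range(n0)] + [f"{prefix_t}_{i}" for i in range(nt)]
    sep = "|" if phased else "/"
    chrom_arr = np.broadcast_to(np.asarray(chrom, dtype=object), positions.shape) \
        if np.ndim(chrom) else np.full(len(positions), str(chrom), dtype=object)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ch in dict.fromkeys(chrom_arr):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(names) + "\n")
        for k in range(len(positions)):
            gts = []
            for mat, n in ((sample0, n0), (sample_t, nt)):
                col = mat[:, k]
                for i in range(n):
                    a, b = int(col[2 * i]), int(col[2 * i + 1])
                    if not phased and a > b:
                        a, b = b, a
                    gts.append(f"{a}{sep}{b}")
            fh.write(
                f"{chrom_arr[k]}\t{int(positions[k])}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
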