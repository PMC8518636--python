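"""Temporal F statistics from two panels of observed allele frequencies.

Implements the arithmetic-mean statistic F_a (mean of squared standardized
changes), its ratio-of-sums counterpart F_b (heterozygosity-weighted mean),
and the two panel filters used before estimation: a minor-allele-frequency
cutoff applied at both time points and random one-SNP-per-window pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LocusPanel",
    "FEstimate",
    "standardized_delta",
    "f_a",
    "f_b",
    "maf_filter",
    "window_prune",
]


@dataclass
class LocusPanel:
    """Per-locus observed allele frequencies at the two time points.

    ``x0`` and ``xt`` are the observed frequencies of the tracked allele
    (the VCF ALT allele, by convention) at generations 0 and t. Which allele
    is tracked is arbitrary: both F statistics are invariant under relabelling
    ``x -> 1 - x`` at any locus.
    """

    chrom: np.ndarray
    pos: np.ndarray
    x0: np.ndarray
    xt: np.ndarray
    ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.x0 = np.asarray(self.x0, dtype=float)
        self.xt = np.asarray(self.xt, dtype=float)
        if self.ids is not None:
            self.ids = np.asarray(self.ids)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.x0) == len(self.xt) == n):
            raise ValueError("panel arrays must have equal length")
        if n < 1:
            raise ValueError("panel must contain at least one locus")
        for name, x in (("x0", self.x0), ("xt", self.xt)):
            if np.any((x < 0) | (x > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def subset(self, mask_or_index) -> "LocusPanel":
        """New panel restricted to the given boolean mask or index array."""
        idx = np.asarray(mask_or_index)
        return LocusPanel(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            x0=self.x0[idx],
            xt=self.xt[idx],
            ids=None if self.ids is None else self.ids[idx],
        )

    def argsort(self) -> np.ndarray:
        """Stable ordering by (chrom, pos)."""
        return np.lexsort((self.pos, self.chrom.astype(str)))

    def sorted(self) -> "LocusPanel":
        return self.subset(self.argsort())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "x0": self.x0, "xt": self.xt}
        )
        if self.ids is not None:
            df.insert(0, "id", self.ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LocusPanel":
        return cls(
            chrom=df["chrom"].to_numpy(),
            pos=df["pos"].to_numpy(),
            x0=df["x0"].to_numpy(),
            xt=df["xt"].to_numpy(),
            ids=df["id"].to_numpy() if "id" in df.columns else None,
        )


@dataclass(frozen=True)
class FEstimate:
    """A temporal F statistic: value, variant ('a' or 'b'), number of loci
    used, and — for variant 'b' — the per-locus heterozygosity weights."""

    value: float
    variant: str
    k: int
    weights: np.ndarray | None = None


def standardized_delta(x0, xt):
    """Standardized change in observed frequency,
    ``delta = (xt - x0) / sqrt(x0 (1 - x0))``.

    Requires ``0 < x0 < 1`` (guaranteed downstream of the MAF filter); a
    fixed initial frequency has an undefined standardization.
    """
    x0 = np.asarray(x0, dtype=float)
    xt = np.asarray(xt, dtype=float)
    if np.any((x0 <= 0) | (x0 >= 1)):
        raise ValueError("x0 must lie strictly in (0, 1); apply a MAF filter first")
    out = (xt - x0) / np.sqrt(x0 * (1.0 - x0))
    return float(out) if np.ndim(out) == 0 else out


def f_a(panel: LocusPanel) -> FEstimate:
    """Arithmetic-mean temporal F: ``F_a = mean_i delta_i^2``."""
    delta = standardized_delta(panel.x0, panel.xt)
    return FEstimate(value=float(np.mean(delta**2)), variant="a", k=panel.n_loci)


def f_b(panel: LocusPanel) -> FEstimate:
    """Ratio-of-sums temporal F:
    ``F_b = sum_i (x_it - x_i0)^2 / sum_i x_i0 (1 - x_i0)``.

    Equivalently the weighted mean of ``delta_i^2`` with weights proportional
    to initial heterozygosity ``x_i0 (1 - x_i0)``; the weights (summing to 1)
    are returned alongside the value for the weighted eigenvalue path.
    """
    x0, xt = panel.x0, panel.xt
    if np.any((x0 <= 0) | (x0 >= 1)):
        raise ValueError("x0 must lie strictly in (0, 1); apply a MAF filter first")
    het = x0 * (1.0 - x0)
    weights = het / het.sum()
    value = float(np.sum((xt - x0) ** 2) / het.sum())
    return FEstimate(value=value, variant="b", k=panel.n_loci, weights=weights)


def maf_filter(panel: LocusPanel, threshold: float) -> tuple[LocusPanel, np.ndarray]:
    """Drop loci whose minor allele frequency is below ``threshold`` at
    either time point.

    Returns the filtered panel (original order preserved) and the boolean
    keep-mask over the input loci, so that companion genotype/haplotype
    matrices can be subset consistently.
    """
    if not 0.0 <= threshold < 0.5:
        raise ValueError("threshold must be in [0, 0.5)")
    maf0 = np.minimum(panel.x0, 1.0 - panel.x0)
    maft = np.minimum(panel.xt, 1.0 - panel.xt)
    keep = (maf0 >= threshold) & (maft >= threshold)
    if threshold == 0.0:
        # threshold 0 still demands a usable standardization denominator
        keep = (panel.x0 > 0) & (panel.x0 < 1)
    if not np.any(keep):
        raise ValueError("no loci pass the MAF filter")
    return panel.subset(keep), keep


def window_prune(
    panel: LocusPanel, window_bp: int, rng: np.random.Generator | int | None
) -> tuple[LocusPanel, np.ndarray]:
    """Keep exactly one uniformly chosen locus per non-overlapping
    ``window_bp`` window on each chromosome.

    Windows are ``[1, w], [w+1, 2w], ...`` in 1-based coordinates. Reduces
    tight linkage before estimation, as in standard LD pruning. Deterministic
    given the generator/seed. Returns (pruned panel, keep-mask).
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    window = (panel.pos - 1) // window_bp
    keep = np.zeros(panel.n_loci, dtype=bool)
    df = pd.DataFrame({"chrom": panel.chrom.astype(str), "window": window})
    for _, idx in df.groupby(["chrom", "window"], sort=False).groups.items():
        idx = np.asarray(idx)
        keep[rng.choice(idx)] = True
    return panel.subset(keep), keep
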