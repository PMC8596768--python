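"""Per-locus summary statistics from haplotype matrices or pooled-read emulations.

Statistics follow common window-based usage: the number of segregating sites
``S``, private ``S``, nucleotide diversity ``pi`` (mean pairwise differences
per locus), Watterson's ``theta_W`` (per locus), Tajima's ``D``, Hudson's
``F_ST`` and absolute divergence ``D_XY`` (per site), plus a binned unfolded
site-frequency spectrum. ``pi``, ``theta_W`` and ``S`` are reported per locus
(window totals); ``D_XY`` per site. Missing values are ``NaN`` sentinels and
are never silently turned into 0.

The pooled path emulates pool sequencing: per-site read depths drawn from a
negative binomial (or fixed) coverage model and derived-read counts binomial
in the pool allele frequency; statistics are then frequency plug-in
(Nei-style) estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coalescent import LocusData, _as_rng

MISSING = float("nan")


def _derived_counts(locus: LocusData, rows: np.ndarray) -> np.ndarray:
    if locus.n_sites == 0:
        return np.zeros(0, dtype=np.int64)
    return locus.haplotypes[rows].sum(axis=0, dtype=np.int64)


def harmonic(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1..n} 1/i**power (Watterson / Tajima constants)."""
    i = np.arange(1, n + 1, dtype=float)
    return float(np.sum(1.0 / i**power))


def pairwise_pi(counts: np.ndarray, n: int) -> float:
    """Mean pairwise difference count per locus from derived-allele counts."""
    if n < 2:
        return MISSING
    d = counts.astype(float)
    return float(np.sum(2.0 * d * (n - d)) / (n * (n - 1)))


def tajimas_d(s: int, pi: float, n: int) -> float:
    """Tajima's D with the standard variance constants; NaN when S == 0."""
    if n < 2 or s == 0:
        return MISSING
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:  # degenerate at n = 2
        return MISSING
    return float((pi - s / a1) / np.sqrt(var))


def diversity_stats(locus: LocusData, pop) -> tuple:
    """(S, private_S, pi, theta_W, Tajima's D) within one deme.

    ``private_S``: segregating within ``pop`` and monomorphic in every other
    deme. ``pi`` and ``theta_W`` are per-locus totals; with fewer than two
    haplotypes they are NaN.
    """
    rows = locus.rows(pop)
    n = len(rows)
    counts = _derived_counts(locus, rows)
    seg = (counts > 0) & (counts < n)
    s = int(seg.sum())
    other = np.setdiff1d(np.arange(locus.n_samples), rows)
    if len(other) and locus.n_sites:
        oc = locus.haplotypes[other].sum(axis=0, dtype=np.int64)
        mono_other = (oc == 0) | (oc == len(other))
    else:
        mono_other = np.ones(locus.n_sites, dtype=bool)
    private_s = int((seg & mono_other).sum())
    if n < 2:
        return s, private_s, MISSING, MISSING, MISSING
    pi = pairwise_pi(counts, n)
    theta_w = s / harmonic(n - 1)
    return s, private_s, pi, theta_w, tajimas_d(s, pi, n)


def divergence_stats(locus: LocusData, pop_a, pop_b) -> tuple:
    """(F_ST, D_XY) between two demes.

    ``D_XY`` is the mean pairwise difference count between the demes divided
    by the locus length (per site). ``F_ST`` is Hudson's estimator
    ``1 - mean(pi_A, pi_B) / pi_between`` on per-locus quantities, clamped to
    [-1, 1]; NaN if there is no between-deme diversity.
    """
    ra, rb = locus.rows(pop_a), locus.rows(pop_b)
    na, nb = len(ra), len(rb)
    if na < 1 or nb < 1:
        return MISSING, MISSING
    da = _derived_counts(locus, ra).astype(float)
    db = _derived_counts(locus, rb).astype(float)
    # mean pairwise differences between pops: P(different) per site summed
    pi_between = float(np.sum(da * (nb - db) + db * (na - da)) / (na * nb))
    dxy = pi_between / locus.locus_length
    if na < 2 or nb < 2:
        return MISSING, dxy
    if pi_between == 0.0:
        return MISSING, dxy
    pi_a = pairwise_pi(da, na)
    pi_b = pairwise_pi(db, nb)
    fst = 1.0 - 0.5 * (pi_a + pi_b) / pi_between
    return float(np.clip(fst, -1.0, 1.0)), dxy


def sfs_stats(locus: LocusData, pop, bins: int) -> np.ndarray:
    """Binned unfolded SFS proportions (k equal frequency bins, sum 1 or all 0)."""
    rows = locus.rows(pop)
    n = len(rows)
    if n == 0:
        raise ValueError(f"population {pop!r} has no samples")
    counts = _derived_counts(locus, rows)
    seg = (counts > 0) & (counts < n)
    if not seg.any():
        return np.zeros(bins)
    freqs = counts[seg] / n
    hist, _ = np.histogram(freqs, bins=bins, range=(0.0, 1.0))
    return hist / hist.sum()


@dataclass
class PooledLocus:
    """Pool-seq emulation of one locus: per-site, per-pool depths and derived reads."""

    depth: np.ndarray  #: (n_sites, n_pools) int
    derived: np.ndarray  #: (n_sites, n_pools) int
    positions: np.ndarray
    locus_length: int
    pools: list  #: pool (deme) ids, column order
    pool_sizes: list  #: haploid genomes per pool (2x diploids pooled)

    def frequencies(self) -> np.ndarray:
        """Derived read frequencies; NaN where depth is 0 (missing)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.depth > 0, self.derived / np.maximum(self.depth, 1), np.nan)


@dataclass
class CoverageModel:
    """Read-depth model: negative binomial with ``mean`` and ``dispersion``
    (variance = mean + mean^2 / dispersion), or exactly ``mean`` if
    ``fixed=True``."""

    mean: float
    dispersion: float = 5.0
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.mean < 0 or (not self.fixed and self.dispersion <= 0):
            raise ValueError("invalid coverage parameters")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.fixed:
            return np.full(size, int(round(self.mean)), dtype=np.int64)
        p = self.dispersion / (self.dispersion + self.mean)
        return rng.negative_binomial(self.dispersion, p, size=size)


def emulate_pool_reads(
    locus: LocusData,
    pools: Mapping[str, int],
    coverage_model: CoverageModel,
    rng,
) -> PooledLocus:
    """Draw pooled reads from ``pools`` (deme -> diploid individuals pooled).

    Pools 2x the requested diploid count in haploid genomes from each deme's
    haplotypes; per site, depth ~ coverage model and derived reads ~
    Binomial(depth, pool derived frequency). Zero-depth sites are missing.
    """
    rng = _as_rng(rng)
    ids = list(pools)
    s = locus.n_sites
    depth = np.zeros((s, len(ids)), dtype=np.int64)
    derived = np.zeros((s, len(ids)), dtype=np.int64)
    for k, pop in enumerate(ids):
        rows = locus.rows(pop)
        n_hap = 2 * int(pools[pop])
        if n_hap > len(rows):
            raise ValueError(
                f"pool {pop!r}: {pools[pop]} diploids need {n_hap} haplotypes, "
                f"only {len(rows)} available"
            )
        chosen = rng.choice(rows, size=n_hap, replace=False)
        freq = locus.haplotypes[chosen].mean(axis=0) if s else np.zeros(0)
        depth[:, k] = coverage_model.sample(rng, s)
        derived[:, k] = rng.binomial(depth[:, k], freq)
    sizes = [2 * int(pools[p]) for p in ids]
    return PooledLocus(depth, derived, locus.positions.copy(), locus.locus_length, ids, sizes)


def _pool_diversity(pool: PooledLocus, k: int, min_private_reads: int) -> tuple:
    d = pool.depth[:, k]
    ok = d > 0
    if not ok.any():
        return 0, 0, MISSING, MISSING, MISSING
    p = pool.derived[ok, k] / d[ok]
    dd = d[ok].astype(float)
    seg = (pool.derived[ok, k] > 0) & (pool.derived[ok, k] < d[ok])
    s = int(seg.sum())
    # plug-in pi with depth (reads drawn with replacement) and pool-size
    # (pairs within the pool) small-sample corrections
    n_pool = pool.pool_sizes[k]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(dd > 1, dd / (dd - 1.0), np.nan)
    pair_corr = n_pool / (n_pool - 1.0) if n_pool > 1 else np.nan
    pi = float(np.nansum(2.0 * p * (1.0 - p) * corr) * pair_corr)
    theta_w = s / harmonic(max(n_pool, 2) - 1)
    tajd = tajimas_d(s, pi, max(n_pool, 2))
    # private sites use an anti-noise minimum read count
    present = pool.derived[:, k] >= min_private_reads
    other = np.delete(np.arange(len(pool.pools)), k)
    absent_other = np.all(pool.derived[:, other] < min_private_reads, axis=1)
    priv = int(np.sum(present & absent_other & (pool.depth[:, k] > 0)))
    return s, priv, pi, theta_w, tajd


def _pool_divergence(pool: PooledLocus, ka: int, kb: int) -> tuple:
    ok = (pool.depth[:, ka] > 0) & (pool.depth[:, kb] > 0)
    if not ok.any():
        return MISSING, MISSING
    pa = pool.derived[ok, ka] / pool.depth[ok, ka]
    pb = pool.derived[ok, kb] / pool.depth[ok, kb]
    pi_between = float(np.sum(pa * (1 - pb) + pb * (1 - pa)))
    # effective length: statistics are computed over covered sites only
    l_eff = pool.locus_length - (pool.depth.shape[0] - int(ok.sum()))
    dxy = pi_between / max(l_eff, 1)
    if pi_between == 0.0:
        return MISSING, dxy
    da, db = pool.depth[ok, ka].astype(float), pool.depth[ok, kb].astype(float)
    na, nb = pool.pool_sizes[ka], pool.pool_sizes[kb]
    ca = na / (na - 1.0) if na > 1 else np.nan
    cb = nb / (nb - 1.0) if nb > 1 else np.nan
    pi_a = float(np.nansum(2 * pa * (1 - pa) * np.where(da > 1, da / (da - 1), np.nan)) * ca)
    pi_b = float(np.nansum(2 * pb * (1 - pb) * np.where(db > 1, db / (db - 1), np.nan)) * cb)
    fst = 1.0 - 0.5 * (pi_a + pi_b) / pi_between
    return float(np.clip(fst, -1.0, 1.0)), dxy


def stat_names(pops: Sequence, sfs_bins: int = 0) -> list[str]:
    """The fixed, documented statistic ordering used everywhere."""
    names: list[str] = []
    for p in pops:
        names += [f"S_{p}", f"privS_{p}", f"pi_{p}", f"thetaW_{p}", f"tajD_{p}"]
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            names += [f"fst_{pops[a]}_{pops[b]}", f"dxy_{pops[a]}_{pops[b]}"]
    names += ["S_total", "pi_total"]
    for p in pops:
        names += [f"sfs{k}_{p}" for k in range(sfs_bins)]
    return names


def infer_sfs_bins(names) -> int:
    """Recover the SFS bin count from a list of statistic names."""
    ks = [int(n[3 : n.index("_")]) for n in names if n.startswith("sfs")]
    return max(ks) + 1 if ks else 0


def stats_vector(
    data: LocusData | PooledLocus,
    pops: Sequence,
    *,
    sfs_bins: int = 0,
    min_private_reads: int = 2,
) -> pd.Series:
    """Aggregate the full named statistics vector for one locus.

    The ordering is fixed (see :func:`stat_names`) and identical for observed
    and simulated data; missing statistics stay NaN.
    """
    pops = list(pops)
    values: dict[str, float] = {}
    if isinstance(data, PooledLocus):
        if set(pops) - set(data.pools):
            raise ValueError(f"pools {set(pops) - set(data.pools)} absent from data")
        idx = {p: data.pools.index(p) for p in pops}
        for p in pops:
            s, priv, pi, tw, td = _pool_diversity(data, idx[p], min_private_reads)
            values.update(
                {f"S_{p}": s, f"privS_{p}": priv, f"pi_{p}": pi, f"thetaW_{p}": tw, f"tajD_{p}": td}
            )
        for a in range(len(pops)):
            for b in range(a + 1, len(pops)):
                fst, dxy = _pool_divergence(data, idx[pops[a]], idx[pops[b]])
                values[f"fst_{pops[a]}_{pops[b]}"] = fst
                values[f"dxy_{pops[a]}_{pops[b]}"] = dxy
        freqs = data.frequencies()
        covered = ~np.all(np.isnan(freqs), axis=1)
        poly = covered & np.any((data.derived > 0) & (data.derived < data.depth), axis=1)
        values["S_total"] = int(poly.sum())
        with np.errstate(invalid="ignore"):
            pbar = np.nanmean(freqs, axis=1)
        values["pi_total"] = float(np.nansum(2 * pbar[covered] * (1 - pbar[covered])))
        if sfs_bins:
            for p in pops:
                k = idx[p]
                ok = data.depth[:, k] > 0
                pf = data.derived[ok, k] / data.depth[ok, k]
                pf = pf[(pf > 0) & (pf < 1)]
                if len(pf):
                    hist, _ = np.histogram(pf, bins=sfs_bins, range=(0, 1))
                    hist = hist / hist.sum()
                else:
                    hist = np.zeros(sfs_bins)
                for kk in range(sfs_bins):
                    values[f"sfs{kk}_{p}"] = float(hist[kk])
    else:
        for p in pops:
            s, priv, pi, tw, td = diversity_stats(data, p)
            values.update(
                {f"S_{p}": s, f"privS_{p}": priv, f"pi_{p}": pi, f"thetaW_{p}": tw, f"tajD_{p}": td}
            )
        for a in range(len(pops)):
            for b in range(a + 1, len(pops)):
                fst, dxy = divergence_stats(data, pops[a], pops[b])
                values[f"fst_{pops[a]}_{pops[b]}"] = fst
                values[f"dxy_{pops[a]}_{pops[b]}"] = dxy
        n = data.n_samples
        counts = data.haplotypes.sum(axis=0, dtype=np.int64) if data.n_sites else np.zeros(0)
        seg = (counts > 0) & (counts < n)
        values["S_total"] = int(seg.sum())
        values["pi_total"] = pairwise_pi(counts, n) if n >= 2 else MISSING
        if sfs_bins:
            for p in pops:
                hist = sfs_stats(data, p, sfs_bins)
                for kk in range(sfs_bins):
                    values[f"sfs{kk}_{p}"] = float(hist[kk])
    return pd.Series(values, index=stat_names(pops, sfs_bins), dtype=float)
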