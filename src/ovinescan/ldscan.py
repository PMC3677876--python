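"""Within-breed linkage disequilibrium from unphased genotypes.

For two biallelic loci the four haplotype frequencies are estimated by
expectation-maximisation over the phase ambiguity of double
heterozygotes (allele frequencies are fixed by the genotypes, leaving a
single free parameter).  Then

    D = f(AB) - p1 * p2,    r^2 = D^2 / (p1 q1 p2 q2).

EM iterates to |delta log-lik| < 1e-8 (at most 1000 iterations) from
three deterministic starts -- linkage equilibrium plus one near each
end of the feasible D range -- because for genotype tables that are
exactly symmetric in the unambiguous haplotype counts the equilibrium
point is a stationary saddle of the likelihood.  The highest-likelihood
solution wins; ties (mirror-image optima with |D| equal) resolve toward
D >= 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plinkio import MISSING, GenotypeDataset

logger = logging.getLogger("ovinescan")

EM_TOL = 1e-8
EM_MAX_ITER = 1000


def genotype_pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 table of joint genotype counts (rows locus 1, cols locus 2)."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (g1[ok], g2[ok]), 1)
    return table


def em_haplotype_freqs(table: np.ndarray) -> np.ndarray:
    """Haplotype frequencies (f11, f10, f01, f00) from a 3x3 count table.

    Index 1 denotes the reference allele at each locus; genotype code k
    carries k reference copies.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        raise ValueError("no jointly called samples")
    # allele counts are fixed by the genotypes
    n1 = 2 * table[2].sum() + table[1].sum()
    n2 = 2 * table[:, 2].sum() + table[:, 1].sum()
    p1, p2 = n1 / (2 * n), n2 / (2 * n)
    ndh = table[1, 1]  # double heterozygotes: phase-ambiguous

    # unambiguous haplotype contributions
    base11 = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    base10 = 2 * table[2, 0] + table[2, 1] + table[1, 0]
    base01 = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    base00 = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    total = 2 * n

    def loglik(f: np.ndarray) -> float:
        cis = f[0] * f[3] + f[1] * f[2]
        ll = 0.0
        if base11:
            ll += base11 * np.log(f[0])
        if base10:
            ll += base10 * np.log(f[1])
        if base01:
            ll += base01 * np.log(f[2])
        if base00:
            ll += base00 * np.log(f[3])
        if ndh:
            ll += ndh * np.log(max(2 * cis, 1e-300))
        return ll

    def em_from(f: np.ndarray) -> tuple[np.ndarray, float]:
        prev = loglik(f)
        for _ in range(EM_MAX_ITER):
            cis = f[0] * f[3] + f[1] * f[2]
            w = f[0] * f[3] / cis if cis > 0 else 0.5  # P(phase is 11/00)
            new = np.array([
                base11 + ndh * w,
                base10 + ndh * (1 - w),
                base01 + ndh * (1 - w),
                base00 + ndh * w,
            ]) / total
            new = np.clip(new, 1e-15, None)
            new /= new.sum()
            cur = loglik(new)
            f = new
            if abs(cur - prev) < EM_TOL:
                break
            prev = cur
        return f, loglik(f)

    # feasible f11 range given the fixed allele frequencies
    f11_lo = max(0.0, p1 + p2 - 1.0)
    f11_hi = min(p1, p2)

    def freqs_at(f11: float) -> np.ndarray:
        f = np.array([f11, p1 - f11, p2 - f11, 1.0 - p1 - p2 + f11])
        f = np.clip(f, 1e-12, None)
        return f / f.sum()

    starts = [
        freqs_at(p1 * p2),                                   # equilibrium
        freqs_at(f11_lo + 0.95 * (f11_hi - f11_lo)),          # strong D > 0
        freqs_at(f11_lo + 0.05 * (f11_hi - f11_lo)),          # strong D < 0
    ]
    best, best_ll = None, -np.inf
    for start in starts:
        f, ll = em_from(start)
        better = ll > best_ll + EM_TOL
        tied = abs(ll - best_ll) <= EM_TOL
        if better or (tied and f[0] - p1 * p2 > best[0] - p1 * p2):
            best, best_ll = f, ll
    return best


def pair_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """EM-based r^2 between two unphased genotype vectors.

    Returns ``nan`` when either locus is monomorphic among the jointly
    called samples.
    """
    table = genotype_pair_counts(np.asarray(g1), np.asarray(g2))
    n = table.sum()
    if n < 2:
        return float("nan")
    p1 = (2 * table[2].sum() + table[1].sum()) / (2 * n)
    p2 = (2 * table[:, 2].sum() + table[:, 1].sum()) / (2 * n)
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return float("nan")
    f = em_haplotype_freqs(table)
    d = f[0] - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    return float(d * d / denom)


@dataclass
class LdDecayCurve:
    """Mean r^2 by physical-distance bin for one breed."""

    breed: str
    table: pd.DataFrame  # columns: bin_start, bin_end, mean_r2, n_pairs

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def decay_curve(
    dataset: GenotypeDataset,
    breed: str | None = None,
    max_distance: int = 1_000_000,
    bin_width: int = 10_000,
) -> LdDecayCurve:
    """Distance-binned mean r^2 over all within-chromosome marker pairs.

    Only mapped markers enter; pairs farther apart than ``max_distance``
    are skipped.  ``dataset`` should already be restricted to one breed,
    or pass ``breed`` to subset.
    """
    if breed is not None:
        dataset = dataset.take_samples(
            (dataset.samples["breed"] == breed).to_numpy()
        )
    mapped = ~dataset.is_unmapped()
    ds = dataset.take_markers(mapped)
    chroms = ds.markers["chrom"].to_numpy()
    pos = ds.markers["pos"].to_numpy()
    g = ds.genotypes

    n_bins = int(np.ceil(max_distance / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        p = pos[idx]
        for ai, i in enumerate(idx):
            for j in idx[ai + 1:]:
                d = abs(int(pos[j]) - int(pos[i]))
                if d > max_distance:
                    break
                r2 = pair_r2(g[:, i], g[:, j])
                if np.isnan(r2):
                    continue
                b = min(int(d // bin_width), n_bins - 1) if d > 0 else 0
                sums[b] += r2
                counts[b] += 1
    if counts.sum() == 0:
        logger.warning("decay_curve: no eligible marker pairs")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_width,
            "bin_end": (np.arange(n_bins) + 1) * bin_width,
            "mean_r2": mean,
            "n_pairs": counts,
        }
    )
    table = table[table["n_pairs"] > 0].reset_index(drop=True)
    return LdDecayCurve(breed=breed or "all", table=table)
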