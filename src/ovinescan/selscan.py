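"""Per-SNP differentiation statistics and along-chromosome smoothing.

The SNP-specific F_ST follows the drift-model moment form: with J
population frequencies p_j and their unweighted mean pi,

    F_ST = (1/J) * sum_j (p_j - pi)^2 / (pi * (1 - pi))

i.e. the mean squared frequency deviation scaled by pooled
heterozygosity.  It is non-negative, reaches 1.00 at a two-population
fixed difference, and uses plug-in sample frequencies with no
finite-sample correction.  Frequencies on the X chromosome come from
male hemizygous counts (one allele per male).

A per-marker two-sided Fisher exact test on the 2x2 allele-count table
(two breed sets) with Bonferroni correction is reported side by side
with the F_ST ranking.  Smoothing is a Nadaraya-Watson Gaussian kernel
with a local bandwidth equal to the distance to the k-th nearest
marker; it never crosses chromosome boundaries and is for reporting
only, never for region calling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .plinkio import GenotypeDataset, _allele_counts

logger = logging.getLogger("ovinescan")


def snp_fst(freqs: np.ndarray) -> np.ndarray | float:
    """Moment-form SNP-specific F_ST from per-population frequencies.

    ``freqs`` has shape (J,) for one marker or (J, m) for a track.
    Markers whose pooled mean frequency is 0 or 1 return ``nan`` (they
    should have been removed by QC).
    """
    p = np.asarray(freqs, dtype=float)
    scalar = p.ndim == 1
    if scalar:
        p = p[:, None]
    if p.shape[0] < 2:
        raise ValueError("need at least two populations")
    pi = p.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.mean((p - pi) ** 2, axis=0) / (pi * (1.0 - pi))
    fst = np.where((pi <= 0.0) | (pi >= 1.0), np.nan, fst)
    return float(fst[0]) if scalar else fst


def group_allele_stats(
    dataset: GenotypeDataset, groups: list[list[str]]
) -> tuple[np.ndarray, np.ndarray]:
    """(frequencies, allele totals) per group over all markers.

    Each group pools the samples of its breed labels.  Male X genotypes
    contribute a single allele; invalid male-het X calls are excluded
    (they are removed by QC anyway).
    """
    breeds = dataset.samples["breed"].to_numpy()
    known = set(breeds)
    freqs, totals = [], []
    for group in groups:
        unknown = set(group) - known
        if unknown:
            raise ValueError(f"unknown breed labels: {sorted(unknown)}")
        sub = dataset.take_samples(np.isin(breeds, group))
        ref, tot = _allele_counts(sub)
        with np.errstate(invalid="ignore"):
            freqs.append(np.where(tot > 0, ref / np.maximum(tot, 1), np.nan))
        totals.append(tot)
    return np.array(freqs), np.array(totals)


def fisher_allele_test(
    counts_a: np.ndarray, counts_b: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher exact test per marker on allele counts.

    ``counts_a``/``counts_b`` are (m, 2) arrays of (ref, alt) allele
    counts for the two breed sets.  Returns (p-values, Bonferroni
    flags) with the correction m = number of markers; a zero-margin
    table yields p = 1.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=np.int64))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=np.int64))
    m = counts_a.shape[0]
    pvals = np.ones(m)
    for i in range(m):
        table = np.array([counts_a[i], counts_b[i]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            pvals[i] = 1.0
        else:
            pvals[i] = sps.fisher_exact(table, alternative="two-sided")[1]
    return pvals, pvals < (alpha / m)


def fst_track(
    dataset: GenotypeDataset,
    groups: list[list[str]],
    smoother_k: int = 20,
    with_fisher: bool = True,
) -> pd.DataFrame:
    """Per-marker F_ST track over the dataset's mapped markers.

    Columns: name, chrom, pos, fst, smoothed, rank (1 = highest raw
    F_ST) and, for two groups, fisher_p / fisher_significant.  Markers
    with undefined F_ST (pooled monomorphic within the groups) are
    dropped with a warning.
    """
    mapped = ~dataset.is_unmapped()
    ds = dataset.take_markers(mapped)
    freqs, totals = group_allele_stats(ds, groups)
    fst = snp_fst(freqs)
    keep = ~np.isnan(fst)
    if not keep.all():
        logger.warning("fst_track: dropping %d markers with undefined F_ST",
                       int((~keep).sum()))
    track = pd.DataFrame(
        {
            "name": ds.markers["name"].to_numpy()[keep],
            "chrom": ds.markers["chrom"].to_numpy()[keep],
            "pos": ds.markers["pos"].to_numpy()[keep],
            "fst": fst[keep],
        }
    )
    if with_fisher and len(groups) == 2:
        ref_a = np.round(freqs[0] * totals[0]).astype(np.int64)
        ref_b = np.round(freqs[1] * totals[1]).astype(np.int64)
        counts_a = np.stack([ref_a, totals[0].astype(np.int64) - ref_a], axis=1)[keep]
        counts_b = np.stack([ref_b, totals[1].astype(np.int64) - ref_b], axis=1)[keep]
        pvals, flags = fisher_allele_test(counts_a, counts_b)
        track["fisher_p"] = pvals
        track["fisher_significant"] = flags
    track = track.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    track["rank"] = track["fst"].rank(ascending=False, method="min").astype(int)
    track["smoothed"] = smooth_track(
        track["chrom"].to_numpy(), track["pos"].to_numpy(),
        track["fst"].to_numpy(), k=smoother_k,
    )
    return track


def smooth_track(
    chroms: np.ndarray,
    positions: np.ndarray,
    values: np.ndarray,
    k: int = 20,
    truncate: float = 5.0,
) -> np.ndarray:
    """Variable-bandwidth Gaussian Nadaraya-Watson smoothing per chromosome.

    The bandwidth at marker i is the distance to its k-th nearest
    marker on the same chromosome (the largest distance if fewer than k
    neighbours exist); kernels are truncated at ``truncate`` bandwidths.
    A chromosome with a single marker is returned unsmoothed.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for chrom in dict.fromkeys(chroms):
        sel = np.flatnonzero(chroms == chrom)
        order = sel[np.argsort(positions[sel], kind="stable")]
        pos = positions[order]
        val = values[order]
        m = pos.size
        if m == 1:
            out[order] = val
            continue
        smoothed = np.empty(m)
        for i in range(m):
            dists = np.abs(pos - pos[i])
            kk = min(k, m - 1)
            h = np.partition(dists, kk)[kk]
            if h <= 0:
                h = max(dists.max(), 1.0)
            lo = np.searchsorted(pos, pos[i] - truncate * h, side="left")
            hi = np.searchsorted(pos, pos[i] + truncate * h, side="right")
            w = np.exp(-0.5 * ((pos[lo:hi] - pos[i]) / h) ** 2)
            smoothed[i] = np.sum(w * val[lo:hi]) / np.sum(w)
        out[order] = smoothed
    return out
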