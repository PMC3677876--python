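"""Per-breed diversity statistics and Wright/Weir-Cockerham F-statistics.

Diversity at a biallelic marker with reference-allele frequency p
(q = 1 - p):

    gene diversity (expected heterozygosity)  D = 1 - p^2 - q^2
    polymorphism information content        PIC = D - 2 p^2 q^2
    observed heterozygosity                   H = het fraction of calls

F-statistics use the Weir-Cockerham (1984) variance components for
diploid data: per marker, ``a`` (among populations), ``b`` (among
individuals within populations) and ``c`` (within individuals), with

    F_ST = sum(a) / sum(a+b+c)      (theta, ratio of sums over markers)
    F_IT = sum(a+b) / sum(a+b+c)
    F_IS = sum(b) / sum(b+c)

These are moment estimators: theta may be slightly negative in
undifferentiated samples.  All F-statistics and diversity summaries are
computed on autosomal diploid genotypes; X markers are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .plinkio import MISSING, GenotypeDataset, split_by_breed

logger = logging.getLogger("ovinescan")

#: bin edges partitioning the minor-allele-frequency range [0, 0.5]
DEFAULT_MAF_BIN_EDGES = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


# ----------------------------------------------------------------------
# marker-level diversity
# ----------------------------------------------------------------------

def gene_diversity(p: np.ndarray | float) -> np.ndarray | float:
    p = np.asarray(p, dtype=float)
    return 2.0 * p * (1.0 - p)


def pic(p: np.ndarray | float) -> np.ndarray | float:
    """Polymorphism information content of a biallelic marker."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2


def marker_diversity(
    p: float, n_het: int, n_called: int
) -> tuple[float, float, float]:
    """(gene diversity, observed heterozygosity, PIC) for one marker."""
    if n_called < 1:
        raise ValueError("no non-missing calls")
    return float(gene_diversity(p)), n_het / n_called, float(pic(p))


def breed_diversity_report(dataset: GenotypeDataset) -> pd.DataFrame:
    """Mean gene diversity, observed heterozygosity and PIC per breed.

    Averages run over the dataset's autosomal markers (the post-QC set),
    weighting markers equally; markers monomorphic within a breed
    contribute zeros rather than being re-filtered per breed.
    """
    aut = dataset.is_autosomal()
    rows = []
    for breed, sub in split_by_breed(dataset).items():
        g = sub.genotypes[:, aut]
        called = g != MISSING
        n_called = called.sum(axis=0)
        ok = n_called > 0
        p = np.where(ok, np.where(called, g, 0).sum(axis=0) / (2 * np.maximum(n_called, 1)), np.nan)
        het = (g == 1).sum(axis=0) / np.maximum(n_called, 1)
        rows.append(
            (
                breed,
                float(np.nanmean(gene_diversity(p[ok]))),
                float(np.mean(het[ok])),
                float(np.nanmean(pic(p[ok]))),
                int(ok.sum()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["breed", "gene_diversity", "heterozygosity", "pic", "n_markers"],
    )


# ----------------------------------------------------------------------
# MAF spectra
# ----------------------------------------------------------------------

def maf_bin_counts(
    dataset: GenotypeDataset,
    bin_edges: tuple[float, ...] = DEFAULT_MAF_BIN_EDGES,
) -> pd.DataFrame:
    """Breed x MAF-bin contingency table of autosomal marker counts.

    Bins are left-open/right-closed intervals over the edges, which must
    partition (0, 0.5]; per-breed MAF of exactly 0 (markers monomorphic
    within the breed) falls in the first bin.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges[0] != 0.0 or edges[-1] != 0.5 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must increase from 0 to 0.5")
    aut = dataset.is_autosomal()
    table = {}
    for breed, sub in split_by_breed(dataset).items():
        g = sub.genotypes[:, aut]
        called = g != MISSING
        n_called = called.sum(axis=0)
        ok = n_called > 0
        p = np.where(called, g, 0).sum(axis=0) / (2 * np.maximum(n_called, 1))
        maf = np.minimum(p, 1.0 - p)[ok]
        idx = np.clip(np.searchsorted(edges, maf, side="left") - 1, 0, len(edges) - 2)
        table[breed] = np.bincount(idx, minlength=len(edges) - 1)
    labels = [f"({edges[i]:g},{edges[i+1]:g}]" for i in range(len(edges) - 1)]
    return pd.DataFrame(table, index=labels).T


def maf_spectrum_chisq(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson chi-squared test on a breed x MAF-bin marker-count table."""
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 breeds and 2 bins")
    arr = table.to_numpy(dtype=float)
    keep_rows = arr.sum(axis=1) > 0
    keep_cols = arr.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        logger.warning("maf_spectrum_chisq: dropping zero-sum rows/columns")
        arr = arr[keep_rows][:, keep_cols]
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


# ----------------------------------------------------------------------
# Weir-Cockerham variance components
# ----------------------------------------------------------------------

def _pop_summaries(
    dataset: GenotypeDataset, groups: list[list[str]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group (n, p, h) arrays over autosomal markers.

    ``groups`` is a list of breed-label lists; each group's samples are
    pooled.  Shapes are (n_groups, n_markers_autosomal).
    """
    aut = dataset.is_autosomal()
    breeds = dataset.samples["breed"].to_numpy()
    known = set(breeds)
    ns, ps, hs = [], [], []
    for group in groups:
        unknown = set(group) - known
        if unknown:
            raise ValueError(f"unknown breed labels: {sorted(unknown)}")
        rows = np.isin(breeds, group)
        g = dataset.genotypes[rows][:, aut]
        called = g != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(called, g, 0).sum(axis=0) / (2 * np.maximum(n, 1))
        h = (g == 1).sum(axis=0) / np.maximum(n, 1)
        ns.append(n)
        ps.append(p)
        hs.append(h)
    return np.array(ns, dtype=float), np.array(ps), np.array(hs)


def wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham per-marker variance components (a, b, c).

    Inputs are per-population arrays of shape (r, m): sample sizes
    (non-missing diploid calls), reference-allele frequencies and
    observed heterozygote fractions.  Markers where any population has
    no calls, or where the mean sample size is <= 1, yield zeros (they
    contribute nothing to the ratio-of-sums estimators).
    """
    n = np.asarray(n, dtype=float)
    r = n.shape[0]
    if r < 2:
        raise ValueError("need at least two populations")
    nbar = n.mean(axis=0)
    valid = (n >= 1).all(axis=0) & (nbar > 1)
    nbar_s = np.where(valid, nbar, 2.0)  # placeholder to avoid 0-division
    nc = (r * nbar_s - (n**2).sum(axis=0) / (r * nbar_s)) / (r - 1)
    nc = np.where(nc > 0, nc, 1.0)
    pbar = (n * p).sum(axis=0) / (r * nbar_s)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar_s)
    hbar = (n * h).sum(axis=0) / (r * nbar_s)

    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = nbar_s / nc * (s2 - (inner - hbar / 4) / (nbar_s - 1))
    b = nbar_s / (nbar_s - 1) * (inner - (2 * nbar_s - 1) / (4 * nbar_s) * hbar)
    c = hbar / 2
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    return a, b, c


@dataclass
class FStatistics:
    """Global Wright F-statistics from summed variance components."""

    f_st: float
    f_it: float
    f_is: float
    sum_a: float
    sum_b: float
    sum_c: float

    @property
    def among_breed_share(self) -> float:
        """Fraction of total allelic variance between populations (= F_ST)."""
        return self.f_st


def global_f_statistics(
    dataset: GenotypeDataset, groups: list[list[str]] | None = None
) -> FStatistics:
    """Multi-population Weir-Cockerham F_ST / F_IT / F_IS."""
    if groups is None:
        groups = [[b] for b in dataset.breeds]
    if len(groups) < 2:
        raise ValueError("need at least two populations")
    n, p, h = _pop_summaries(dataset, groups)
    a, b, c = wc_components(n, p, h)
    sa, sb, sc = float(a.sum()), float(b.sum()), float(c.sum())
    tot = sa + sb + sc
    if tot == 0:
        raise ValueError("all markers monomorphic: F-statistics undefined")
    return FStatistics(
        f_st=sa / tot,
        f_it=(sa + sb) / tot,
        f_is=sb / (sb + sc) if (sb + sc) != 0 else float("nan"),
        sum_a=sa,
        sum_b=sb,
        sum_c=sc,
    )


def wc_pairwise_fst(dataset: GenotypeDataset, breed_a: str, breed_b: str) -> float:
    """Multi-locus Weir-Cockerham theta between two breeds."""
    return global_f_statistics(dataset, [[breed_a], [breed_b]]).f_st


def pairwise_fst_matrix(
    dataset: GenotypeDataset,
    n_perm: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Symmetric matrix of pairwise theta, optionally with permutation p."""
    breeds = dataset.breeds
    k = len(breeds)
    mat = pd.DataFrame(np.zeros((k, k)), index=breeds, columns=breeds)
    pmat = pd.DataFrame(np.ones((k, k)), index=breeds, columns=breeds) if n_perm else None
    for i in range(k):
        for j in range(i + 1, k):
            theta = wc_pairwise_fst(dataset, breeds[i], breeds[j])
            mat.iloc[i, j] = mat.iloc[j, i] = theta
            if n_perm:
                pv = fst_permutation_test(dataset, breeds[i], breeds[j], n_perm, rng)
                pmat.iloc[i, j] = pmat.iloc[j, i] = pv
    return mat, pmat


def fst_permutation_test(
    dataset: GenotypeDataset,
    breed_a: str,
    breed_b: str,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """One-sided permutation p-value for pairwise theta.

    Individuals of the two breeds are randomly reassigned to the two
    labels (sizes preserved); p = (1 + #{theta_perm >= theta_obs}) /
    (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    if rng is None:
        rng = np.random.default_rng(0)
    breeds = dataset.samples["breed"].to_numpy()
    rows = np.flatnonzero(np.isin(breeds, [breed_a, breed_b]))
    sub = dataset.take_samples(rows)
    n_a = int((sub.samples["breed"] == breed_a).sum())
    aut = sub.is_autosomal()
    g = sub.genotypes[:, aut]

    def theta_for(labels_a: np.ndarray) -> float:
        ns, ps, hs = [], [], []
        for rows_g in (labels_a, ~labels_a):
            gg = g[rows_g]
            called = gg != MISSING
            nn = called.sum(axis=0)
            pp = np.where(called, gg, 0).sum(axis=0) / (2 * np.maximum(nn, 1))
            hh = (gg == 1).sum(axis=0) / np.maximum(nn, 1)
            ns.append(nn)
            ps.append(pp)
            hs.append(hh)
        a, b, c = wc_components(np.array(ns, float), np.array(ps), np.array(hs))
        tot = a.sum() + b.sum() + c.sum()
        return float(a.sum() / tot) if tot else 0.0

    obs_labels = (sub.samples["breed"] == breed_a).to_numpy()
    theta_obs = theta_for(obs_labels)
    count = 0
    idx = np.arange(sub.n_samples)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        lab = np.zeros(sub.n_samples, dtype=bool)
        lab[perm[:n_a]] = True
        if theta_for(lab) >= theta_obs:
            count += 1
    return (1 + count) / (n_perm + 1)
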