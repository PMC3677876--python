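"""Independent brute-force oracles used to validate the implementations.

Everything here is computed from first principles by a different route
than the package code: log-factorial probability formulas, exhaustive
grid searches and raw indicator-variable ANOVA sums of squares.
"""

import numpy as np
from scipy.special import gammaln


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test by direct probability evaluation
# ----------------------------------------------------------------------

def hwe_config_log_prob(n_aa: int, n_ab: int, n_bb: int) -> float:
    """log P(genotype configuration | allele counts) under random mating.

    P = n! * 2^n_ab / (n_aa! n_ab! n_bb!) / C(2n, n_a)
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    return (
        gammaln(n + 1) + n_ab * np.log(2.0)
        - gammaln(n_aa + 1) - gammaln(n_ab + 1) - gammaln(n_bb + 1)
        - (gammaln(2 * n + 1) - gammaln(n_a + 1) - gammaln(2 * n - n_a + 1))
    )


def hwe_exact_p_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact p by full enumeration of compatible het counts."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    logps = np.array([
        hwe_config_log_prob((n_a - h) // 2, h, (n_b - h) // 2) for h in hets
    ])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == n_ab)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ----------------------------------------------------------------------
# two-locus likelihood grid search
# ----------------------------------------------------------------------

def joint_genotype_probs(f11, f10, f01, f00):
    """3x3 joint genotype probabilities from haplotype frequencies."""
    haps = [(1, 1, f11), (1, 0, f10), (0, 1, f01), (0, 0, f00)]
    probs = np.zeros((3, 3))
    for a1, b1, fa in haps:
        for a2, b2, fb in haps:
            probs[a1 + a2, b1 + b2] += fa * fb
    return probs


def r2_grid_oracle(table: np.ndarray, step: float = 1e-4) -> float:
    """Maximum-likelihood r^2 via grid search over the free haplotype freq."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    p1 = (2 * table[2].sum() + table[1].sum()) / (2 * n)
    p2 = (2 * table[:, 2].sum() + table[:, 1].sum()) / (2 * n)
    lo = max(0.0, p1 + p2 - 1.0)
    hi = min(p1, p2)
    grid = np.arange(lo, hi + step, step)
    grid = np.clip(grid, lo, hi)
    best_ll, best_f = -np.inf, p1 * p2
    for f11 in grid:
        probs = joint_genotype_probs(
            f11, p1 - f11, p2 - f11, 1 - p1 - p2 + f11
        )
        with np.errstate(divide="ignore"):
            ll = float(np.sum(table * np.log(np.clip(probs, 1e-300, None))))
        if ll > best_ll + 1e-12:
            best_ll, best_f = ll, f11
    d = best_f - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    return float(d * d / denom) if denom > 0 else float("nan")


# ----------------------------------------------------------------------
# Weir-Cockerham components from raw allele indicators (nested ANOVA)
# ----------------------------------------------------------------------

def wc_anova_oracle(genotype_blocks: list[np.ndarray]) -> tuple[float, float, float]:
    """(a, b, c) variance components for ONE marker from genotype codes.

    ``genotype_blocks`` holds one int array of diploid genotype codes
    (0/1/2, no missing) per population.  Computed via explicit sums of
    squares on the 0/1 allele indicators in a population/individual/
    allele nested design, then method-of-moments inversion.
    """
    r = len(genotype_blocks)
    alleles_by_ind = []
    pop_of_ind = []
    for i, block in enumerate(genotype_blocks):
        for g in block:
            pair = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(g)]
            alleles_by_ind.append(pair)
            pop_of_ind.append(i)
    x = np.array(alleles_by_ind, dtype=float)  # (n_ind, 2)
    pop = np.array(pop_of_ind)
    n_ind = x.shape[0]
    n_i = np.array([(pop == i).sum() for i in range(r)], dtype=float)

    ind_mean = x.mean(axis=1)
    pop_mean = np.array([ind_mean[pop == i].mean() for i in range(r)])
    tot_mean = x.mean()

    ss_g = float(((x - ind_mean[:, None]) ** 2).sum())
    ss_i = float((2 * (ind_mean - pop_mean[pop]) ** 2).sum())
    ss_p = float((2 * n_i * (pop_mean - tot_mean) ** 2).sum())

    ms_g = ss_g / n_ind
    ms_i = ss_i / (n_ind - r)
    ms_p = ss_p / (r - 1)
    n_c = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)

    c = ms_g
    b = (ms_i - ms_g) / 2.0
    a = (ms_p - ms_i) / (2.0 * n_c)
    return a, b, c
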