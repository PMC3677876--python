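"""Sequential marker quality control.

The chain applies, in order: (1) markers with no calls at all,
(2) call rate below threshold, (3) markers with a single observed
allele across all breeds, (4) markers without a map position,
(5) pooled minor-allele frequency at or below threshold (inclusive),
(6) autosomal markers deviating from Hardy-Weinberg equilibrium
(exact test, per breed; removed when failing in at least one breed;
X is never tested because the panel's males carry one copy), and
(7) X markers with any heterozygous male raw call.  Each marker is
attributed to the first stage that removes it, so the per-stage counts
form a sequential exclusion ledger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .plinkio import MISSING, GenotypeDataset, _allele_counts, split_by_breed

logger = logging.getLogger("ovinescan")

STAGES = (
    "all_missing",
    "call_rate",
    "monomorphic",
    "unmapped",
    "low_maf",
    "hwe",
    "x_male_het",
)


@dataclass
class QcReport:
    """Per-stage exclusion ledger for one QC run."""

    stages: list[tuple[str, int, list[str]]]
    n_input: int
    n_retained_autosomal: int
    n_retained_x: int

    @property
    def n_retained_total(self) -> int:
        return self.n_retained_autosomal + self.n_retained_x

    @property
    def n_removed(self) -> int:
        return sum(n for _, n, _ in self.stages)

    def removed_at(self, stage: str) -> int:
        for name, n, _ in self.stages:
            if name == stage:
                return n
        raise KeyError(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, n, ",".join(ids)) for s, n, ids in self.stages],
            columns=["stage", "n_removed", "marker_ids"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    The p-value sums, over every heterozygote count compatible with the
    observed allele counts, the probabilities of configurations no more
    probable than the observed one.  Monomorphic input returns 1.0.

    Probabilities follow the standard levene/haldane conditional
    distribution, evaluated with the numerically stable ratio
    recurrence rather than raw factorials.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)

    # compatible het counts share the parity of n_a (== parity of rare)
    # and range from rare % 2 up to rare
    n_het_max = rare
    probs: dict[int, float] = {}
    h = rare % 2
    probs[h] = 1.0
    cur = 1.0
    for het in range(h, n_het_max, 2):
        hom_a = (n_a - het) // 2
        hom_b = (n_b - het) // 2
        # P(het+2)/P(het) = 4 * hom_a * hom_b / ((het+2)*(het+1))
        cur *= 4.0 * hom_a * hom_b / ((het + 2.0) * (het + 1.0))
        probs[het + 2] = cur
    total = sum(probs.values())
    p_obs = probs[n_ab] / total
    p_val = sum(p for p in probs.values() if p / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p_val)


def x_male_het_screen(
    dataset: GenotypeDataset,
) -> tuple[list[str], list[str]]:
    """Split X markers by presence of a heterozygous male raw call.

    Returns (retained marker names, removed marker names).  Only male
    calls can trigger removal; a heterozygous female is legitimate.
    """
    x_mask = dataset.is_x()
    if not x_mask.any():
        logger.warning("x_male_het_screen: dataset has no X markers")
        return [], []
    male = dataset.is_male()
    g = dataset.genotypes[male][:, x_mask]
    bad = (g == 1).any(axis=0)
    names = dataset.markers.loc[x_mask, "name"].to_numpy()
    return list(names[~bad]), list(names[bad])


# ----------------------------------------------------------------------
# the chain
# ----------------------------------------------------------------------

def run_qc(
    dataset: GenotypeDataset,
    call_rate: float = 0.95,
    maf: float = 0.05,
    hwe_p: float = 0.01,
) -> tuple[GenotypeDataset, QcReport]:
    """Apply the sequential QC chain; returns the filtered dataset and ledger."""
    for name, value in (("call_rate", call_rate), ("maf", maf), ("hwe_p", hwe_p)):
        if not 0.0 < value < 1.0:
            raise ValueError(f"threshold {name}={value} outside (0,1)")
    if dataset.n_markers == 0 or dataset.n_samples == 0:
        raise ValueError("empty dataset")

    g = dataset.genotypes
    names = dataset.markers["name"].to_numpy()
    active = np.ones(dataset.n_markers, dtype=bool)
    stages: list[tuple[str, int, list[str]]] = []

    def remove(stage: str, mask: np.ndarray) -> None:
        mask = mask & active
        stages.append((stage, int(mask.sum()), list(names[mask])))
        active[mask] = False
        logger.info("qc stage %-12s removed %6d markers", stage, int(mask.sum()))

    called = g != MISSING
    n_called = called.sum(axis=0)

    # 1. markers never genotyped
    remove("all_missing", n_called == 0)

    # 2. call rate below threshold
    remove("call_rate", (n_called / dataset.n_samples) < call_rate)

    # 3. single observed allele pooled over all breeds
    ref, tot = _allele_counts(dataset)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(tot > 0, ref / np.maximum(tot, 1), np.nan)
    mono = (tot > 0) & ((ref == 0) | (ref == tot))
    remove("monomorphic", mono)

    # 4. no chromosome assignment
    remove("unmapped", dataset.is_unmapped())

    # 5. pooled MAF at or below threshold (inclusive removal)
    maf_val = np.minimum(freq, 1.0 - freq)
    remove("low_maf", (maf_val <= maf) & ~np.isnan(maf_val))

    # 6. HWE exact test per breed on autosomes; removed if failing anywhere
    aut = dataset.is_autosomal()
    hwe_fail = np.zeros(dataset.n_markers, dtype=bool)
    test_cols = np.flatnonzero(active & aut)
    for _, sub in split_by_breed(dataset).items():
        gb = sub.genotypes[:, test_cols]
        n_aa = (gb == 2).sum(axis=0)
        n_ab = (gb == 1).sum(axis=0)
        n_bb = (gb == 0).sum(axis=0)
        for k, j in enumerate(test_cols):
            if hwe_fail[j] or n_aa[k] + n_ab[k] + n_bb[k] == 0:
                continue
            if hwe_exact_test(int(n_aa[k]), int(n_ab[k]), int(n_bb[k])) < hwe_p:
                hwe_fail[j] = True
    remove("hwe", hwe_fail)

    # 7. X markers with heterozygous male calls
    x_bad = np.zeros(dataset.n_markers, dtype=bool)
    x_mask = dataset.is_x()
    if x_mask.any():
        male = dataset.is_male()
        if male.any():
            x_bad[x_mask] = (g[male][:, x_mask] == 1).any(axis=0)
    remove("x_male_het", x_bad)

    filtered = dataset.take_markers(active)
    report = QcReport(
        stages=stages,
        n_input=dataset.n_markers,
        n_retained_autosomal=int((active & aut).sum()),
        n_retained_x=int((active & x_mask).sum()),
    )
    return filtered, report
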