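"""Synthetic multi-breed SNP-array genotype generator.

Breed allele frequencies drift from a common ancestral frequency under
the Balding–Nichols model: at a locus with ancestral frequency ``pi``
and per-population drift parameter ``c`` in (0, 1), each population's
frequency is drawn

    p_j ~ Beta(pi * (1 - c) / c,  (1 - pi) * (1 - c) / c)

so that E[p_j] = pi and Var[p_j] = c * pi * (1 - pi); ``c`` is the
differentiation (F_ST-like) parameter.  Genotypes are binomial(2, p_j)
on autosomes and hemizygous binomial(1, p_j) for males on X.

Optional intra-chromosomal LD uses a persistent-uniform copying chain:
each haplotype carries a latent uniform that is refreshed between
adjacent markers with probability 1 - exp(-d / lambda).  Marginal
frequencies are preserved exactly, and the allelic correlation between
markers at distance d is exactly exp(-d / lambda) when their
frequencies are equal (approximately exponential otherwise).

The module also builds genotype-QC fixtures: datasets with exact planted
counts of defective marker classes (no calls, low call rate,
monomorphic, unmapped, low MAF, Hardy-Weinberg failures, male-
heterozygous X markers), each class constructed so it is removed at —
and only at — its intended stage of the sequential QC chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plinkio import (
    MISSING,
    SEX_MALE,
    UNMAPPED,
    X_CHROM,
    GenotypeDataset,
)

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("C", "T"), ("G", "T")]


# ----------------------------------------------------------------------
# specification types
# ----------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Layout and parameters of one simulated dataset.

    ``chrom_layout`` is a list of ``(chrom_name, n_markers, span_bp)``
    tuples; ``populations`` a list of ``(breed, n_samples, c)``.
    """

    chrom_layout: list[tuple[str, int, int]]
    populations: list[tuple[str, int, float]]
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    ld_decay_length: float | None = None
    seed: int = 0
    all_male: bool = True

    def __post_init__(self) -> None:
        for chrom, n, span in self.chrom_layout:
            if n < 1 or span <= 0:
                raise ValueError(f"chromosome {chrom}: need n>=1 and span>0")
        for breed, n, c in self.populations:
            if n < 1:
                raise ValueError(f"population {breed}: sample count must be >= 1")
            if not 0.0 < c < 1.0:
                raise ValueError(f"population {breed}: c={c} outside (0,1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        if self.ld_decay_length is not None and self.ld_decay_length <= 0:
            raise ValueError("ld_decay_length must be positive")

    @property
    def n_markers(self) -> int:
        return sum(n for _, n, _ in self.chrom_layout)

    @property
    def n_samples(self) -> int:
        return sum(n for _, n, _ in self.populations)


def default_chrom_layout(
    n_markers: int, n_autosomes: int = 26, include_x: bool = False,
    span_bp: int = 100_000_000,
) -> list[tuple[str, int, int]]:
    """Spread markers evenly over ``n_autosomes`` autosomes (+ X)."""
    n_chroms = n_autosomes + int(include_x)
    base, extra = divmod(n_markers, n_chroms)
    names = [str(i) for i in range(1, n_autosomes + 1)]
    if include_x:
        names.append(X_CHROM)
    return [(nm, base + (1 if i < extra else 0), span_bp)
            for i, nm in enumerate(names)]


@dataclass
class QcFixtureLayout:
    """Exact counts of each defective marker class to plant.

    The defect classes are disjoint by construction; autosomal classes
    are evaluated in the QC chain's filter order, so the planted counts
    are recovered exactly as the chain's sequential exclusions.
    """

    n_total: int
    n_all_missing: int = 0
    n_low_callrate: int = 0
    n_monomorphic: int = 0
    n_unmapped: int = 0
    n_low_maf: int = 0
    n_hwe_fail: int = 0
    n_x_total: int = 0
    n_x_male_het: int = 0

    def __post_init__(self) -> None:
        if self.n_x_male_het > self.n_x_total:
            raise ValueError("n_x_male_het exceeds n_x_total")
        if self.n_defects + self.n_x_total + self.n_hwe_fail > self.n_total:
            raise ValueError("planted classes exceed n_total markers")

    @property
    def n_defects(self) -> int:
        return (self.n_all_missing + self.n_low_callrate + self.n_monomorphic
                + self.n_unmapped + self.n_low_maf)

    @classmethod
    def ovine_chip(cls) -> "QcFixtureLayout":
        """Layout mirroring the OvineSNP50 five-breed study's QC ledger."""
        return cls(
            n_total=54_241,
            n_all_missing=695,
            n_low_callrate=1_019,
            n_monomorphic=1_235,
            n_unmapped=350,
            n_low_maf=2_057,
            n_hwe_fail=747,
            n_x_total=1_288,
            n_x_male_het=112,
        )


#: breed sizes of the five-breed ram panel the pipeline emulates
STUDY_POPULATIONS: list[tuple[str, int, float]] = [
    ("Columbia", 19, 0.114),
    ("Polypay", 19, 0.114),
    ("Rambouillet", 16, 0.114),
    ("Suffolk", 18, 0.114),
    ("Targhee", 22, 0.114),
]


@dataclass
class PlantedSignal:
    """A genomic span whose markers are redrawn at elevated drift."""

    chrom: str
    start_bp: int
    end_bp: int
    elevated_c: float
    population_subset: list[str] | None = None

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("end_bp must exceed start_bp")
        if not 0.0 < self.elevated_c < 1.0:
            raise ValueError("elevated_c outside (0,1)")


# ----------------------------------------------------------------------
# core draws
# ----------------------------------------------------------------------

def draw_population_frequencies(
    pi: float | np.ndarray, c: float | np.ndarray, n_pops: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Balding–Nichols population frequencies around ancestral ``pi``.

    Returns an array of shape ``(n_pops,) + shape(pi)``.  ``c`` may be
    scalar or one value per population.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any((pi <= 0.0) | (pi >= 1.0)):
        raise ValueError("ancestral frequency must be strictly inside (0,1)")
    c = np.asarray(c, dtype=float)
    if np.any((c <= 0.0) | (c >= 1.0)):
        raise ValueError("drift parameter c must be strictly inside (0,1)")
    if c.ndim == 0:
        c = np.broadcast_to(c, (n_pops,))
    scale = (1.0 - c) / c  # shape (n_pops,)
    alpha = pi[None, ...] * scale.reshape((n_pops,) + (1,) * pi.ndim)
    beta = (1.0 - pi[None, ...]) * scale.reshape((n_pops,) + (1,) * pi.ndim)
    return rng.beta(alpha, beta)


def sample_genotypes(
    freqs: np.ndarray,
    n_per_pop: list[int],
    rng: np.random.Generator,
    is_x: np.ndarray | None = None,
    is_male: np.ndarray | None = None,
    missing_rate: float = 0.0,
) -> np.ndarray:
    """Draw genotype codes from per-population frequencies.

    ``freqs`` has shape (n_pops, n_markers).  Autosomal genotypes are
    binomial(2, p); male X genotypes binomial(1, p) coded {0, 2}.
    """
    freqs = np.asarray(freqs, dtype=float)
    n_pops, n_markers = freqs.shape
    if len(n_per_pop) != n_pops:
        raise ValueError("n_per_pop length does not match freqs")
    n_total = int(sum(n_per_pop))
    if is_x is None:
        is_x = np.zeros(n_markers, dtype=bool)
    if is_male is None:
        is_male = np.ones(n_total, dtype=bool)
    g = np.empty((n_total, n_markers), dtype=np.int8)
    row = 0
    for j, n in enumerate(n_per_pop):
        p = freqs[j]
        block = rng.binomial(2, p, size=(n, n_markers)).astype(np.int8)
        if is_x.any():
            male_rows = is_male[row:row + n]
            if male_rows.any():
                hemi = rng.binomial(1, p[is_x],
                                    size=(int(male_rows.sum()), int(is_x.sum())))
                block[np.ix_(male_rows, is_x)] = (2 * hemi).astype(np.int8)
        g[row:row + n] = block
        row += n
    if missing_rate > 0.0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    return g


def simulate_ld_haplotypes(
    freqs: np.ndarray,
    positions: np.ndarray,
    n_haplotypes: int,
    ld_decay_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotype pool for one chromosome with distance-decaying LD.

    A per-haplotype latent uniform persists along the chromosome and is
    refreshed between adjacent markers with probability
    ``1 - exp(-d / ld_decay_length)``; allele_i = latent < freq_i.
    Returns a 0/1 array (n_haplotypes, n_markers).
    """
    if ld_decay_length <= 0:
        raise ValueError("ld_decay_length must be positive")
    freqs = np.asarray(freqs, dtype=float)
    positions = np.asarray(positions, dtype=float)
    m = freqs.shape[0]
    gaps = np.diff(positions)
    if np.any(gaps < 0):
        raise ValueError("positions must be sorted")
    keep_prob = np.exp(-gaps / ld_decay_length)
    u = np.empty((n_haplotypes, m))
    u[:, 0] = rng.random(n_haplotypes)
    for i in range(1, m):
        refresh = rng.random(n_haplotypes) >= keep_prob[i - 1]
        u[:, i] = np.where(refresh, rng.random(n_haplotypes), u[:, i - 1])
    return (u < freqs[None, :]).astype(np.int8)


# ----------------------------------------------------------------------
# whole-dataset simulation
# ----------------------------------------------------------------------

def _marker_table(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, n, span in spec.chrom_layout:
        pos = np.round(span * (np.arange(n) + 1) / n).astype(np.int64)
        pos = np.maximum(pos, 1)
        for k in range(n):
            rows.append((f"snp_{chrom}_{k + 1}", chrom, int(pos[k])))
    markers = pd.DataFrame(rows, columns=["name", "chrom", "pos"])
    pairs = rng.integers(0, len(_ALLELE_PAIRS), size=len(markers))
    markers["a1"] = [_ALLELE_PAIRS[i][0] for i in pairs]
    markers["a2"] = [_ALLELE_PAIRS[i][1] for i in pairs]
    return markers


def simulate(spec: SimulationSpec, rng: np.random.Generator | None = None) -> GenotypeDataset:
    """Draw one dataset under the spec; deterministic for a given seed."""
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(spec.seed))
    markers = _marker_table(spec, rng)
    n_markers = len(markers)
    lo, hi = spec.ancestral_maf_range
    pi = rng.uniform(lo, hi, size=n_markers)
    # random strand so the reference allele is not always the minor one
    flip = rng.random(n_markers) < 0.5
    pi = np.where(flip, 1.0 - pi, pi)
    markers["ancestral_freq"] = pi

    c = np.array([c_j for _, _, c_j in spec.populations])
    n_per_pop = [n for _, n, _ in spec.populations]
    freqs = draw_population_frequencies(pi, c, len(spec.populations), rng)

    is_x = (markers["chrom"] == X_CHROM).to_numpy()
    samples = pd.DataFrame(
        [
            (f"{breed}_{i + 1}", breed, SEX_MALE if spec.all_male else (1 + i % 2))
            for breed, n, _ in spec.populations
            for i in range(n)
        ],
        columns=["sample_id", "breed", "sex"],
    )
    is_male = (samples["sex"] == SEX_MALE).to_numpy()

    if spec.ld_decay_length is None:
        g = sample_genotypes(
            freqs, n_per_pop, rng, is_x=is_x, is_male=is_male,
            missing_rate=0.0,
        )
    else:
        g = _sample_genotypes_ld(spec, markers, freqs, is_male, rng)

    if spec.missing_rate > 0.0:
        g[rng.random(g.shape) < spec.missing_rate] = MISSING

    ds = GenotypeDataset(samples=samples, markers=markers, genotypes=g)
    return ds.with_first_observed_reference()


def _sample_genotypes_ld(
    spec: SimulationSpec,
    markers: pd.DataFrame,
    freqs: np.ndarray,
    is_male: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n_total = spec.n_samples
    g = np.empty((n_total, len(markers)), dtype=np.int8)
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()
    for chrom, _, _ in spec.chrom_layout:
        sel = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[sel]
        row = 0
        for j, (_, n, _) in enumerate(spec.populations):
            p = freqs[j][sel]
            if chrom == X_CHROM:
                male_rows = is_male[row:row + n]
                n_hap = 2 * int((~male_rows).sum()) + int(male_rows.sum())
                haps = simulate_ld_haplotypes(p, pos, n_hap, spec.ld_decay_length, rng)
                block = np.empty((n, len(sel)), dtype=np.int8)
                h = 0
                for i in range(n):
                    if male_rows[i]:
                        block[i] = 2 * haps[h]
                        h += 1
                    else:
                        block[i] = haps[h] + haps[h + 1]
                        h += 2
            else:
                haps = simulate_ld_haplotypes(p, pos, 2 * n, spec.ld_decay_length, rng)
                block = (haps[0::2] + haps[1::2]).astype(np.int8)
            g[np.ix_(np.arange(row, row + n), sel)] = block
            row += n
    return g


def plant_signal(
    dataset: GenotypeDataset,
    signal: PlantedSignal,
    spec: SimulationSpec,
    rng: np.random.Generator,
) -> GenotypeDataset:
    """Redraw markers inside the signal span at elevated drift.

    Ground truth for region-calling recovery tests: population
    frequencies for the affected populations are redrawn from the
    Balding–Nichols distribution with ``elevated_c`` around the stored
    ancestral frequency, and genotypes inside the span resampled.
    Markers outside the span are untouched.
    """
    markers = dataset.markers
    if signal.chrom not in set(markers["chrom"]):
        raise ValueError(f"chromosome {signal.chrom!r} not present in the map")
    if "ancestral_freq" not in markers:
        raise ValueError("dataset lacks ancestral frequencies (not simulated?)")
    in_span = (
        (markers["chrom"] == signal.chrom)
        & (markers["pos"] >= signal.start_bp)
        & (markers["pos"] <= signal.end_bp)
    ).to_numpy()
    if not in_span.any():
        raise ValueError("signal span covers no markers")
    pops = [name for name, _, _ in spec.populations]
    subset = signal.population_subset or pops
    unknown = set(subset) - set(pops)
    if unknown:
        raise ValueError(f"unknown populations in signal: {sorted(unknown)}")
    for name, _, bg_c in spec.populations:
        if name in subset and signal.elevated_c <= bg_c:
            raise ValueError(
                f"elevated_c={signal.elevated_c} not above background "
                f"c={bg_c} of population {name}"
            )

    g = dataset.genotypes.copy()
    pi = markers.loc[in_span, "ancestral_freq"].to_numpy()
    is_x_span = (markers.loc[in_span, "chrom"] == X_CHROM).to_numpy()
    breeds = dataset.samples["breed"].to_numpy()
    is_male = dataset.is_male()
    cols = np.flatnonzero(in_span)
    for name, _, _ in spec.populations:
        if name not in subset:
            continue
        p_new = draw_population_frequencies(pi, signal.elevated_c, 1, rng)[0]
        rows = np.flatnonzero(breeds == name)
        block = rng.binomial(2, p_new, size=(rows.size, cols.size)).astype(np.int8)
        if is_x_span.any():
            male_rows = is_male[rows]
            hemi = rng.binomial(
                1, p_new[is_x_span],
                size=(int(male_rows.sum()), int(is_x_span.sum())),
            )
            block[np.ix_(male_rows, is_x_span)] = (2 * hemi).astype(np.int8)
        g[np.ix_(rows, cols)] = block
    return GenotypeDataset(dataset.samples.copy(), markers.copy(), g)


# ----------------------------------------------------------------------
# QC fixture construction
# ----------------------------------------------------------------------

def _hwe_conformant_counts(p: float, n: int) -> tuple[int, int, int]:
    """Genotype counts at the rounded Hardy-Weinberg expectation."""
    n_aa = int(round(p * p * n))
    n_bb = int(round((1 - p) * (1 - p) * n))
    n_ab = n - n_aa - n_bb
    if n_ab < 0:  # extreme p with rounding; push into homozygotes
        n_ab = 0
        n_aa = min(n_aa, n)
        n_bb = n - n_aa
    return n_aa, n_ab, n_bb


def _fill_counts(col: np.ndarray, rows: np.ndarray, counts: tuple[int, int, int]) -> None:
    n_aa, n_ab, n_bb = counts
    codes = np.concatenate([
        np.full(n_aa, 2, dtype=np.int8),
        np.full(n_ab, 1, dtype=np.int8),
        np.full(n_bb, 0, dtype=np.int8),
    ])
    col[rows] = codes


def build_qc_fixture(
    layout: QcFixtureLayout,
    populations: list[tuple[str, int, float]] | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> GenotypeDataset:
    """Dataset with exactly the planted counts of each QC defect class.

    Clean markers have per-breed genotype counts at the rounded
    Hardy-Weinberg expectation of a frequency in (0.15, 0.45), so they
    deterministically pass every filter; each defect class fails its
    intended stage and no earlier one.
    """
    if populations is None:
        populations = STUDY_POPULATIONS
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(seed))

    pop_sizes = [n for _, n, _ in populations]
    n_samples = int(sum(pop_sizes))
    pop_slices = []
    start = 0
    for n in pop_sizes:
        pop_slices.append(np.arange(start, start + n))
        start += n

    n_aut = layout.n_total - layout.n_x_total - layout.n_unmapped
    n_x = layout.n_x_total
    # autosomal classes (all defect classes except unmapped live on autosomes)
    class_sizes = {
        "all_missing": layout.n_all_missing,
        "low_callrate": layout.n_low_callrate,
        "monomorphic": layout.n_monomorphic,
        "low_maf": layout.n_low_maf,
        "hwe_fail": layout.n_hwe_fail,
    }
    n_clean_aut = n_aut - sum(class_sizes.values())
    if n_clean_aut < 0:
        raise ValueError("autosomal defect classes exceed autosomal total")

    # --- marker map: autosomes 1..26, then X, then unmapped -----------
    aut_layout = default_chrom_layout(n_aut, n_autosomes=26)
    rows = []
    for chrom, n, span in aut_layout:
        pos = np.round(span * (np.arange(n) + 1) / n).astype(np.int64)
        for k in range(n):
            rows.append((f"snp_{chrom}_{k + 1}", chrom, int(max(pos[k], 1))))
    for k in range(n_x):
        rows.append((f"snp_X_{k + 1}", X_CHROM, int(100_000 * (k + 1))))
    for k in range(layout.n_unmapped):
        rows.append((f"snp_un_{k + 1}", UNMAPPED, 0))
    markers = pd.DataFrame(rows, columns=["name", "chrom", "pos"])
    pairs = rng.integers(0, len(_ALLELE_PAIRS), size=len(markers))
    markers["a1"] = [_ALLELE_PAIRS[i][0] for i in pairs]
    markers["a2"] = [_ALLELE_PAIRS[i][1] for i in pairs]

    samples = pd.DataFrame(
        [
            (f"{breed}_{i + 1}", breed, SEX_MALE)
            for breed, n, _ in populations
            for i in range(n)
        ],
        columns=["sample_id", "breed", "sex"],
    )

    n_markers = len(markers)
    g = np.empty((n_samples, n_markers), dtype=np.int8)

    # class membership over autosomal marker indices, shuffled
    aut_idx = rng.permutation(n_aut)
    assign: dict[str, np.ndarray] = {}
    off = 0
    for name, size in class_sizes.items():
        assign[name] = np.sort(aut_idx[off:off + size])
        off += size
    clean_aut = np.sort(aut_idx[off:])
    x_idx = np.arange(n_aut, n_aut + n_x)
    x_het = x_idx[:layout.n_x_male_het]
    x_clean = x_idx[layout.n_x_male_het:]
    un_idx = np.arange(n_aut + n_x, n_markers)

    def clean_column(j: int) -> None:
        p = rng.uniform(0.15, 0.45)
        for sl, (_, n, _) in zip(pop_slices, populations):
            _fill_counts(g[:, j], sl, _hwe_conformant_counts(p, n))

    # clean autosomal + unmapped markers (unmapped fail only stage 4)
    for j in np.concatenate([clean_aut, un_idx]):
        clean_column(int(j))

    # stage 1: no calls at all
    g[:, assign["all_missing"]] = MISSING

    # stage 2: call rate just under threshold (but not all missing)
    n_called = int(np.ceil(0.95 * n_samples)) - 1
    for j in assign["low_callrate"]:
        clean_column(int(j))
        drop = rng.choice(n_samples, size=n_samples - n_called, replace=False)
        g[drop, j] = MISSING

    # stage 3: one allele observed everywhere
    g[:, assign["monomorphic"]] = 2

    # stage 5: pooled MAF <= 0.05 but polymorphic (a few het carriers)
    n_minor = max(1, int(0.05 * 2 * n_samples) - 3)
    for j in assign["low_maf"]:
        g[:, j] = 2
        carriers = rng.choice(n_samples, size=n_minor, replace=False)
        g[carriers, j] = 1

    # stage 6: grossly heterozygote-excessive in the largest breed
    big = int(np.argmax(pop_sizes))
    for j in assign["hwe_fail"]:
        clean_column(int(j))
        g[pop_slices[big], j] = 1  # all heterozygous: exact-test P << 0.01

    # X markers: hemizygous males, codes {0,2}; target freq > MAF threshold
    for j in np.concatenate([x_clean, x_het]):
        p = rng.uniform(0.15, 0.45)
        for sl, (_, n, _) in zip(pop_slices, populations):
            n_ref = int(round(p * n))
            col = np.concatenate([
                np.full(n_ref, 2, dtype=np.int8),
                np.full(n - n_ref, 0, dtype=np.int8),
            ])
            g[sl, j] = col
    # plant >= 1 heterozygous male call on the flagged X markers
    for j in x_het:
        bad = rng.choice(n_samples, size=3, replace=False)
        g[bad, j] = 1

    ds = GenotypeDataset(samples=samples, markers=markers, genotypes=g)
    return ds.with_first_observed_reference()
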