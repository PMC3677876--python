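"""PLINK PED/MAP text I/O and the shared genotype container.

Genotypes are stored as an ``int8`` matrix of counts of a per-marker
reference allele (``a1``): 0, 1, 2, with -1 for missing.  Male X
genotypes are hemizygous and coded {0, 2} (the single allele written
twice, as PLINK does); a male heterozygous raw call on X is an invalid
genotype that is kept in the matrix (code 1) so that QC can detect it,
but it is excluded from allele-frequency denominators.

Breed labels travel in the PED family-id column, the standard PLINK
convention for population cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ovinescan")

MISSING: int = -1
#: chromosome label used for markers without a map position
UNMAPPED: str = "0"
X_CHROM: str = "X"

_VALID_ALLELES = frozenset("ACGT0")

SEX_MALE = 1
SEX_FEMALE = 2


class PlinkFormatError(ValueError):
    """Malformed PED/MAP input; message carries file and line number."""


@dataclass
class GenotypeDataset:
    """Samples x markers genotype table with breed and sex metadata.

    Attributes
    ----------
    samples : pandas.DataFrame
        Columns ``sample_id``, ``breed``, ``sex`` (1=male, 2=female).
    markers : pandas.DataFrame
        Columns ``name``, ``chrom`` (``"1"``..``"26"``, ``"X"`` or
        ``"0"`` for unmapped), ``pos`` (1-based bp; 0 when unmapped),
        ``a1``, ``a2``.  Simulated datasets carry an extra
        ``ancestral_freq`` column.
    genotypes : numpy.ndarray
        ``int8`` array of shape (n_samples, n_markers); counts of
        ``a1`` with -1 for missing.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        n_s, n_m = self.genotypes.shape
        if len(self.samples) != n_s or len(self.markers) != n_m:
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        names = self.markers["name"]
        if names.duplicated().any():
            dups = names[names.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker name {dups!r}")
        if (self.samples["breed"].astype(str) == "").any():
            raise ValueError("empty breed label")

    # ------------------------------------------------------------------
    # basic views
    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def breeds(self) -> list[str]:
        return list(dict.fromkeys(self.samples["breed"]))

    def is_x(self) -> np.ndarray:
        return (self.markers["chrom"] == X_CHROM).to_numpy()

    def is_unmapped(self) -> np.ndarray:
        return (self.markers["chrom"] == UNMAPPED).to_numpy()

    def is_autosomal(self) -> np.ndarray:
        return ~self.is_x() & ~self.is_unmapped()

    def is_male(self) -> np.ndarray:
        return (self.samples["sex"] == SEX_MALE).to_numpy()

    def take_markers(self, index: np.ndarray) -> "GenotypeDataset":
        """Subset to the given marker positions (bool mask or int index)."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            samples=self.samples.reset_index(drop=True),
            markers=self.markers.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, idx].copy(),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            samples=self.samples.iloc[idx].reset_index(drop=True),
            markers=self.markers.reset_index(drop=True),
            genotypes=self.genotypes[idx, :].copy(),
        )

    # ------------------------------------------------------------------
    # allele bookkeeping
    # ------------------------------------------------------------------
    def with_first_observed_reference(self) -> "GenotypeDataset":
        """Flip codes so that ``a1`` is the first allele seen in sample order.

        Writing then re-reading a dataset in this normal form reproduces
        the genotype matrix exactly; every downstream statistic is
        invariant to the flip.
        """
        g = self.genotypes
        markers = self.markers.copy()
        flip = np.zeros(self.n_markers, dtype=bool)
        for j in range(self.n_markers):
            col = g[:, j]
            called = col[col != MISSING]
            if called.size == 0:
                continue
            first = called[0]
            # first allele listed for the first called sample: a1 if the
            # genotype carries any a1 copy, else a2
            if first == 0:
                flip[j] = True
        if flip.any():
            g = g.copy()
            cols = np.flatnonzero(flip)
            sub = g[:, cols]
            miss = sub == MISSING
            sub = 2 - sub
            sub[miss] = MISSING
            g[:, cols] = sub
            a1 = markers["a1"].to_numpy().copy()
            a2 = markers["a2"].to_numpy().copy()
            a1[cols], a2[cols] = a2[cols], a1[cols].copy()
            markers["a1"], markers["a2"] = a1, a2
            if "ancestral_freq" in markers:
                af = markers["ancestral_freq"].to_numpy().copy()
                af[cols] = 1.0 - af[cols]
                markers["ancestral_freq"] = af
        return GenotypeDataset(self.samples.copy(), markers, g)


def split_by_breed(dataset: GenotypeDataset) -> dict[str, GenotypeDataset]:
    """Partition samples into one dataset view per breed (shared marker set)."""
    out: dict[str, GenotypeDataset] = {}
    breeds = dataset.samples["breed"].to_numpy()
    for breed in dict.fromkeys(breeds):
        if str(breed) == "":
            raise ValueError("empty breed label")
        out[str(breed)] = dataset.take_samples(breeds == breed)
    return out


def allele_frequencies(
    dataset: GenotypeDataset, by_breed: bool = False
) -> pd.DataFrame:
    """Reference-allele frequency and call counts per marker.

    Missing genotypes are excluded from denominators.  Male X genotypes
    contribute a single allele; male heterozygous X calls are invalid
    and excluded.  With ``by_breed`` the table gains one
    ``freq_<breed>`` / ``n_alleles_<breed>`` column pair per breed.
    """
    base = _freq_columns(dataset)
    if by_breed:
        for breed, sub in split_by_breed(dataset).items():
            cols = _freq_columns(sub)
            base[f"n_alleles_{breed}"] = cols["n_alleles"]
            base[f"freq_{breed}"] = cols["freq"]
    return base


def _allele_counts(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """(reference-allele count, total allele count) per marker."""
    g = dataset.genotypes
    called = g != MISSING
    x = dataset.is_x()
    male = dataset.is_male()
    # weight per (sample, marker): 2 alleles except male X (1 allele)
    weight = np.full(g.shape, 2.0)
    weight[np.ix_(male, np.flatnonzero(x))] = 1.0
    # ref-copy contribution: code for diploid calls, code/2 for male X
    contrib = np.where(called, g, 0).astype(float)
    contrib[np.ix_(male, np.flatnonzero(x))] /= 2.0
    valid = called.copy()
    # male het on X: invalid call, excluded
    if x.any() and male.any():
        bad = (g == 1) & male[:, None] & x[None, :]
        valid &= ~bad
    ref = np.where(valid, contrib, 0.0).sum(axis=0)
    tot = np.where(valid, weight, 0.0).sum(axis=0)
    return ref, tot


def _freq_columns(dataset: GenotypeDataset) -> pd.DataFrame:
    ref, tot = _allele_counts(dataset)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(tot > 0, ref / np.maximum(tot, 1), np.nan)
    return pd.DataFrame(
        {
            "name": dataset.markers["name"].to_numpy(),
            "n_calls": (dataset.genotypes != MISSING).sum(axis=0),
            "n_alleles": tot.astype(int),
            "freq": freq,
        }
    )


# ----------------------------------------------------------------------
# PED/MAP reading and writing
# ----------------------------------------------------------------------

def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Parse a whitespace-separated PED/MAP pair into a dataset.

    The per-marker reference allele ``a1`` is the first non-missing
    allele symbol observed in file order.  The PED family-id column is
    taken as the breed label.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    markers = _read_map(map_path)
    n_markers = len(markers)

    sample_rows = []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise PlinkFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} "
                    f"fields, got {len(fields)}"
                )
            fid, iid, _pat, _mat, sex, _pheno = fields[:6]
            sample_rows.append((iid, fid, int(sex)))
            alleles = fields[6:]
            for k, a in enumerate(alleles):
                if a not in _VALID_ALLELES:
                    raise PlinkFormatError(
                        f"{ped_path}:{lineno}: invalid allele symbol {a!r} "
                        f"at marker {markers['name'].iloc[k // 2]!r}"
                    )
            allele_rows.append(alleles)

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "breed", "sex"])
    allele_arr = np.array(allele_rows, dtype="U1").reshape(len(samples), n_markers, 2)

    a1 = np.full(n_markers, "0", dtype="U1")
    a2 = np.full(n_markers, "0", dtype="U1")
    geno = np.full((len(samples), n_markers), MISSING, dtype=np.int8)
    for j in range(n_markers):
        pair = allele_arr[:, j, :]
        flat = pair.reshape(-1)
        nz = flat != "0"
        if nz.any():
            a1[j] = flat[np.argmax(nz)]
            other = nz & (flat != a1[j])
            if other.any():
                a2[j] = flat[np.argmax(other)]
        half_missing = (pair == "0").sum(axis=1) == 1
        if half_missing.any():
            raise PlinkFormatError(
                f"{ped_path}: half-missing genotype at marker "
                f"{markers['name'].iloc[j]!r}"
            )
        called = pair[:, 0] != "0"
        geno[called, j] = (pair[called] == a1[j]).sum(axis=1)

    markers = markers.assign(a1=a1, a2=a2)
    return GenotypeDataset(samples=samples, markers=markers, genotypes=geno)


def _read_map(map_path: Path) -> pd.DataFrame:
    rows = []
    seen: set[str] = set()
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PlinkFormatError(
                    f"{map_path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            chrom, name, _cm, pos = fields
            if name in seen:
                raise PlinkFormatError(
                    f"{map_path}:{lineno}: duplicate marker name {name!r}"
                )
            seen.add(name)
            rows.append((name, chrom, int(pos)))
    return pd.DataFrame(rows, columns=["name", "chrom", "pos"])


def write_ped_map(
    dataset: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write the dataset as a PED/MAP pair (missing = ``0 0``, 0 cM)."""
    markers = dataset.markers
    with open(map_path, "w") as fh:
        for row in markers.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.name}\t0\t{int(row.pos)}\n")

    a1 = markers["a1"].to_numpy()
    a2 = markers["a2"].to_numpy()
    g = dataset.genotypes
    # genotype code -> two allele symbols per marker
    sym = np.empty((4, len(markers)), dtype=object)
    sym[0] = [f"{b} {b}" for b in a2]
    sym[1] = [f"{a} {b}" for a, b in zip(a1, a2)]
    sym[2] = [f"{a} {a}" for a in a1]
    sym[3] = "0 0"  # missing
    if ((g == 0) & (a2 == "0")[None, :]).any() or ((g == 1) & (a2 == "0")[None, :]).any():
        raise ValueError("genotype carries an allele with no symbol (a2='0')")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(dataset.samples.itertuples(index=False)):
            codes = g[i].copy()
            codes[codes == MISSING] = 3
            geno_str = " ".join(sym[codes, np.arange(len(markers))])
            fh.write(f"{s.breed} {s.sample_id} 0 0 {int(s.sex)} -9 {geno_str}\n")


def write_prefix(dataset: GenotypeDataset, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` / ``<prefix>.map``; returns the two paths."""
    prefix = Path(prefix)
    ped, mp = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    write_ped_map(dataset, ped, mp)
    return ped, mp


def read_prefix(prefix: str | Path) -> GenotypeDataset:
    prefix = Path(prefix)
    return read_ped_map(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
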