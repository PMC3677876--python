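"""Differentially selected region (DSR) calling from a ranked F_ST track.

Raw per-SNP F_ST values are ranked jointly across all chromosomes in
the track; markers at or above the empirical top-0.1% and top-5%
quantile values are flagged (ties included).  Each top-0.1% marker
seeds a region: the scan extends outward marker by marker in each
direction independently and a direction stops once four consecutive
markers outside the top 5% have been seen ("more than three
consecutive" non-significant SNPs).  The region boundary is the
outermost included top-5% marker (the seed alone if none).  Candidate
regions longer than 3 Mb are truncated to the 1.5 Mb up- and downstream
flanks of the peak SNP, and overlapping regions on a chromosome are
merged (peak = highest raw F_ST of the union).  Seeds are processed in
descending F_ST order; a seed already inside a called region does not
nucleate a new one.

Coordinates are 1-based closed internally; BED output converts to
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ovinescan")

TOP_SEED_QUANTILE = 0.001
TOP_EXTEND_QUANTILE = 0.05
RUN_BREAK = 4          # stop a direction at the 4th consecutive non-top-5% SNP
MAX_SPAN_BP = 3_000_000
FLANK_BP = 1_500_000


@dataclass
class Region:
    """One called region with its peak SNP and flagged-marker counts."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_name: str
    peak_pos: int
    peak_fst: float
    n_top01: int
    n_top5: int
    member_names: list[str] = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )


# ----------------------------------------------------------------------
# ranking
# ----------------------------------------------------------------------

def rank_and_flag(
    track: pd.DataFrame,
    top01: float = TOP_SEED_QUANTILE,
    top5: float = TOP_EXTEND_QUANTILE,
) -> pd.DataFrame:
    """Flag top-0.1% and top-5% markers of one joint ranking.

    Thresholds are the empirical quantile values: with m markers the
    top-q threshold is the ceil(q*m)-th largest raw F_ST, and every
    marker with F_ST >= threshold is flagged, so ties at the threshold
    are all included.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    track = track.copy()
    fst = track["fst"].to_numpy(dtype=float)
    m = fst.size
    srt = np.sort(fst)
    for label, q in (("in_top01", top01), ("in_top5", top5)):
        kth = max(1, int(np.ceil(q * m)))
        threshold = srt[m - kth]
        track[label] = fst >= threshold
    if track["in_top01"].all():
        logger.warning("rank_and_flag: degenerate ranking, every marker flagged")
    track["rank"] = pd.Series(fst).rank(ascending=False, method="min").astype(int).to_numpy()
    return track


# ----------------------------------------------------------------------
# growth, truncation, merging
# ----------------------------------------------------------------------

def grow_region(
    chrom_track: pd.DataFrame, seed_iloc: int, run_break: int = RUN_BREAK
) -> Region:
    """Grow one region around a top-0.1% seed within one chromosome.

    ``chrom_track`` must be sorted by position and flagged.  Each
    direction is scanned independently; it stops once ``run_break``
    consecutive markers outside the top 5% are encountered.
    """
    if not bool(chrom_track["in_top01"].iloc[seed_iloc]):
        raise ValueError("seed marker is not in the top 0.1%")
    pos = chrom_track["pos"].to_numpy()
    top5 = chrom_track["in_top5"].to_numpy()
    m = len(chrom_track)

    def scan(direction: int) -> int:
        """Index of the outermost included top-5% marker in a direction."""
        boundary = seed_iloc
        run = 0
        i = seed_iloc + direction
        while 0 <= i < m:
            if top5[i]:
                boundary = i
                run = 0
            else:
                run += 1
                if run >= run_break:
                    break
            i += direction
        return boundary

    left, right = scan(-1), scan(+1)
    members = chrom_track.iloc[left:right + 1]
    peak_iloc = int(members["fst"].to_numpy().argmax()) + left
    return Region(
        chrom=str(chrom_track["chrom"].iloc[0]),
        start_bp=int(pos[left]),
        end_bp=int(pos[right]),
        peak_name=str(chrom_track["name"].iloc[peak_iloc]),
        peak_pos=int(pos[peak_iloc]),
        peak_fst=float(chrom_track["fst"].iloc[peak_iloc]),
        n_top01=int(members["in_top01"].sum()),
        n_top5=int(members["in_top5"].sum()),
        member_names=list(members["name"]),
    )


def _recount(region: Region, chrom_track: pd.DataFrame) -> Region:
    """Recompute membership, counts and peak from the region's span."""
    sel = (chrom_track["pos"] >= region.start_bp) & (chrom_track["pos"] <= region.end_bp)
    members = chrom_track[sel]
    if len(members) == 0:
        raise ValueError("region covers no markers after truncation")
    peak = members["fst"].idxmax()
    return Region(
        chrom=region.chrom,
        start_bp=region.start_bp,
        end_bp=region.end_bp,
        peak_name=str(members.loc[peak, "name"]),
        peak_pos=int(members.loc[peak, "pos"]),
        peak_fst=float(members.loc[peak, "fst"]),
        n_top01=int(members["in_top01"].sum()),
        n_top5=int(members["in_top5"].sum()),
        member_names=list(members["name"]),
    )


def truncate_and_merge(
    regions: list[Region],
    chrom_track: pd.DataFrame,
    max_span: int = MAX_SPAN_BP,
    flank: int = FLANK_BP,
) -> list[Region]:
    """Cap over-long regions at peak +/- flank, then union overlaps.

    Truncation precedes merging; merged regions take the higher peak
    and have their counts recomputed over the union span.
    """
    capped = []
    for reg in regions:
        if reg.span_bp > max_span:
            reg = _recount(
                Region(
                    chrom=reg.chrom,
                    start_bp=max(1, reg.peak_pos - flank),
                    end_bp=reg.peak_pos + flank,
                    peak_name=reg.peak_name,
                    peak_pos=reg.peak_pos,
                    peak_fst=reg.peak_fst,
                    n_top01=0,
                    n_top5=0,
                ),
                chrom_track,
            )
        capped.append(reg)
    capped.sort(key=lambda r: r.start_bp)
    merged: list[Region] = []
    for reg in capped:
        if merged and merged[-1].overlaps(reg):
            prev = merged.pop()
            union = Region(
                chrom=reg.chrom,
                start_bp=min(prev.start_bp, reg.start_bp),
                end_bp=max(prev.end_bp, reg.end_bp),
                peak_name="",
                peak_pos=0,
                peak_fst=0.0,
                n_top01=0,
                n_top5=0,
            )
            merged.append(_recount(union, chrom_track))
        else:
            merged.append(reg)
    return merged


def call_regions(
    track: pd.DataFrame,
    top01: float = TOP_SEED_QUANTILE,
    top5: float = TOP_EXTEND_QUANTILE,
    run_break: int = RUN_BREAK,
    max_span: int = MAX_SPAN_BP,
    flank: int = FLANK_BP,
) -> list[Region]:
    """Full calling pass: rank, grow from each seed, truncate, merge.

    The ranking is joint over every chromosome in the track (autosomes
    and X together).  Deterministic for a fixed track and invariant to
    marker naming.
    """
    flagged = rank_and_flag(track, top01=top01, top5=top5)
    out: list[Region] = []
    for chrom in dict.fromkeys(flagged["chrom"]):
        ct = (
            flagged[flagged["chrom"] == chrom]
            .sort_values("pos", kind="stable")
            .reset_index(drop=True)
        )
        seeds = ct[ct["in_top01"]].sort_values("fst", ascending=False, kind="stable")
        regions: list[Region] = []
        for seed_iloc in seeds.index:
            seed_pos = int(ct["pos"].iloc[seed_iloc])
            if any(r.start_bp <= seed_pos <= r.end_bp for r in regions):
                continue  # seed already inside a called region
            regions.append(grow_region(ct, int(seed_iloc), run_break=run_break))
        out.extend(truncate_and_merge(regions, ct, max_span=max_span, flank=flank))
    return out


# ----------------------------------------------------------------------
# annotation and output
# ----------------------------------------------------------------------

def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open) or GFF3 (1-based closed).

    Returns a frame with 1-based closed ``chrom``/``start``/``end``/
    ``name`` columns.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end",
                   "score", "strand", "frame", "attributes"],
            dtype={"chrom": str},
        )
        names = df["attributes"].str.extract(r"(?:Name|ID|gene_id)[=\s]\"?([\w.\-]+)")[0]
        out = pd.DataFrame(
            {"chrom": df["chrom"], "start": df["start"].astype(int),
             "end": df["end"].astype(int), "name": names.fillna("unnamed")}
        )
    else:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
        if df.shape[1] < 3:
            raise ValueError(f"{path}: BED needs at least 3 columns")
        out = pd.DataFrame(
            {
                "chrom": df[0],
                "start": df[1].astype(int) + 1,  # BED is 0-based half-open
                "end": df[2].astype(int),
                "name": df[3] if df.shape[1] > 3 else "unnamed",
            }
        )
    return out


def annotate_regions(
    regions: list[Region], genes: pd.DataFrame
) -> list[list[str]]:
    """Genes overlapping each region by at least 1 bp (closed intervals)."""
    gene_chroms = set(genes["chrom"].astype(str))
    region_chroms = {r.chrom for r in regions}
    unmatched = region_chroms - gene_chroms
    if unmatched:
        logger.warning(
            "annotate_regions: no gene intervals on chromosome(s) %s",
            ",".join(sorted(unmatched)),
        )
    out = []
    for reg in regions:
        sel = (
            (genes["chrom"].astype(str) == reg.chrom)
            & (genes["start"] <= reg.end_bp)
            & (genes["end"] >= reg.start_bp)
        )
        out.append(list(genes.loc[sel, "name"]))
    return out


def regions_to_frame(regions: list[Region], genes: pd.DataFrame | None = None) -> pd.DataFrame:
    rows = []
    gene_lists = annotate_regions(regions, genes) if genes is not None else None
    for i, reg in enumerate(regions):
        row = {
            "region": i + 1,
            "chrom": reg.chrom,
            "start_bp": reg.start_bp,
            "end_bp": reg.end_bp,
            "peak_snp": reg.peak_name,
            "peak_fst": round(reg.peak_fst, 4),
            "n_top01": reg.n_top01,
            "n_top5": reg.n_top5,
            "n_snps": len(reg.member_names),
        }
        if gene_lists is not None:
            row["genes"] = ",".join(gene_lists[i])
        rows.append(row)
    return pd.DataFrame(rows)


def write_regions_bed(regions: list[Region], path: str | Path) -> None:
    """Write regions as BED: 0-based half-open converted from 1-based closed."""
    with open(path, "w") as fh:
        for i, reg in enumerate(regions):
            fh.write(
                f"{reg.chrom}\t{reg.start_bp - 1}\t{reg.end_bp}\t"
                f"region_{i + 1}\t{reg.peak_fst:.4f}\n"
            )


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Round-trip helper: BED back to 1-based closed (chrom, start, end)."""
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            out.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    return out
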