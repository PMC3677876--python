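"""End-to-end orchestration: simulate/read -> QC -> statistics -> scan -> DSR.

A single YAML-serialisable :class:`Config` carries every threshold of
the analysis (QC call rate 0.95, MAF 0.05, HWE P 0.01; ranking
quantiles 0.1% / 5%; run-break 4; 3 Mb cap with 1.5 Mb flanks;
smoother k = 20) plus the group comparisons to scan.  Identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dsrcall, ldscan, popstats, popstructure, selscan
from .plinkio import GenotypeDataset, read_prefix, write_prefix
from .qc import QcReport, run_qc
from .simdata import SimulationSpec, default_chrom_layout, simulate

logger = logging.getLogger("ovinescan")


@dataclass
class Config:
    """Run configuration; every analysis threshold lives here."""

    # input: either a PED/MAP prefix or a simulation block
    input_prefix: str | None = None
    simulation: dict | None = None

    # QC thresholds
    call_rate: float = 0.95
    maf: float = 0.05
    hwe_p: float = 0.01

    # scan / DSR thresholds
    top01: float = 0.001
    top5: float = 0.05
    run_break: int = 4
    max_span_bp: int = 3_000_000
    flank_bp: int = 1_500_000
    smoother_k: int = 20

    # group comparisons: list of scans, each a list of breed-label groups
    comparisons: list[list[list[str]]] = field(default_factory=list)

    # optional stages
    ld_breeds: list[str] = field(default_factory=list)
    ld_max_distance: int = 1_000_000
    ld_bin_width: int = 10_000
    fst_permutations: int = 0

    seed: int = 0
    out_dir: str = "ovinescan_out"

    def validate(self, dataset: GenotypeDataset) -> None:
        for name, v in (("call_rate", self.call_rate), ("maf", self.maf),
                        ("hwe_p", self.hwe_p), ("top01", self.top01),
                        ("top5", self.top5)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"threshold {name}={v} outside (0,1)")
        if self.run_break < 1 or self.max_span_bp <= 0 or self.flank_bp <= 0:
            raise ValueError("invalid region-calling constants")
        known = set(dataset.samples["breed"])
        for comparison in self.comparisons:
            for group in comparison:
                unknown = set(group) - known
                if unknown:
                    raise ValueError(
                        f"comparison references unknown breed(s): {sorted(unknown)}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def default_config() -> Config:
    """Config mirroring the five-breed study design on simulated data."""
    return Config(
        simulation={
            "n_markers": 5000,
            "populations": [
                ["Columbia", 19, 0.114],
                ["Polypay", 19, 0.114],
                ["Rambouillet", 16, 0.114],
                ["Suffolk", 18, 0.114],
                ["Targhee", 22, 0.114],
            ],
            "span_bp": 100_000_000,
        },
        comparisons=[
            [["Suffolk"], ["Rambouillet"]],
            [["Rambouillet"], ["Columbia"], ["Polypay"], ["Targhee"]],
        ],
        seed=1,
    )


def _load_dataset(config: Config) -> GenotypeDataset:
    if config.input_prefix:
        return read_prefix(config.input_prefix)
    if config.simulation is None:
        raise ValueError("config needs input_prefix or a simulation block")
    sim = dict(config.simulation)
    populations = [tuple(p) for p in sim["populations"]]
    layout = sim.get("chrom_layout")
    if layout is None:
        layout = default_chrom_layout(
            int(sim.get("n_markers", 5000)),
            span_bp=int(sim.get("span_bp", 100_000_000)),
        )
    else:
        layout = [tuple(c) for c in layout]
    spec = SimulationSpec(
        chrom_layout=layout,
        populations=populations,
        ancestral_maf_range=tuple(sim.get("ancestral_maf_range", (0.05, 0.5))),
        missing_rate=float(sim.get("missing_rate", 0.0)),
        ld_decay_length=sim.get("ld_decay_length"),
        seed=int(config.seed),
    )
    return simulate(spec)


@dataclass
class RunArtifacts:
    dataset: GenotypeDataset
    qc_report: QcReport
    diversity: "object"
    fst_matrix: "object"
    f_statistics: "object"
    tracks: list
    regions: list


def run(config: Config) -> RunArtifacts:
    """Execute every configured stage, writing artifacts to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run: seed=%d out=%s", config.seed, out)

    raw = _load_dataset(config)
    config.validate(raw)
    write_prefix(raw, out / "raw")

    filtered, qc_report = run_qc(
        raw, call_rate=config.call_rate, maf=config.maf, hwe_p=config.hwe_p
    )
    qc_report.write_tsv(out / "qc_report.tsv")
    write_prefix(filtered, out / "filtered")
    logger.info(
        "qc: retained %d markers (%d autosomal + %d X) of %d",
        qc_report.n_retained_total, qc_report.n_retained_autosomal,
        qc_report.n_retained_x, qc_report.n_input,
    )

    diversity = popstats.breed_diversity_report(filtered)
    diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
    maf_table = popstats.maf_bin_counts(filtered)
    maf_table.to_csv(out / "maf_spectrum.tsv", sep="\t")
    if len(filtered.breeds) >= 2:
        chi2, p = popstats.maf_spectrum_chisq(maf_table)
        (out / "maf_chisq.tsv").write_text(f"chi2\tp\n{chi2:.6g}\t{p:.6g}\n")

    rng = np.random.Generator(np.random.PCG64(config.seed + 1))
    fstat = None
    fst_matrix = None
    if len(filtered.breeds) >= 2:
        fstat = popstats.global_f_statistics(filtered)
        (out / "f_statistics.tsv").write_text(
            "f_st\tf_it\tf_is\n"
            f"{fstat.f_st:.6f}\t{fstat.f_it:.6f}\t{fstat.f_is:.6f}\n"
        )
        fst_matrix, pmat = popstats.pairwise_fst_matrix(
            filtered, n_perm=config.fst_permutations, rng=rng
        )
        fst_matrix.to_csv(out / "pairwise_fst.tsv", sep="\t")
        if pmat is not None:
            pmat.to_csv(out / "pairwise_fst_pvalues.tsv", sep="\t")

    for breed in config.ld_breeds:
        curve = ldscan.decay_curve(
            filtered, breed=breed,
            max_distance=config.ld_max_distance, bin_width=config.ld_bin_width,
        )
        curve.write_tsv(out / f"ld_decay_{breed}.tsv")

    aut = filtered.is_autosomal()
    asd = popstructure.asd_matrix(filtered, markers=aut)
    asd.to_csv(out / "asd_matrix.tsv", sep="\t")
    if filtered.n_samples >= 3:
        tree = popstructure.neighbor_joining(asd)
        popstructure.write_newick(tree, out / "nj_tree.nwk")
    if filtered.n_samples > 2:
        mds = popstructure.mds_classical(asd, k=2)
        mds.to_csv(out / "mds.tsv", sep="\t")

    tracks = []
    regions_all = []
    for ci, comparison in enumerate(config.comparisons, start=1):
        track = selscan.fst_track(filtered, comparison, smoother_k=config.smoother_k)
        regions = dsrcall.call_regions(
            track, top01=config.top01, top5=config.top5,
            run_break=config.run_break, max_span=config.max_span_bp,
            flank=config.flank_bp,
        )
        label = "_vs_".join("+".join(g) for g in comparison)
        track.to_csv(out / f"track_{ci}_{label}.tsv", sep="\t", index=False)
        dsrcall.regions_to_frame(regions).to_csv(
            out / f"regions_{ci}_{label}.tsv", sep="\t", index=False
        )
        dsrcall.write_regions_bed(regions, out / f"regions_{ci}_{label}.bed")
        logger.info("scan %s: %d regions called", label, len(regions))
        tracks.append(track)
        regions_all.append(regions)

    return RunArtifacts(
        dataset=filtered,
        qc_report=qc_report,
        diversity=diversity,
        fst_matrix=fst_matrix,
        f_statistics=fstat,
        tracks=tracks,
        regions=regions_all,
    )
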