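"""Top-level experiment driver: simulate -> map -> scan -> test.

:class:`RunConfig` collects every stage parameter, with defaults equal to
the study's stated analysis settings where one exists (100-kb ancestry
windows, minimum count 10, 1 fixed difference / 1000 sites IBD rule,
501-SNP Dxy windows, minimum coverage 2, 101-SNP HKA windows, 11 My
calibration).  :func:`run_pipeline` chains the stages into a run directory
with a manifest (config echo, seed, version, per-file checksums); a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import FlcdError
from . import ancestry_mapping as am
from . import clock_dating as cd
from . import divergence_scan as ds
from . import haplotype_popgen as hp
from . import hka_scan as hka
from . import io as fio
from . import synthetic_data as sd


@dataclass
class RunConfig:
    """All stage parameters of a simulated mapping experiment."""

    seed: int = 1
    chrom: str = "X"
    chrom_length: int = 10_000_000
    snp_density: float = 0.02
    fixed_diff_fraction: float = 0.10
    outgroup_divergent_fraction: float = 0.65
    causal_position: int | None = None        # default: centre of the middle window
    core_peak_divergence: float = 0.10
    core_decay_bp: float = 2000.0
    # cross design
    n_backcross_generations: int = 7
    nn_generations: int = 12
    pool_size: int = 30
    n_founders: int = 12
    recombination_rate: float = 0.02          # crossovers / Mb / female meiosis
    # pooled sequencing (per-line mean depths follow the sequenced genomes)
    depth_dark: float = 30.0
    depth_light: float = 17.0
    depth_bc7: float = 44.0
    depth_nn: float = 80.0
    depth_outgroup: float = 21.0
    error_rate: float = 0.001
    # ancestry mapping
    window_width: int = 100_000
    min_count: int = 10
    ibd_threshold: float = 1e-3
    band: float = 0.05
    # divergence scan
    min_coverage: int = 2
    dxy_half_width: int = 250
    peak_multiplier: float = 5.0
    # HKA scan
    hka_half_width: int = 50
    # balanced haplotype locus
    locus_length: int = 3000
    core_interval: tuple[int, int] = (1250, 1750)
    n_per_haplogroup: int = 18
    between_divergence: float = 0.07
    within_diversity: float = 0.005
    outgroup_divergence: float = 0.05
    flank_decay: float = 500.0
    outgroup_gap_length: int = 44
    ils_window_bp: int = 500
    ils_step_bp: int = 100
    # clock dating
    calibration_age: float = 11.0
    n_boot: int = 1000

    def __post_init__(self):
        if self.causal_position is None:
            mid_window = (self.chrom_length // 2 - 1) // self.window_width
            self.causal_position = mid_window * self.window_width + self.window_width // 2

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FlcdError(f"unknown config keys: {sorted(unknown)}")
        if "core_interval" in data:
            data["core_interval"] = tuple(data["core_interval"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["core_interval"] = list(d["core_interval"])
        return d


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage generator derived from the run seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


# ------------------------------------------------------------ simulate -----

def simulate_inputs(cfg: RunConfig, seed: int | None = None):
    """Generate parents, pool truths, pooled counts, and the haplotype locus."""
    seed = cfg.seed if seed is None else seed
    core = sd.BalancedCoreConfig(
        center=cfg.causal_position,
        peak_divergence=cfg.core_peak_divergence,
        decay_bp=cfg.core_decay_bp,
    )
    parents = sd.simulate_parental_genomes(
        cfg.chrom_length,
        cfg.snp_density,
        cfg.fixed_diff_fraction,
        stage_rng(seed, 0),
        outgroup_divergent_fraction=cfg.outgroup_divergent_fraction,
        core=core,
        causal_position=cfg.causal_position,
        chrom=cfg.chrom,
    )
    bc7_design = sd.CrossDesign(
        causal_position=cfg.causal_position,
        n_backcross_generations=cfg.n_backcross_generations,
        pool_size=cfg.pool_size,
        recombination_rate=cfg.recombination_rate,
    )
    nn_design = dataclasses.replace(
        bc7_design,
        n_backcross_generations=cfg.nn_generations,
        homozygous_line=True,
        n_founders=cfg.n_founders,
    )
    bc7 = sd.simulate_backcross(parents, bc7_design, stage_rng(seed, 1))
    nn = sd.simulate_backcross(parents, nn_design, stage_rng(seed, 2))
    line = sd.line_truth_fractions(parents)
    counts = sd.simulate_experiment_counts(
        parents,
        pools={
            "dark": (line["dark"], cfg.depth_dark),
            "light": (line["light"], cfg.depth_light),
            "bc7": (bc7, cfg.depth_bc7),
            "nn": (nn, cfg.depth_nn),
            "outgroup": (line["outgroup"], cfg.depth_outgroup),
        },
        error_rate=cfg.error_rate,
        seed=stage_rng(seed, 3),
    )
    locus_cfg = sd.BalancedLocusConfig(
        locus_length=cfg.locus_length,
        core_interval=cfg.core_interval,
        n_per_haplogroup=cfg.n_per_haplogroup,
        between_divergence=cfg.between_divergence,
        within_diversity=cfg.within_diversity,
        outgroup_divergence=cfg.outgroup_divergence,
        flank_decay=cfg.flank_decay,
        outgroup_gap_length=cfg.outgroup_gap_length,
    )
    haplotypes = sd.simulate_balanced_locus(locus_cfg, stage_rng(seed, 4))
    return parents, bc7, nn, counts, haplotypes


# ------------------------------------------------------- map ancestry ------

def map_ancestry(counts: fio.PooledCounts, cfg: RunConfig, chrom_length=None):
    """Diagnostic SNPs -> per-SNP ancestry -> windows -> IBD -> candidates."""
    chrom_length = chrom_length or cfg.chrom_length
    diag = am.call_diagnostic_snps(counts, min_count=cfg.min_count)
    anc_bc7 = am.snp_ancestry(counts, "bc7", diag)
    anc_nn = am.snp_ancestry(counts, "nn", diag)
    w_bc7 = am.window_average(anc_bc7, diag.positions, cfg.window_width, chrom_length)
    w_nn = am.window_average(anc_nn, diag.positions, cfg.window_width, chrom_length)
    fixed = am.parental_fixed_diff_windows(
        counts, width=cfg.window_width, chrom_length=chrom_length,
        min_coverage=cfg.min_coverage,
    )
    excluded = am.ibd_filter(
        fixed["fixed_diffs"].to_numpy(), cfg.window_width, cfg.ibd_threshold
    )
    windows, intervals = am.candidate_windows(
        w_bc7["mean"].to_numpy(),
        w_nn["mean"].to_numpy(),
        excluded,
        w_bc7["start"].to_numpy(),
        cfg.window_width,
        band=cfg.band,
    )
    persnp = {
        "pos": diag.positions,
        "bc7": anc_bc7,
        "nn": anc_nn,
    }
    return diag, persnp, windows, intervals


def top_candidate_window(windows) -> tuple[int, int] | None:
    """(start, end) of the best-ranked candidate window, if any."""
    cand = windows[windows["candidate"]]
    if cand.empty:
        return None
    best = cand.sort_values("rank").iloc[0]
    return int(best["start"]), int(best["end"])


# ------------------------------------------------------------ pipeline -----

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Execute every stage in order and write a reproducible run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "simulate"
    try:
        parents, bc7, nn, counts, haplotypes = simulate_inputs(cfg)
        hdr = {"seed": cfg.seed, "version": __version__}
        fio.write_sync(counts, outdir / "counts.sync",
                       fio.format_header(hdr))
        haplotypes.to_fasta(outdir / "haplotypes.fasta")
        fio.write_bed(
            [(i, int(np.floor(s)) + 1, int(np.floor(e))) for i, s, e in bc7.truth_intervals()],
            outdir / "truth_bc7.bed", chrom=cfg.chrom,
            header_comments=["dark-ancestry intervals per carrier copy (copy, start, end)"],
        )
        written += [outdir / "counts.sync", outdir / "haplotypes.fasta",
                    outdir / "truth_bc7.bed"]

        stage = "map-ancestry"
        diag, persnp, windows, intervals = map_ancestry(counts, cfg)
        import pandas as pd

        fio.write_tsv(pd.DataFrame(persnp), outdir / "ancestry_snps.tsv",
                      {**hdr, "min_count": cfg.min_count})
        fio.write_tsv(windows, outdir / "ancestry_windows.tsv",
                      {**hdr, "window_width": cfg.window_width,
                       "ibd_threshold": cfg.ibd_threshold, "band": cfg.band})
        fio.write_bed(intervals, outdir / "candidates.bed", chrom=cfg.chrom,
                      header_comments=[f"candidate windows |score-0.75|<={cfg.band}"])
        written += [outdir / "ancestry_snps.tsv", outdir / "ancestry_windows.tsv",
                    outdir / "candidates.bed"]

        stage = "scan-dxy"
        p_dark = ds.allele_frequencies(counts, "dark", cfg.min_coverage)
        p_light = ds.allele_frequencies(counts, "light", cfg.min_coverage)
        dxy = ds.snp_dxy(p_dark, p_light)
        smooth = ds.sliding_dxy(dxy, counts.positions, cfg.dxy_half_width)
        peaks = ds.peak_interval(
            smooth["smoothed"].to_numpy(), smooth["pos"].to_numpy(),
            cfg.peak_multiplier,
        )
        fio.write_tsv(smooth, outdir / "dxy.tsv",
                      {**hdr, "half_width": cfg.dxy_half_width,
                       "min_coverage": cfg.min_coverage})
        fio.write_bed(peaks, outdir / "dxy_peaks.bed", chrom=cfg.chrom,
                      header_comments=[f"smoothed dxy > {cfg.peak_multiplier} x median"])
        written += [outdir / "dxy.tsv", outdir / "dxy_peaks.bed"]

        stage = "scan-hka"
        p_out = ds.allele_frequencies(counts, "outgroup", cfg.min_coverage)
        codes = hka.classify_sites(p_dark, p_light, p_out)
        hka_tab = hka.window_hka(codes, counts.positions, cfg.hka_half_width)
        fio.write_tsv(hka_tab, outdir / "hka.tsv",
                      {**hdr, "half_width": cfg.hka_half_width})
        written += [outdir / "hka.tsv"]

        stage = "haplo-stats"
        ingroup = haplotypes.ingroup_ids
        dm = hp.pairwise_distances(haplotypes, ingroup)
        tree = hp.nj_tree(dm)
        (outdir / "haplotypes.nwk").write_text(str(tree))
        assign = hp.assign_haplogroups(tree, ingroup)
        fst = hp.per_snp_fst(haplotypes, assign)
        n_seg, n_fixed, _, _ = hp.site_counts(haplotypes, assign)
        ils = hp.ils_scan(haplotypes, assign, haplotypes.outgroup_id,
                          cfg.ils_window_bp, cfg.ils_step_bp)
        fio.write_tsv(
            pd.DataFrame({"column": np.arange(haplotypes.length), "fst": fst}),
            outdir / "fst.tsv", hdr,
        )
        fio.write_bed([(s + 1, e) for s, e in ils], outdir / "ils.bed",
                      chrom="locus",
                      header_comments=["windows with dxy(A,B) > min dxy(group, outgroup)"])
        written += [outdir / "haplotypes.nwk", outdir / "fst.tsv", outdir / "ils.bed"]

        stage = "clock-date"
        a_ids = assign.members("A")
        b_ids = assign.members("B")
        cal = cd.ClockCalibration(
            group1=tuple(ingroup), group2=(haplotypes.outgroup_id,),
            age_mya=cfg.calibration_age,
        )
        est = cd.date_split(haplotypes, a_ids, b_ids, cal,
                            n_boot=cfg.n_boot, seed=cfg.seed)
        fio.write_tsv(
            pd.DataFrame([{
                "split": "haplogroup_A_vs_B", "age_mya": est.age_mya,
                "ci_low": est.ci_low, "ci_high": est.ci_high, "sd": est.sd,
                "n_boot": est.n_boot, "seed": cfg.seed,
            }]),
            outdir / "dates.tsv", {**hdr, "calibration_age": cfg.calibration_age},
        )
        written += [outdir / "dates.tsv"]

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "summary": {
                "n_diagnostic_snps": int(diag.n),
                "n_candidate_intervals": len(intervals),
                "top_candidate_window": top_candidate_window(windows),
                "n_dxy_peaks": len(peaks),
                "locus_segregating": n_seg,
                "locus_fixed_differences": n_fixed,
                "n_ils_intervals": len(ils),
                "haplogroup_split_age_mya": est.age_mya,
            },
            "checksums": {p.name: _sha256(p) for p in written},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:  # noqa: BLE001 - abort with the failing stage's name
        raise FlcdError(f"stage {stage!r} failed: {exc}") from exc
    return outdir


# ------------------------------------------------- replicate experiments ---

def replicate_cross_summaries(
    cfg: RunConfig,
    n_replicates: int,
    seed: int,
    error_rate: float | None = None,
    depth_bc7: float | None = None,
    depth_nn: float | None = None,
):
    """Replicate the crossing design and summarise the causal window.

    The parental lines are simulated once (one pair of inbred strains, as in
    the study); each replicate redraws the backcross pools and their pooled
    sequencing.  Returns one row per replicate with the pools' ancestry at
    the causal SNP itself, their mean over diagnostic SNPs in the 100-kb
    window containing the causal position, and the combined window score.
    """
    import pandas as pd

    error_rate = cfg.error_rate if error_rate is None else error_rate
    depth_bc7 = cfg.depth_bc7 if depth_bc7 is None else depth_bc7
    depth_nn = cfg.depth_nn if depth_nn is None else depth_nn
    core = sd.BalancedCoreConfig(cfg.causal_position, cfg.core_peak_divergence,
                                 cfg.core_decay_bp)
    parents = sd.simulate_parental_genomes(
        cfg.chrom_length, cfg.snp_density, cfg.fixed_diff_fraction,
        stage_rng(seed, 0),
        outgroup_divergent_fraction=cfg.outgroup_divergent_fraction,
        core=core, causal_position=cfg.causal_position, chrom=cfg.chrom,
    )
    bc7_design = sd.CrossDesign(
        causal_position=cfg.causal_position,
        n_backcross_generations=cfg.n_backcross_generations,
        pool_size=cfg.pool_size,
        recombination_rate=cfg.recombination_rate,
    )
    nn_design = dataclasses.replace(
        bc7_design, n_backcross_generations=cfg.nn_generations,
        homozygous_line=True, n_founders=cfg.n_founders,
    )
    line = sd.line_truth_fractions(parents)
    causal_window = (cfg.causal_position - 1) // cfg.window_width

    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1000 + rep]))
        bc7 = sd.simulate_backcross(parents, bc7_design, rng)
        nn = sd.simulate_backcross(parents, nn_design, rng)
        counts = sd.simulate_experiment_counts(
            parents,
            pools={
                "dark": (line["dark"], cfg.depth_dark),
                "light": (line["light"], cfg.depth_light),
                "bc7": (bc7, depth_bc7),
                "nn": (nn, depth_nn),
                "outgroup": (line["outgroup"], cfg.depth_outgroup),
            },
            error_rate=error_rate,
            seed=rng,
        )
        diag = am.call_diagnostic_snps(counts, min_count=cfg.min_count)
        anc_bc7 = am.snp_ancestry(counts, "bc7", diag)
        anc_nn = am.snp_ancestry(counts, "nn", diag)
        in_window = (diag.positions - 1) // cfg.window_width == causal_window
        at_causal = diag.positions == cfg.causal_position
        row = {
            "bc7_causal_snp": float(anc_bc7[at_causal][0]) if at_causal.any() else np.nan,
            "nn_causal_snp": float(anc_nn[at_causal][0]) if at_causal.any() else np.nan,
            "bc7_window": float(np.nanmean(anc_bc7[in_window])),
            "nn_window": float(np.nanmean(anc_nn[in_window])),
        }
        row["score"] = (row["bc7_window"] + row["nn_window"]) / 2.0
        rows.append(row)
    return pd.DataFrame(rows)
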