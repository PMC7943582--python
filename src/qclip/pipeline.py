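"""End-to-end orchestration of the CLIP and TRAP analyses.

``run_clip_analysis`` composes: simulate (or accept) inputs -> window the
genome -> count reads -> fit the ZTNB null -> score and merge peaks ->
filter -> TMM -> NB GLM enrichment against IgG and Input -> intersect into
high-confidence calls -> assign annotation features -> characterize bound
3'UTRs against matched-length controls -> metagene profiles.

``run_trap_analysis`` composes: filter -> TMM -> NB GLM contrasts (knockout
vs wild-type TRAP; TRAP vs Input) -> astrocyte-marker quality gate ->
CLIP-target abundance shift -> maturation-set overlap tests.

All stages are deterministic given the config seed; every report echoes the
thresholds used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_model import (
    FEATURE_THREE_UTR,
    TranscriptomeIndex,
    assign_peak_feature,
    feature_fraction_summary,
    transcript_sequence,
)
from .count_model import (
    astrocyte_enrichment_check,
    call_high_confidence,
    estimate_dispersion,
    filter_min_count,
    nb_glm_lrt,
    tmm_factors,
)
from .metagene import metagene_profiles
from .peak_calling import (
    bin_genome,
    count_reads_in_windows,
    fit_ztnb,
    merge_significant_windows,
    peaks_to_bed,
    score_windows,
)
from .set_stats import (
    clip_target_shift,
    derive_de_sets,
    maturation_shift,
)
from .synthetic_data import (
    SimConfig,
    SyntheticGenome,
    simulate_clip_reads,
    simulate_genome,
    simulate_maturation_sets,
    simulate_trap_counts,
    write_bed,
    write_genome_files,
)
from .utr_features import (
    ConservationTrack,
    MotifConfig,
    UTRRecord,
    conservation_flank_compare,
    find_qres,
    relative_position,
    scan_motif,
    select_matched_controls,
    utr_summary_table,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Run-level thresholds (defaults are the study's printed values where
    it prints one) plus the synthetic-data configuration."""

    window_width: int = 50
    peak_fdr: float = 0.05
    hc_fold: float = 2.0
    hc_fdr: float = 0.05          # Methods-style 0.1 available as config
    min_count: int = 5
    min_samples: int = 2
    qre_max_gap: int = 20
    flank: int = 200
    metagene_half_width: int = 500
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    outdir: str = "qclip_out"
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**obj.pop("sim", {}))
        return cls(sim=sim, **obj)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def motif_config(self) -> MotifConfig:
        return MotifConfig(max_gap=self.qre_max_gap)


@dataclass
class RunReport:
    stage_counts: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    results: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, set):
                return sorted(o)
            return str(o)

        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, default=default)
        )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def simulate(config: PipelineConfig) -> tuple[SyntheticGenome, dict, dict, RunReport]:
    """Generate the synthetic study and write all its files."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config.sim)
    paths = write_genome_files(genome, outdir)
    beds, roles = simulate_clip_reads(genome, config.sim, width=config.window_width)
    for name, bed in beds.items():
        p = outdir / f"reads_{name}.bed"
        write_bed(bed, p)
        paths[name] = p
    report = RunReport(
        stage_counts={
            "transcripts": len(genome.transcripts),
            "planted_sites": len(genome.truth.planted_qbm_sites),
            **{f"reads_{k}": len(v) for k, v in beds.items()},
        },
        thresholds=config.to_dict(),
        outputs=[str(p) for p in paths.values()],
    )
    report.to_json(outdir / "simulate_report.json")
    return genome, beds, roles, report


# ---------------------------------------------------------------------------
# CLIP analysis
# ---------------------------------------------------------------------------

def _peak_sample_counts(
    scored: pd.DataFrame, peaks: pd.DataFrame, samples: list[str]
) -> pd.DataFrame:
    """Per-sample counts per merged peak = sum of member-window counts."""
    rows = {}
    grouped = {
        key: sub for key, sub in scored.groupby(["chrom", "strand"], sort=False)
    }
    for i, pk in peaks.iterrows():
        sub = grouped.get((pk["chrom"], pk["strand"]))
        inside = sub[(sub["start"] >= pk["start"]) & (sub["end"] <= pk["end"])]
        rows[f"peak_{i}"] = inside[samples].sum()
    return pd.DataFrame(rows).T[samples]


def _peak_gene(peaks: pd.DataFrame, index: TranscriptomeIndex) -> list[str | None]:
    genes = []
    for pk in peaks.itertuples(index=False):
        cands = [
            t for t in index.query(pk.chrom, pk.start, pk.end)
            if t.strand == pk.strand
        ]
        if not cands:
            genes.append(None)
            continue
        # prefer a transcript whose 3'UTR the peak touches
        def key(t):
            in_utr = any(s < pk.end and pk.start < e for s, e in t.three_utr)
            return (not in_utr, t.transcript_id)
        cands.sort(key=key)
        genes.append(cands[0].gene_id)
    return genes


def _utr_site_from_genomic(t, genomic_pos: int) -> int | None:
    """Map a genomic position into a transcript-sense 3'UTR coordinate."""
    offset = 0
    ivs = t.three_utr if t.strand == "+" else list(reversed(t.three_utr))
    for s, e in ivs:
        if s <= genomic_pos < e:
            return offset + (genomic_pos - s if t.strand == "+" else e - 1 - genomic_pos)
        offset += e - s
    return None


def _utr_genomic_from_site(t, site: int) -> int:
    ivs = t.three_utr if t.strand == "+" else list(reversed(t.three_utr))
    off = site
    for s, e in ivs:
        if off < e - s:
            return s + off if t.strand == "+" else e - 1 - off
        off -= e - s
    s, e = ivs[-1]
    return e - 1 if t.strand == "+" else s


def run_clip_analysis(
    config: PipelineConfig,
    genome: SyntheticGenome | None = None,
    beds: dict[str, pd.DataFrame] | None = None,
    roles: dict[str, str] | None = None,
) -> RunReport:
    """Full CLIP pipeline on synthetic (default) or supplied inputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if genome is None:
        genome, beds, roles, _ = simulate(config)
    index = genome.index()
    report = RunReport(thresholds=config.to_dict())

    windows = bin_genome(genome.build, config.window_width)
    counts = count_reads_in_windows(beds, windows, genome.build,
                                    width=config.window_width)
    clip_samples = [s for s, r in roles.items() if r == "clip"]
    igg_samples = [s for s, r in roles.items() if r == "igg"]
    input_samples = [s for s, r in roles.items() if r == "input"]
    merged = counts[clip_samples].sum(axis=1)
    fit = fit_ztnb(merged.to_numpy())
    scored = score_windows(counts, clip_samples, fit, fdr=config.peak_fdr)
    peaks = merge_significant_windows(scored)
    report.stage_counts.update({
        "windows": len(windows),
        "windows_tested": int((scored["merged_count"] > 0).sum()),
        "windows_significant": int(scored["significant"].sum()),
        "peaks": len(peaks),
        "ztnb_mu": fit.mu, "ztnb_alpha": fit.alpha,
    })
    _write_tsv(peaks_to_bed(peaks), outdir / "peaks.bed")
    report.outputs.append(str(outdir / "peaks.bed"))

    if peaks.empty:
        report.warnings.append("no significant windows; empty peak set")
        report.results["high_confidence_peaks"] = 0
        report.results["high_confidence_genes"] = []
        report.to_json(outdir / "clip_report.json")
        return report

    # --- dual-background enrichment on peak counts ---
    sample_names = clip_samples + igg_samples + input_samples
    peak_counts = _peak_sample_counts(scored, peaks, sample_names)
    filtered = filter_min_count(peak_counts, config.min_count, config.min_samples)
    groups = pd.Series(
        [roles[s] for s in filtered.columns], index=filtered.columns
    )
    # Offsets use the full per-library read totals, not peak-restricted
    # column sums, and no composition (TMM) correction: the tested feature
    # set IS the enriched set, so composition normalization would absorb
    # the enrichment being measured.
    lib_sizes = pd.Series({s: float(len(beds[s])) for s in filtered.columns})
    disp = estimate_dispersion(filtered, groups, lib_sizes=lib_sizes)
    de_igg = nb_glm_lrt(filtered, groups, ("clip", "igg"), None, disp,
                        lib_sizes=lib_sizes)
    de_input = nb_glm_lrt(filtered, groups, ("clip", "input"), None, disp,
                          lib_sizes=lib_sizes)
    hc = call_high_confidence(de_igg, de_input, config.hc_fold, config.hc_fdr)
    peak_ids = {pid: int(pid.split("_")[1]) for pid in hc.index}
    hc_peaks = peaks.loc[[peak_ids[p] for p in hc.index[hc["pass"]]]]
    genes_all = _peak_gene(peaks, index)
    hc_genes = sorted({
        genes_all[peak_ids[p]] for p in hc.index[hc["pass"]]
        if genes_all[peak_ids[p]] is not None
    })
    _write_tsv(de_igg, outdir / "enrichment_vs_igg.tsv", index=True)
    _write_tsv(de_input, outdir / "enrichment_vs_input.tsv", index=True)
    _write_tsv(hc, outdir / "high_confidence.tsv", index=True)
    report.stage_counts.update({
        "peaks_count_filtered": len(filtered),
        "high_confidence_peaks": int(hc["pass"].sum()),
        "high_confidence_genes": len(hc_genes),
    })
    report.results["high_confidence_genes"] = hc_genes

    # --- feature assignment over all called peaks ---
    labels = [
        assign_peak_feature((pk.start, pk.end), pk.chrom, pk.strand, index)
        for pk in peaks.itertuples(index=False)
    ]
    feat = feature_fraction_summary(labels)
    _write_tsv(feat, outdir / "peak_features.tsv")
    report.results["feature_fractions"] = dict(
        zip(feat["label"], feat["percent"])
    )

    # --- 3'UTR characterization of high-confidence targets ---
    mcfg = config.motif_config()
    hc_rows = hc[hc["pass"]]
    target_records: list[UTRRecord] = []
    seen_tx = set()
    for pid in hc_rows.index:
        pk = peaks.loc[peak_ids[pid]]
        mid = int((pk["start"] + pk["end"]) // 2)
        cands = [
            t for t in index.query(pk["chrom"], pk["start"], pk["end"])
            if t.strand == pk["strand"] and t.three_utr
        ]
        for t in cands:
            site = _utr_site_from_genomic(t, mid)
            if site is None or t.transcript_id in seen_tx:
                continue
            seen_tx.add(t.transcript_id)
            target_records.append(UTRRecord(
                transcript_id=t.transcript_id,
                utr_sequence=transcript_sequence(
                    t, genome.sequences[t.chrom], "three_utr"
                ),
                chrom=t.chrom, strand=t.strand, intervals=list(t.three_utr),
                site=site, gene_id=t.gene_id,
            ))
            break

    results_json: dict = {}
    if target_records:
        pool = []
        target_tx = {r.transcript_id for r in target_records}
        expr = _transcript_input_counts(counts, input_samples, index)
        for t in index.coding_transcripts():
            if t.transcript_id in target_tx or not t.three_utr:
                continue
            pool.append(UTRRecord(
                transcript_id=t.transcript_id,
                utr_sequence=transcript_sequence(
                    t, genome.sequences[t.chrom], "three_utr"
                ),
                chrom=t.chrom, strand=t.strand, intervals=list(t.three_utr),
                gene_id=t.gene_id,
            ))
        try:
            controls = select_matched_controls(
                target_records, pool, min_len=50, expression=expr,
                seed=config.seed,
            )
        except Exception as exc:  # pool too small at tiny scales
            report.warnings.append(f"control selection failed: {exc}")
            controls = []

        summary = utr_summary_table(target_records, mcfg)
        summary["group"] = "target"
        if controls:
            csum = utr_summary_table(controls, mcfg)
            csum["group"] = "control"
            summary = pd.concat([summary, csum], ignore_index=True)
        # relative position of each target site between stop codon and PAS
        rel = []
        for r in target_records:
            t = index.by_id[r.transcript_id]
            pas_sites = scan_motif(r.utr_sequence, mcfg.pas_pattern)
            if not pas_sites or r.site is None:
                rel.append(np.nan)
                continue
            pas = min(pas_sites, key=lambda x: abs(x - r.site))
            stop_g = _utr_genomic_from_site(t, 0)
            pas_g = _utr_genomic_from_site(t, pas)
            site_g = _utr_genomic_from_site(t, r.site)
            if pas_g == stop_g:
                rel.append(np.nan)
                continue
            rp = relative_position(site_g, pas_g, stop_g, t.strand)
            rel.append(rp.percent if rp.valid else np.nan)
        summary.loc[summary["group"] == "target", "relative_percent"] = rel
        _write_tsv(summary, outdir / "utr_features.tsv")
        report.outputs.append(str(outdir / "utr_features.tsv"))

        if controls and len(genome.conservation):
            track = ConservationTrack(genome.conservation)
            tsites = pd.DataFrame({
                "chrom": [r.chrom for r in target_records],
                "pos": [_utr_genomic_from_site(index.by_id[r.transcript_id], r.site)
                        for r in target_records],
                "strand": [r.strand for r in target_records],
            })
            csites = pd.DataFrame({
                "chrom": [r.chrom for r in controls],
                "pos": [_utr_genomic_from_site(index.by_id[r.transcript_id], r.site)
                        for r in controls],
                "strand": [r.strand for r in controls],
            })
            cons = conservation_flank_compare(tsites, csites, track,
                                              flank=config.flank)
            results_json["conservation"] = {
                "t": cons["t"], "p": cons["p"],
                "target_mean": float(np.mean(cons["target_site_means"])),
                "control_mean": float(np.mean(cons["control_site_means"])),
            }

        # --- metagene at planted/observed QBM anchors (QRE full sites) ---
        anchor_rows = []
        for r in target_records:
            t = index.by_id[r.transcript_id]
            for q in find_qres(r.utr_sequence, mcfg)[:1]:
                anchor_rows.append({
                    "chrom": r.chrom,
                    "pos": _utr_genomic_from_site(t, q.full_start + 3),
                    "strand": r.strand, "kind": "QBM",
                })
        if len(anchor_rows) >= 2:
            anchors = pd.DataFrame(anchor_rows)
            prof = metagene_profiles(
                beds, roles, anchors, genome.build,
                half_width=config.metagene_half_width,
                n_boot=config.n_boot, level=config.ci_level, seed=config.seed,
            )
            _write_tsv(prof, outdir / "metagene_qbm.tsv")
            report.outputs.append(str(outdir / "metagene_qbm.tsv"))

    report.results.update(results_json)
    # recovery against the generator's truth
    truth = genome.truth
    if truth.target_genes:
        tp = len(set(hc_genes) & truth.target_genes)
        report.results["target_gene_sensitivity"] = (
            tp / len(truth.target_genes)
        )
        report.results["target_gene_precision"] = (
            tp / len(hc_genes) if hc_genes else float("nan")
        )
    report.to_json(outdir / "clip_report.json")
    report.outputs.append(str(outdir / "clip_report.json"))
    return report


def _transcript_input_counts(
    counts: pd.DataFrame, input_samples: list[str], index: TranscriptomeIndex
) -> pd.Series:
    """Input reads per transcript (sum of same-strand window counts over the
    transcript span); the expression filter for control selection."""
    vals = {}
    by_key = {
        key: sub for key, sub in counts.groupby(["chrom", "strand"], sort=False)
    }
    for t in index.transcripts:
        sub = by_key.get((t.chrom, t.strand))
        if sub is None:
            vals[t.transcript_id] = 0.0
            continue
        inside = sub[(sub["end"] > t.start) & (sub["start"] < t.end)]
        vals[t.transcript_id] = float(inside[input_samples].sum().sum())
    return pd.Series(vals)


# ---------------------------------------------------------------------------
# TRAP analysis
# ---------------------------------------------------------------------------

def run_trap_analysis(
    config: PipelineConfig,
    genome: SyntheticGenome | None = None,
    counts: pd.DataFrame | None = None,
    groups: pd.Series | None = None,
    clip_targets: set[str] | None = None,
) -> RunReport:
    """TRAP knockout differential expression and downstream set statistics."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if genome is None and (counts is None or groups is None):
        genome = simulate_genome(config.sim)
    if counts is None:
        counts, groups = simulate_trap_counts(genome, config.sim)
    for g in ("WT-TRAP", "KO-TRAP", "WT-Input", "KO-Input"):
        if g not in set(groups):
            raise ValueError(f"missing sample group: {g}")
    report = RunReport(thresholds=config.to_dict())

    filtered = filter_min_count(counts, config.min_count, config.min_samples)
    norm = tmm_factors(filtered)
    disp = estimate_dispersion(filtered, groups, norm_factors=norm)
    de_ko = nb_glm_lrt(filtered, groups, ("KO-TRAP", "WT-TRAP"), norm, disp)
    frac = groups.map(lambda g: "TRAP" if g.endswith("TRAP") else "Input")
    disp_frac = estimate_dispersion(filtered, frac, norm_factors=norm)
    de_enrich = nb_glm_lrt(filtered, frac, ("TRAP", "Input"), norm, disp_frac)
    _write_tsv(de_ko, outdir / "de_ko_vs_wt.tsv", index=True)
    _write_tsv(de_enrich, outdir / "de_trap_vs_input.tsv", index=True)
    report.stage_counts.update({
        "genes_tested": len(filtered),
        "ko_de_fdr05": int((de_ko["FDR"] < 0.05).sum()),
    })

    truth = genome.truth if genome is not None else None
    if truth is not None and truth.marker_genes:
        marker = astrocyte_enrichment_check(
            de_enrich, truth.marker_genes, truth.neg_marker_genes
        )
        report.results["marker_check"] = marker

    targets = clip_targets if clip_targets is not None else (
        truth.target_genes if truth else set()
    )
    if targets:
        shift = clip_target_shift(de_ko, targets)
        report.results["target_shift"] = {
            "mean_log2fc_targets": shift.mean_log2fc_targets,
            "mean_percent_change": shift.mean_percent_change,
            "t": shift.t, "p": shift.p,
            "n_targets": shift.n_targets,
        }
        ecdf = pd.DataFrame({
            "group": ["target"] * shift.n_targets
            + ["background"] * shift.n_background,
            "log2FC": np.concatenate([shift.ecdf_targets,
                                      shift.ecdf_background]),
        })
        _write_tsv(ecdf, outdir / "target_shift_ecdf.tsv")

    # maturation analysis from simulated P7/P32-style matrices
    if genome is not None:
        mat = simulate_maturation_sets(genome, config.sim)
        mat_filt = filter_min_count(mat["counts"], config.min_count,
                                    config.min_samples)
        mat_norm = tmm_factors(mat_filt)
        mat_disp = estimate_dispersion(mat_filt, mat["groups"],
                                       norm_factors=mat_norm)
        p7_set, p32_set = derive_de_sets(
            mat_filt, mat["groups"], ("P7", "P32"),
            p_threshold=0.05, dispersion=mat_disp, norm_factors=mat_norm,
        )
        sig = de_ko[de_ko["FDR"] < 0.05]
        ko_up = set(sig.index[sig["log2FC"] > 0])
        ko_down = set(sig.index[sig["log2FC"] < 0])
        universe = set(filtered.index) | p7_set | p32_set
        ms = maturation_shift(ko_up, ko_down, p7_set, p32_set, universe)
        report.results["maturation"] = {
            "up_vs_p7_p": ms["up_vs_p7"].p,
            "up_vs_p7_or": ms["up_vs_p7"].odds_ratio,
            "down_vs_p32_p": ms["down_vs_p32"].p,
            "down_vs_p32_or": ms["down_vs_p32"].odds_ratio,
            "n_ko_up": len(ko_up), "n_ko_down": len(ko_down),
            "p7_recovered": len(p7_set), "p32_recovered": len(p32_set),
        }
        _write_tsv(ms["genes"], outdir / "maturation_genes.tsv")
    report.to_json(outdir / "trap_report.json")
    report.outputs.append(str(outdir / "trap_report.json"))
    return report
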