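"""Seeded synthetic-data generator with ground truth.

Emulates the statistical structure of a CLIP-seq / TRAP-seq study of a
STAR-family RNA-binding protein (QKI): a miniature genome whose target
transcripts carry planted QKI-binding motifs (QBM, ACUAAC/ACUAAU with a
nearby YAAY half site) in their 3'UTRs, stranded CLIP/IgG/Input read sets
whose window counts follow a negative-binomial model with enrichment
decaying exponentially with distance from the planted sites, a conservation
track elevated at those sites, TRAP count matrices with a small planted
multiplicative knockout effect on target genes and astrocyte-marker
enrichment in the TRAP fraction, and immature/mature (P7/P32-style)
maturation gene sets overlapping the planted knockout-responsive sets.

Everything is driven by one root seed; identical (config, seed) gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    GenomeBuild,
    Transcript,
    TranscriptomeIndex,
    extract_sequence,
    write_fasta,
    write_gtf,
)

_BASES = np.array(list("ACGT"))
_QBM_FULL = ("ACTAAC", "ACTAAT")      # DNA-encoded ACUAAY
_QBM_HALF = ("CAAC", "CAAT", "TAAC", "TAAT")  # YAAY
_PAS = ("AATAAA", "ATTAAA")           # A[AT]TAAA

# fixed spawn keys so each stage has an independent, reproducible stream
_STAGES = ("genome", "clip", "trap", "maturation")


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Generator parameters. Defaults define the package's reference
    synthetic study; see docs/methods.md for the rationale behind each."""

    seed: int = 0
    n_transcripts: int = 1000
    n_chroms: int = 3
    # 3'UTR length ~ LogNormal(meanlog, sdlog), floored at min_utr3_length
    utr3_meanlog: float = math.log(400.0)
    utr3_sdlog: float = 0.6
    min_utr3_length: int = 80
    fraction_target_transcripts: float = 0.10
    # per-window expression intensity ~ LogNormal
    expr_meanlog: float = 0.0
    expr_sdlog: float = 0.3
    clip_enrichment: float = 16.0     # fold enrichment E at a planted QBM
    decay_lambda: float = 150.0       # nt, spatial decay scale of binding
    nb_dispersion: float = 0.1        # phi for CLIP window counts
    library_sizes: dict = field(
        default_factory=lambda: {"clip": 100_000, "input": 100_000, "igg": 20_000}
    )
    n_clip_reps: int = 3
    read_length: int = 50
    # TRAP experiment
    ko_log2_effect: float = math.log2(0.9)   # beta: -10% on targets in KO-TRAP
    n_trap_per_group: int = 6
    marker_enrichment: float = 4.0           # M: astrocyte markers in TRAP
    trap_dispersion: float = 0.05            # BCV ~0.22, inbred littermates
    trap_meanlog: float = math.log(150.0)
    trap_sdlog: float = 0.7
    n_marker_genes: int = 30
    n_neg_marker_genes: int = 30
    # extra planted knockout-responsive genes defining KO-up / KO-down sets
    n_ko_up: int = 60
    n_ko_down: int = 60
    ko_set_log2fc: float = 1.0
    # maturation (P7/P32-style) sets
    maturation_set_size: int = 80
    maturation_enrichment: float = 4.0
    maturation_log2fc: float = 1.5
    n_maturation_per_group: int = 6
    # conservation track
    conservation_baseline_mean: float = 0.0
    conservation_baseline_sd: float = 0.5
    conservation_bump: float = 1.5
    conservation_flank: int = 300

    def validate(self) -> None:
        if not (0.0 <= self.fraction_target_transcripts <= 1.0):
            raise SimulationError("fraction_target_transcripts must be in [0, 1]")
        for name in ("clip_enrichment", "decay_lambda", "nb_dispersion",
                     "trap_dispersion", "marker_enrichment",
                     "maturation_enrichment"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.clip_enrichment < 1.0:
            raise SimulationError("clip_enrichment must be >= 1")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise SimulationError("library sizes must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        key = _STAGES.index(stage)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )


@dataclass
class PlantedSite:
    transcript_id: str
    gene_id: str
    chrom: str
    pos: int          # genomic (leftmost) start of the 6-base QBM footprint
    strand: str
    motif: str        # transcript-sense DNA motif (ACTAAC or ACTAAT)

    @property
    def midpoint(self) -> int:
        return self.pos + 3


@dataclass
class SimTruth:
    """Ground truth emitted by the generator."""

    planted_qbm_sites: list[PlantedSite]
    target_genes: set[str]
    ko_effects: dict[str, float]
    marker_genes: set[str]
    neg_marker_genes: set[str]
    p7_like_genes: set[str]
    p32_like_genes: set[str]
    ko_up_genes: set[str]
    ko_down_genes: set[str]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "planted_qbm_sites": [dataclasses.asdict(s) for s in self.planted_qbm_sites],
            "target_genes": sorted(self.target_genes),
            "ko_effects": dict(sorted(self.ko_effects.items())),
            "marker_genes": sorted(self.marker_genes),
            "neg_marker_genes": sorted(self.neg_marker_genes),
            "p7_like_genes": sorted(self.p7_like_genes),
            "p32_like_genes": sorted(self.p32_like_genes),
            "ko_up_genes": sorted(self.ko_up_genes),
            "ko_down_genes": sorted(self.ko_down_genes),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            planted_qbm_sites=[PlantedSite(**s) for s in obj["planted_qbm_sites"]],
            target_genes=set(obj["target_genes"]),
            ko_effects={k: float(v) for k, v in obj["ko_effects"].items()},
            marker_genes=set(obj["marker_genes"]),
            neg_marker_genes=set(obj["neg_marker_genes"]),
            p7_like_genes=set(obj["p7_like_genes"]),
            p32_like_genes=set(obj["p32_like_genes"]),
            ko_up_genes=set(obj["ko_up_genes"]),
            ko_down_genes=set(obj["ko_down_genes"]),
        )


@dataclass
class SyntheticGenome:
    """In-memory simulation product: sequences, annotation, expression,
    conservation and truth. File emission via :func:`write_genome_files`."""

    build: GenomeBuild
    sequences: dict[str, str]
    transcripts: list[Transcript]
    expression: dict[str, float]      # transcript_id -> per-window intensity
    conservation: pd.DataFrame        # chrom, start, end, score (per-base rows)
    truth: SimTruth
    config: SimConfig

    def index(self) -> TranscriptomeIndex:
        return TranscriptomeIndex(self.transcripts, self.build)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _plant(seq: np.ndarray, utr3: tuple[int, int], strand: str,
           sense_offset: int, motif: str) -> int:
    """Write a transcript-sense motif into a contiguous 3'UTR at the given
    offset from the UTR's transcript-5' end; returns the genomic start."""
    s, e = utr3
    k = len(motif)
    if strand == "+":
        g = s + sense_offset
        seq[g : g + k] = list(motif)
    else:
        g = e - sense_offset - k
        comp = motif.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seq[g : g + k] = list(comp)
    return g


def simulate_genome(config: SimConfig) -> SyntheticGenome:
    """Generate the miniature genome, annotation, conservation and truth.

    Transcript layout: transcripts are placed sequentially along
    ``n_chroms`` chromosomes with intergenic gaps, random strand, a short
    5'UTR, a CDS (about a third of transcripts carry one intron inside the
    CDS), and a contiguous 3'UTR of log-normal length.  Every 3'UTR ends
    with a polyadenylation signal (PAS, ``A[AT]TAAA``) whose hexamer ends
    10-30 nt before the transcript end.  Target transcripts additionally
    carry one full QBM with a YAAY half site 5-15 nt downstream.
    """
    config.validate()
    rng = config.rng("genome")
    n = config.n_transcripts

    n_targets = int(round(config.fraction_target_transcripts * n))
    target_idx = set(rng.choice(n, size=n_targets, replace=False).tolist())

    per_chrom = math.ceil(n / config.n_chroms) if n else 0
    chrom_parts: dict[str, list] = {}
    transcripts: list[Transcript] = []
    planted: list[PlantedSite] = []
    expression: dict[str, float] = {}
    cursor = 0
    chrom_i = 0
    chrom_name = "chr1"
    placed_on_chrom = 0
    chrom_records: dict[str, list[dict]] = {chrom_name: []}

    for i in range(n):
        if placed_on_chrom >= per_chrom and chrom_i + 1 < config.n_chroms:
            chrom_i += 1
            chrom_name = f"chr{chrom_i + 1}"
            chrom_records[chrom_name] = []
            cursor = 0
            placed_on_chrom = 0
        tid, gid = f"tx{i:04d}", f"gene{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        utr5_len = int(rng.integers(60, 151))
        cds_len = 3 * int(rng.integers(100, 301))
        intron_len = int(rng.integers(100, 301)) if rng.random() < 0.3 else 0
        utr3_len = 0
        for _attempt in range(100):
            utr3_len = int(round(rng.lognormal(config.utr3_meanlog, config.utr3_sdlog)))
            if utr3_len >= config.min_utr3_length:
                break
        else:
            raise SimulationError(f"could not draw a usable 3'UTR for {tid}")

        gap = int(rng.integers(200, 501))
        start = cursor + gap
        # genomic layout in + orientation; mirror for '-' strand transcripts
        if strand == "+":
            u5 = (start, start + utr5_len)
            cds_start = u5[1]
        else:
            u3g = (start, start + utr3_len)
            cds_start = u3g[1]
        if intron_len:
            half = (cds_len // 6) * 3  # split CDS into two in-frame chunks
            if strand == "+":
                cds_iv1 = (cds_start, cds_start + half)
                cds_iv2 = (cds_iv1[1] + intron_len, cds_iv1[1] + intron_len + cds_len - half)
                cds_end = cds_iv2[1]
            else:
                cds_iv1 = (cds_start, cds_start + cds_len - half)
                cds_iv2 = (cds_iv1[1] + intron_len, cds_iv1[1] + intron_len + half)
                cds_end = cds_iv2[1]
            cds_exons = [cds_iv1, cds_iv2]
        else:
            cds_exons = [(cds_start, cds_start + cds_len)]
            cds_end = cds_start + cds_len
        if strand == "+":
            u3 = (cds_end, cds_end + utr3_len)
            tx_end = u3[1]
            exons = [(u5[0], cds_exons[0][1])] + (
                [(cds_exons[1][0], u3[1])] if intron_len else []
            )
            if not intron_len:
                exons = [(u5[0], u3[1])]
        else:
            u3 = u3g
            u5 = (cds_end, cds_end + utr5_len)
            tx_end = u5[1]
            exons = (
                [(u3[0], cds_exons[0][1]), (cds_exons[1][0], u5[1])]
                if intron_len
                else [(u3[0], u5[1])]
            )
        cds_span = (cds_exons[0][0], cds_exons[-1][1])
        chrom_records[chrom_name].append({
            "tid": tid, "gid": gid, "strand": strand, "exons": exons,
            "cds_span": cds_span, "u3": u3, "target": i in target_idx,
        })
        expression[tid] = float(rng.lognormal(config.expr_meanlog, config.expr_sdlog))
        cursor = tx_end
        placed_on_chrom += 1

    sequences: dict[str, str] = {}
    chrom_lengths: dict[str, int] = {}
    for chrom, records in chrom_records.items():
        end = max((r["exons"][-1][1] for r in records), default=0) + 300
        seq = _BASES[rng.integers(0, 4, size=end)]
        for r in records:
            L3 = r["u3"][1] - r["u3"][0]
            # PAS at every 3'UTR: hexamer ends 10-30 nt before transcript end
            u = int(rng.integers(10, 31))
            pas_start = L3 - 6 - u
            _plant(seq, r["u3"], r["strand"], pas_start, _PAS[rng.integers(0, 2)])
            if r["target"]:
                qhi = pas_start - 26
                q = int(rng.integers(5, qhi + 1)) if qhi > 5 else 5
                motif = _QBM_FULL[rng.integers(0, 2)]
                gpos = _plant(seq, r["u3"], r["strand"], q, motif)
                gap_nt = int(rng.integers(5, 16))
                _plant(seq, r["u3"], r["strand"], q + 6 + gap_nt,
                       _QBM_HALF[rng.integers(0, 4)])
                planted.append(PlantedSite(
                    transcript_id=r["tid"], gene_id=r["gid"], chrom=chrom,
                    pos=gpos, strand=r["strand"], motif=motif,
                ))
        sequences[chrom] = "".join(seq)
        chrom_lengths[chrom] = end

    build = GenomeBuild(chrom_lengths)
    for chrom, records in chrom_records.items():
        for r in records:
            transcripts.append(Transcript(
                transcript_id=r["tid"], gene_id=r["gid"], chrom=chrom,
                strand=r["strand"], exons=r["exons"], cds_span=r["cds_span"],
            ))

    conservation = _simulate_conservation(config, rng, chrom_records, planted)
    truth = _assemble_truth(config, rng, planted, [t.gene_id for t in transcripts])
    return SyntheticGenome(
        build=build, sequences=sequences, transcripts=transcripts,
        expression=expression, conservation=conservation, truth=truth,
        config=config,
    )


def _simulate_conservation(config, rng, chrom_records, planted) -> pd.DataFrame:
    """Per-base conservation over every 3'UTR +/- flank: Gaussian baseline
    plus an additive bump decaying exponentially from planted QBM midpoints."""
    rows = []
    sites_by_chrom: dict[str, np.ndarray] = {}
    for s in planted:
        sites_by_chrom.setdefault(s.chrom, []).append(s.midpoint)
    sites_by_chrom = {c: np.asarray(sorted(v)) for c, v in sites_by_chrom.items()}
    for chrom, records in chrom_records.items():
        seen: set[int] = set()
        for r in records:
            lo = max(0, r["u3"][0] - config.conservation_flank)
            hi = r["u3"][1] + config.conservation_flank
            pos = np.arange(lo, hi)
            mask = np.array([p not in seen for p in pos])
            pos = pos[mask]
            if pos.size == 0:
                continue
            seen.update(pos.tolist())
            vals = rng.normal(config.conservation_baseline_mean,
                              config.conservation_baseline_sd, size=pos.size)
            sites = sites_by_chrom.get(chrom)
            if sites is not None and sites.size:
                d = np.abs(pos[:, None] - sites[None, :]).min(axis=1)
                vals = vals + config.conservation_bump * np.exp(-d / config.decay_lambda)
            rows.append(pd.DataFrame({
                "chrom": chrom, "start": pos, "end": pos + 1, "score": vals,
            }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "score"])
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["chrom", "start"], ignore_index=True)


def _assemble_truth(config, rng, planted, gene_ids) -> SimTruth:
    target_genes = {s.gene_id for s in planted}
    non_targets = [g for g in gene_ids if g not in target_genes]
    perm = rng.permutation(len(non_targets))
    shuffled = [non_targets[j] for j in perm]
    k_up, k_dn = config.n_ko_up, config.n_ko_down
    k_m, k_nm = config.n_marker_genes, config.n_neg_marker_genes
    need = k_up + k_dn + k_m + k_nm
    if need > len(shuffled):
        # miniature genomes: shrink the planted sets proportionally
        scale = len(shuffled) / need
        k_up, k_dn, k_m, k_nm = (
            max(1, int(k * scale)) for k in (k_up, k_dn, k_m, k_nm)
        )
        if k_up + k_dn + k_m + k_nm > len(shuffled):
            raise SimulationError("not enough non-target genes for planted sets")
    ko_up = set(shuffled[:k_up])
    ko_down = set(shuffled[k_up : k_up + k_dn])
    markers = set(shuffled[k_up + k_dn : k_up + k_dn + k_m])
    neg_markers = set(shuffled[k_up + k_dn + k_m : k_up + k_dn + k_m + k_nm])
    ko_effects = {g: config.ko_log2_effect for g in sorted(target_genes)}
    ko_effects.update({g: config.ko_set_log2fc for g in sorted(ko_up)})
    ko_effects.update({g: -config.ko_set_log2fc for g in sorted(ko_down)})
    return SimTruth(
        planted_qbm_sites=planted, target_genes=target_genes,
        ko_effects=ko_effects, marker_genes=markers,
        neg_marker_genes=neg_markers,
        p7_like_genes=set(), p32_like_genes=set(),
        ko_up_genes=ko_up, ko_down_genes=ko_down,
    )


# ---------------------------------------------------------------------------
# CLIP read simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + np.maximum(mean, 1e-300))
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def _transcript_windows(genome: SyntheticGenome, width: int = 50):
    """Per transcript: the genome-tiling windows overlapping its span,
    with window means' building blocks (expression, distance to nearest
    planted QBM on the same chromosome/strand)."""
    sites: dict[tuple[str, str], np.ndarray] = {}
    for s in genome.truth.planted_qbm_sites:
        sites.setdefault((s.chrom, s.strand), []).append(s.midpoint)
    sites = {k: np.asarray(sorted(v)) for k, v in sites.items()}
    recs = []
    for t in genome.transcripts:
        w0 = (t.start // width) * width
        starts = np.arange(w0, t.end, width)
        ends = np.minimum(starts + width, genome.build.length(t.chrom))
        mids = (starts + ends) / 2.0
        key = (t.chrom, t.strand)
        if key in sites and sites[key].size:
            d = np.abs(mids[:, None] - sites[key][None, :]).min(axis=1)
        else:
            d = np.full(mids.shape, np.inf)
        recs.append({
            "transcript": t, "starts": starts, "ends": ends,
            "expr": genome.expression[t.transcript_id], "dist": d,
        })
    return recs


def simulate_clip_reads(
    genome: SyntheticGenome, config: SimConfig | None = None, width: int = 50
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Simulate stranded BED6 read sets: n_clip_reps CLIP replicates, one
    IgG and one Input library.

    Per 50-nt window w of transcript t the count is NB(mean, phi) with
    mean = s * e_t for Input, s_bg * e_t for IgG (smaller library), and
    s * e_t * (1 + (E - 1) * exp(-d(w)/decay_lambda)) for each CLIP
    replicate, d(w) = distance from the window midpoint to the nearest
    planted QBM (infinite -> multiplier 1).  The common scale s is set so
    the Input library totals ``library_sizes['input']`` reads in
    expectation; CLIP library sizes are the background-equivalent
    ``library_sizes['clip']`` scaled up by the planted enrichment.
    Counts are realized as read_length intervals with 5' ends uniform in
    the window.

    Returns (sample name -> BED6 DataFrame, sample name -> role).
    """
    config = config or genome.config
    rng = config.rng("clip")
    recs = _transcript_windows(genome, width)
    expr_tot = sum(r["expr"] * len(r["starts"]) for r in recs)
    if expr_tot == 0:
        raise SimulationError("no transcripts to simulate reads from")
    s_input = config.library_sizes["input"] / expr_tot
    s_clip = config.library_sizes["clip"] / expr_tot
    s_igg = config.library_sizes["igg"] / expr_tot
    E, lam, phi = config.clip_enrichment, config.decay_lambda, config.nb_dispersion

    samples = [(f"clip_rep{i + 1}", "clip") for i in range(config.n_clip_reps)]
    samples += [("igg", "igg"), ("input", "input")]
    beds: dict[str, pd.DataFrame] = {}
    roles: dict[str, str] = {}
    for name, role in samples:
        frames = []
        for r in recs:
            t = r["transcript"]
            base = r["expr"]
            if role == "clip":
                mult = 1.0 + (E - 1.0) * np.exp(-r["dist"] / lam)
                mean = s_clip * base * mult
            elif role == "input":
                mean = np.full(r["starts"].shape, s_input * base)
            else:
                mean = np.full(r["starts"].shape, s_igg * base)
            counts = _nb_draw(rng, mean, phi)
            total = int(counts.sum())
            if total == 0:
                continue
            wstarts = np.repeat(r["starts"], counts)
            wlens = np.repeat(r["ends"] - r["starts"], counts)
            five = wstarts + (rng.random(total) * wlens).astype(np.int64)
            L = config.read_length
            clen = genome.build.length(t.chrom)
            if t.strand == "+":
                starts = five
                ends = np.minimum(five + L, clen)
            else:
                starts = np.maximum(five - L + 1, 0)
                ends = five + 1
            frames.append(pd.DataFrame({
                "chrom": t.chrom, "start": starts, "end": ends,
                "name": name, "score": 0, "strand": t.strand,
            }))
        bed = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
        )
        beds[name] = bed.sort_values(
            ["chrom", "start", "end"], ignore_index=True
        )
        roles[name] = role
    return beds, roles


# ---------------------------------------------------------------------------
# TRAP count simulation
# ---------------------------------------------------------------------------

def _sample_names(groups: list[str], per_group: int) -> list[str]:
    out = []
    i = 1
    for g in groups:
        for _ in range(per_group):
            out.append(f"S{i:02d}:{g}")
            i += 1
    return out


def simulate_trap_counts(
    genome: SyntheticGenome, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x sample TRAP/Input count matrix with group labels.

    count ~ NB(L_s * mu_g * 2^(beta * 1[target, KO-TRAP])
                 * 2^(+/-ko_set_log2fc for planted KO-up/down genes, KO-TRAP)
                 * M^(+1 markers / -1 neg markers, TRAP samples), phi).
    Column names embed the group as ``sample:group``.
    """
    config = config or genome.config
    rng = config.rng("trap")
    genes = [t.gene_id for t in genome.transcripts]
    G = len(genes)
    mu = rng.lognormal(config.trap_meanlog, config.trap_sdlog, size=G)
    groups_order = ["WT-TRAP", "KO-TRAP", "WT-Input", "KO-Input"]
    names = _sample_names(groups_order, config.n_trap_per_group)
    groups = pd.Series([n.split(":", 1)[1] for n in names], index=names)
    libfac = rng.uniform(0.8, 1.2, size=len(names))

    truth = genome.truth
    is_target = np.array([g in truth.target_genes for g in genes])
    is_up = np.array([g in truth.ko_up_genes for g in genes])
    is_down = np.array([g in truth.ko_down_genes for g in genes])
    is_mark = np.array([g in truth.marker_genes for g in genes])
    is_neg = np.array([g in truth.neg_marker_genes for g in genes])

    counts = np.zeros((G, len(names)), dtype=np.int64)
    for j, name in enumerate(names):
        grp = groups.iloc[j]
        mean = mu * libfac[j]
        if grp == "KO-TRAP":
            mean = mean * np.where(is_target, 2.0 ** config.ko_log2_effect, 1.0)
            mean = mean * np.where(is_up, 2.0 ** config.ko_set_log2fc, 1.0)
            mean = mean * np.where(is_down, 2.0 ** -config.ko_set_log2fc, 1.0)
        if grp.endswith("TRAP"):
            mean = mean * np.where(is_mark, config.marker_enrichment, 1.0)
            mean = mean * np.where(is_neg, 1.0 / config.marker_enrichment, 1.0)
        counts[:, j] = _nb_draw(rng, mean, config.trap_dispersion)
    return pd.DataFrame(counts, index=genes, columns=names), groups


# ---------------------------------------------------------------------------
# maturation (P7/P32-style) sets and count matrices
# ---------------------------------------------------------------------------

def simulate_maturation_sets(
    genome: SyntheticGenome, config: SimConfig | None = None
) -> dict:
    """Plant immature (P7-like) and mature (P32-like) gene sets overlapping
    the KO-up and KO-down sets at the configured enrichment, plus count
    matrices from which differential expression at p < 0.05 recovers them.

    Updates ``genome.truth.p7_like_genes`` / ``p32_like_genes`` in place and
    returns ``{"p7_like", "p32_like", "counts", "groups"}`` where ``counts``
    is a gene x sample matrix over P7/P32 groups.
    """
    config = config or genome.config
    rng = config.rng("maturation")
    genes = [t.gene_id for t in genome.transcripts]
    G = len(genes)
    truth = genome.truth
    k = config.maturation_set_size

    def build_set(source: set[str]) -> set[str]:
        src = sorted(source)
        rest = sorted(set(genes) - source)
        base_rate = k * len(src) / G            # expected overlap if independent
        n_in = min(len(src), k, int(round(config.maturation_enrichment * base_rate)))
        chosen = set(
            np.array(src)[rng.choice(len(src), size=n_in, replace=False)].tolist()
        )
        chosen |= set(
            np.array(rest)[rng.choice(len(rest), size=k - n_in, replace=False)].tolist()
        )
        return chosen

    p7 = build_set(truth.ko_up_genes)
    p32 = build_set(truth.ko_down_genes)
    truth.p7_like_genes, truth.p32_like_genes = p7, p32

    mu = rng.lognormal(config.trap_meanlog, config.trap_sdlog, size=G)
    names = _sample_names(["P7", "P32"], config.n_maturation_per_group)
    groups = pd.Series([n.split(":", 1)[1] for n in names], index=names)
    in_p7 = np.array([g in p7 for g in genes])
    in_p32 = np.array([g in p32 for g in genes])
    counts = np.zeros((G, len(names)), dtype=np.int64)
    fc = 2.0 ** config.maturation_log2fc
    for j, name in enumerate(names):
        mean = mu.copy()
        if groups.iloc[j] == "P7":
            mean = mean * np.where(in_p7, fc, 1.0)
        else:
            mean = mean * np.where(in_p32, fc, 1.0)
        counts[:, j] = _nb_draw(rng, mean, config.trap_dispersion)
    return {
        "p7_like": p7, "p32_like": p32,
        "counts": pd.DataFrame(counts, index=genes, columns=names),
        "groups": groups,
    }


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "name": str, "strand": str},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              float_format="%.6g")


def write_genome_files(genome: SyntheticGenome, outdir: str | Path) -> dict[str, Path]:
    """Emit FASTA, GTF, conservation bedGraph and truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "conservation": outdir / "conservation.bedgraph",
        "truth": outdir / "truth.json",
    }
    write_fasta(genome.sequences, paths["fasta"])
    write_gtf(genome.index(), paths["gtf"])
    write_bedgraph(genome.conservation, paths["conservation"])
    genome.truth.to_json(paths["truth"])
    return paths


def verify_planted_sites(genome: SyntheticGenome) -> bool:
    """Truth consistency: every planted QBM footprint extracts to its
    transcript-sense motif."""
    for s in genome.truth.planted_qbm_sites:
        seq = extract_sequence([(s.pos, s.pos + 6)], s.strand,
                               genome.sequences[s.chrom])
        if seq != s.motif:
            return False
    return True
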