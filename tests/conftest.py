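"""Shared fixtures: synthetic study objects reused across test modules.

The reference study (default SimConfig, seed 1) is generated once per
session; small bespoke genomes are built per test where structure matters.
"""

import numpy as np
import pandas as pd
import pytest

from qclip.genome_model import GenomeBuild, Transcript, TranscriptomeIndex
from qclip.peak_calling import (
    bin_genome,
    count_reads_in_windows,
    fit_ztnb,
    merge_significant_windows,
    score_windows,
)
from qclip.synthetic_data import SimConfig, simulate_clip_reads, simulate_genome


@pytest.fixture(scope="session")
def default_genome():
    """The reference synthetic study at its frozen default conditions."""
    return simulate_genome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_clip_run(default_genome):
    """Peak calling on the reference study: windows, counts, fit, peaks."""
    g = default_genome
    beds, roles = simulate_clip_reads(g)
    windows = bin_genome(g.build, 50)
    counts = count_reads_in_windows(beds, windows, g.build, width=50)
    clip = [s for s, r in roles.items() if r == "clip"]
    fit = fit_ztnb(counts[clip].sum(axis=1).to_numpy())
    scored = score_windows(counts, clip, fit, fdr=0.05)
    peaks = merge_significant_windows(scored)
    return {
        "genome": g, "beds": beds, "roles": roles, "windows": windows,
        "counts": counts, "clip_samples": clip, "fit": fit,
        "scored": scored, "peaks": peaks,
    }


@pytest.fixture(scope="session")
def clip_report(default_clip_run, tmp_path_factory):
    """Full CLIP pipeline report on the reference study (shared)."""
    from qclip.pipeline import PipelineConfig, run_clip_analysis

    run = default_clip_run
    cfg = PipelineConfig(seed=1,
                         outdir=str(tmp_path_factory.mktemp("clip_run")))
    return run_clip_analysis(cfg, genome=run["genome"], beds=run["beds"],
                             roles=run["roles"])


@pytest.fixture(scope="session")
def trap_report(default_genome, tmp_path_factory):
    """Full TRAP pipeline report on the reference study (shared)."""
    from qclip.pipeline import PipelineConfig, run_trap_analysis

    cfg = PipelineConfig(seed=1,
                         outdir=str(tmp_path_factory.mktemp("trap_run")))
    return run_trap_analysis(cfg, genome=default_genome)


@pytest.fixture()
def two_exon_plus():
    """GTF example transcript: exons 101-200, 301-400 (1-based), CDS 151-350,
    on '+': 0-based five_utr [100,150), three_utr [350,400)."""
    return Transcript(
        transcript_id="txp", gene_id="gp", chrom="chr1", strand="+",
        exons=[(100, 200), (300, 400)], cds_span=(150, 350),
    )


@pytest.fixture()
def two_exon_minus():
    return Transcript(
        transcript_id="txm", gene_id="gm", chrom="chr1", strand="-",
        exons=[(100, 200), (300, 400)], cds_span=(150, 350),
    )


@pytest.fixture()
def tiny_index(two_exon_plus):
    build = GenomeBuild({"chr1": 1000})
    noncoding = Transcript(
        transcript_id="txn", gene_id="gn", chrom="chr1", strand="+",
        exons=[(500, 560), (600, 660)], cds_span=None,
    )
    return TranscriptomeIndex([two_exon_plus, noncoding], build)


def random_transcript(rng, chrom="chr1", chrom_len=100_000):
    """A random valid coding transcript for brute-force comparisons."""
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, chrom_len - 10_000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 400))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(20, 300))
    strand = "+" if rng.random() < 0.5 else "-"
    total = sum(e - s for s, e in exons)
    # pick CDS endpoints strictly inside the exonic span (exonic coordinates)
    lo = int(rng.integers(1, total - 2))
    hi = int(rng.integers(lo + 1, total))
    flat = [b for s, e in exons for b in range(s, e)]
    cds_span = (flat[lo], flat[hi - 1] + 1)
    return Transcript(
        transcript_id=f"t{rng.integers(1e9)}", gene_id="g", chrom=chrom,
        strand=strand, exons=exons, cds_span=cds_span,
    )


def make_bed(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)
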