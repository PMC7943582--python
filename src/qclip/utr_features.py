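"""Sequence-level characterization of bound 3'UTRs.

QBM/QRE scanning (full site ACUAAY paired with a disjoint YAAY half site
within a bounded gap), polyadenylation-signal counting (A[AT]TAAA),
matched-length control UTR selection with artificial peak sites,
conservation flank comparison against a base-wise track, the
relative-position statistic (how far a bound site sits between the stop
codon and its nearest PAS), and UTR-length rank-sum tests.

Sequences are DNA or RNA alphabet; T and U are equivalent throughout, and
overlapping motif matches are all reported (every start position is tested
independently).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "Y": frozenset("CT"), "R": frozenset("AG"), "W": frozenset("AT"),
    "S": frozenset("CG"), "K": frozenset("GT"), "M": frozenset("AC"),
    "N": frozenset("ACGT"),
}


class UtrFeatureError(ValueError):
    pass


@dataclass(frozen=True)
class MotifConfig:
    """Motif definitions: full QBM hexamer, half-site tetramer, the maximum
    edge-to-edge gap pairing them into a QRE, and the PAS hexamer."""

    qbm_full: str = "ACUAAY"
    qbm_half: str = "YAAY"
    max_gap: int = 20
    pas_pattern: str = "A[AT]TAAA"


@dataclass(frozen=True)
class QREHit:
    full_start: int
    half_start: int
    gap: int          # edge-to-edge distance between the two motif spans


@dataclass
class UTRRecord:
    """A 3'UTR with its transcript-sense sequence and a site position
    (a real CLIP peak for targets, an artificial draw for controls)."""

    transcript_id: str
    utr_sequence: str
    chrom: str = ""
    strand: str = "+"
    intervals: list = field(default_factory=list)
    site: int | None = None
    gene_id: str = ""

    @property
    def length(self) -> int:
        return len(self.utr_sequence)


def _parse_pattern(pattern: str) -> list[frozenset]:
    sets = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            allowed = frozenset(
                b for c in pattern[i + 1 : j] for b in _IUPAC[c.upper()]
            )
            sets.append(allowed)
            i = j + 1
        else:
            sets.append(_IUPAC[ch.upper()])
            i += 1
    return sets


def scan_motif(seq: str, pattern: str) -> list[int]:
    """All start positions where the degenerate k-mer matches (overlaps
    allowed; N in the sequence matches nothing; T and U are equivalent)."""
    sets = _parse_pattern(pattern)
    k = len(sets)
    s = seq.upper().replace("U", "T")
    n = len(s)
    if k > n:
        return []
    hits = []
    for i in range(n - k + 1):
        if all(s[i + j] in sets[j] for j in range(k)):
            hits.append(i)
    return hits


def find_qres(seq: str, config: MotifConfig = MotifConfig()) -> list[QREHit]:
    """Pair every full-site match with every half-site match whose span is
    disjoint from the full site and whose edge-to-edge gap is within
    ``max_gap``, on either side.  (Every ACUAAY contains a YAAY internally,
    so the disjointness rule is what keeps full sites from self-pairing.)"""
    fulls = scan_motif(seq, config.qbm_full)
    halves = scan_motif(seq, config.qbm_half)
    kf = sum(1 for _ in _parse_pattern(config.qbm_full))
    kh = sum(1 for _ in _parse_pattern(config.qbm_half))
    hits = []
    for f in fulls:
        for h in halves:
            if h >= f + kf:
                gap = h - (f + kf)
            elif h + kh <= f:
                gap = f - (h + kh)
            else:
                continue  # overlapping spans never form a QRE
            if gap <= config.max_gap:
                hits.append(QREHit(full_start=f, half_start=h, gap=gap))
    return sorted(hits, key=lambda q: (q.full_start, q.half_start))


def count_pas(utr_seq: str, config: MotifConfig = MotifConfig()) -> int:
    """Number of polyadenylation-signal matches (overlapping allowed)."""
    return len(scan_motif(utr_seq, config.pas_pattern))


# ---------------------------------------------------------------------------
# matched-length control selection
# ---------------------------------------------------------------------------

def select_matched_controls(
    target_utrs: list[UTRRecord],
    pool: list[UTRRecord],
    min_len: int = 50,
    expression: pd.Series | None = None,
    min_expression: float = 10.0,
    seed: int = 0,
) -> list[UTRRecord]:
    """One control UTR per target, matched by length.

    The pool (which must exclude targets) is filtered to UTRs of length
    >= min_len with measurable expression (> min_expression counts) when an
    expression table is supplied.  Controls are taken without replacement as
    the pool UTR of nearest length (ties broken by a seeded draw), each
    assigned an artificial site uniform on [0, len).  The control-vs-target
    length distributions must be indistinguishable (rank-sum p > 0.05) or
    the selection fails.
    """
    rng = np.random.default_rng(seed)
    target_ids = {t.transcript_id for t in target_utrs}
    cand = [
        u for u in pool
        if u.transcript_id not in target_ids and u.length >= min_len
        and (expression is None
             or float(expression.get(u.transcript_id, 0.0)) > min_expression)
    ]
    if len(cand) < len(target_utrs):
        raise UtrFeatureError(
            f"control pool ({len(cand)}) smaller than target list "
            f"({len(target_utrs)})"
        )
    lengths = np.array([u.length for u in cand], dtype=float)
    available = np.ones(len(cand), dtype=bool)
    controls: list[UTRRecord] = []
    order = rng.permutation(len(target_utrs))
    picked = [None] * len(target_utrs)
    for ti in order:
        t = target_utrs[ti]
        diffs = np.abs(lengths - t.length)
        diffs[~available] = np.inf
        best = diffs.min()
        tie_idx = np.where(diffs == best)[0]
        j = int(rng.choice(tie_idx))
        available[j] = False
        src = cand[j]
        site = int(rng.integers(0, src.length))
        picked[ti] = UTRRecord(
            transcript_id=src.transcript_id, utr_sequence=src.utr_sequence,
            chrom=src.chrom, strand=src.strand, intervals=list(src.intervals),
            site=site, gene_id=src.gene_id,
        )
    controls = list(picked)
    _, p = utr_length_test(
        [t.length for t in target_utrs], [c.length for c in controls]
    )
    if p <= 0.05:
        raise UtrFeatureError(
            f"matched control lengths differ from targets (rank-sum p={p:.3g}); "
            "supply a larger pool"
        )
    return controls


# ---------------------------------------------------------------------------
# relative position between stop codon and PAS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelativePositionResult:
    percent: float
    valid: bool     # site lies between the stop codon and its nearest PAS


def relative_position(
    site_pos: int, pas_pos: int, stop_pos: int, strand: str
) -> RelativePositionResult:
    """Percent of the stop-codon-to-PAS span covered from the PAS side:
    100 at the stop codon, 0 at the PAS.

    '+' strand: (pas - site) / (pas - stop) * 100;
    '-' strand: (site - pas) / (stop - pas) * 100.
    """
    if pas_pos == stop_pos:
        raise UtrFeatureError("PAS and stop codon coincide; percent undefined")
    if strand == "+":
        percent = (pas_pos - site_pos) / (pas_pos - stop_pos) * 100.0
    else:
        percent = (site_pos - pas_pos) / (stop_pos - pas_pos) * 100.0
    return RelativePositionResult(percent=float(percent),
                                  valid=0.0 <= percent <= 100.0)


# ---------------------------------------------------------------------------
# conservation track and flank comparison
# ---------------------------------------------------------------------------

class ConservationTrack:
    """Base-wise score track (bedGraph semantics: absent bases score 0)."""

    def __init__(self, df: pd.DataFrame):
        self._pos: dict[str, np.ndarray] = {}
        self._val: dict[str, np.ndarray] = {}
        self.n_missing_queried = 0
        for chrom, sub in df.groupby("chrom", sort=True):
            pos = np.concatenate([
                np.arange(s, e) for s, e in zip(sub["start"], sub["end"])
            ]) if len(sub) else np.array([], dtype=np.int64)
            val = np.repeat(
                sub["score"].to_numpy(dtype=float),
                (sub["end"] - sub["start"]).to_numpy(),
            ) if len(sub) else np.array([])
            order = np.argsort(pos, kind="stable")
            self._pos[chrom] = pos[order]
            self._val[chrom] = val[order]

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "ConservationTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "score"])
        return cls(df)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores for [start, end); bases absent from the track return 0
        (counted in ``n_missing_queried``)."""
        q = np.arange(start, end)
        pos = self._pos.get(chrom)
        out = np.zeros(q.size)
        if pos is None or pos.size == 0:
            self.n_missing_queried += q.size
            return out
        idx = np.searchsorted(pos, q)
        ok = (idx < pos.size) & (pos[np.minimum(idx, pos.size - 1)] == q)
        out[ok] = self._val[chrom][idx[ok]]
        self.n_missing_queried += int((~ok).sum())
        return out


def conservation_flank_compare(
    target_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    track: ConservationTrack,
    flank: int = 200,
) -> dict:
    """Compare conservation around bound sites vs control sites.

    Sites are rows with chrom, pos (and optionally strand, which orients
    the profile).  For each site the score vector over
    [pos - flank, pos + flank] is taken; group profiles are position-wise
    means and the test is a classical equal-variance two-sided t test on
    per-site mean scores.  Sites whose window leaves the chromosome start
    are dropped with a warning.
    """
    def collect(sites: pd.DataFrame):
        mats, dropped = [], 0
        for row in sites.itertuples(index=False):
            pos = int(row.pos)
            if pos - flank < 0:
                dropped += 1
                continue
            v = track.values(row.chrom, pos - flank, pos + flank + 1)
            if getattr(row, "strand", "+") == "-":
                v = v[::-1]
            mats.append(v)
        if dropped:
            logger.warning("%d sites within %d nt of a chromosome start dropped",
                           dropped, flank)
        if not mats:
            raise UtrFeatureError("no usable sites for conservation comparison")
        return np.vstack(mats)

    tm = collect(target_sites)
    cm = collect(control_sites)
    t_means, c_means = tm.mean(axis=1), cm.mean(axis=1)
    if np.var(t_means) == 0.0 and np.var(c_means) == 0.0:
        # degenerate (e.g. constant track): no evidence of separation
        equal = t_means.mean() == c_means.mean()
        t_stat, p = (0.0, 1.0) if equal else (np.inf, 0.0)
    else:
        t_stat, p = stats.ttest_ind(t_means, c_means, equal_var=True)
    return {
        "offsets": np.arange(-flank, flank + 1),
        "target_profile": tm.mean(axis=0),
        "control_profile": cm.mean(axis=0),
        "target_site_means": t_means,
        "control_site_means": c_means,
        "t": float(t_stat), "p": float(p),
        "n_target": tm.shape[0], "n_control": cm.shape[0],
    }


# ---------------------------------------------------------------------------
# UTR length comparison
# ---------------------------------------------------------------------------

def utr_length_test(target_lengths, control_lengths) -> tuple[float, float]:
    """Mann-Whitney U (two-sided) on UTR lengths: exact enumeration of all
    rank assignments when both samples have n <= 8 (tie-aware), otherwise
    the normal approximation with tie correction."""
    x = np.asarray(target_lengths, dtype=float)
    y = np.asarray(control_lengths, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UtrFeatureError("both length samples must be non-empty")
    if x.size <= 8 and y.size <= 8:
        return _exact_mwu(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _exact_mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    from itertools import combinations

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks handle ties
    n1, n = x.size, pooled.size
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = np.array([
        ranks[list(c)].sum() - n1 * (n1 + 1) / 2.0
        for c in combinations(range(n), n1)
    ])
    # two-sided by doubling the smaller tail (cap at 1)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return float(u_obs), float(p)


# ---------------------------------------------------------------------------
# per-UTR summary
# ---------------------------------------------------------------------------

def utr_summary_table(
    records: list[UTRRecord], config: MotifConfig = MotifConfig()
) -> pd.DataFrame:
    """Per-UTR feature table: length, PAS count, full-QBM count, QRE count."""
    rows = []
    for r in records:
        rows.append({
            "transcript_id": r.transcript_id,
            "length": r.length,
            "n_pas": count_pas(r.utr_sequence, config),
            "n_qbm_full": len(scan_motif(r.utr_sequence, config.qbm_full)),
            "n_qre": len(find_qres(r.utr_sequence, config)),
            "site": r.site,
        })
    return pd.DataFrame(rows)
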