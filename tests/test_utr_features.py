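"""Motif scanning, QREs, matched controls, conservation, relative position."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from qclip.utr_features import (
    ConservationTrack,
    MotifConfig,
    UtrFeatureError,
    UTRRecord,
    _exact_mwu,
    conservation_flank_compare,
    count_pas,
    find_qres,
    relative_position,
    scan_motif,
    select_matched_controls,
    utr_length_test,
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T", "Y": "CT",
}


def brute_force_scan(seq, pattern):
    """Position-wise oracle: expand the pattern and test every start."""
    seq = seq.upper().replace("U", "T")
    toks = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            toks.append(set(pattern[i + 1 : j]))
            i = j + 1
        else:
            toks.append(set(_IUPAC[pattern[i]]))
            i += 1
    out = []
    for s in range(len(seq) - len(toks) + 1):
        if all(seq[s + k] in t for k, t in enumerate(toks)):
            out.append(s)
    return out


class TestScanMotif:
    def test_qbm_example(self):
        assert scan_motif("GGACUAACGG", "ACUAAY") == [2]

    def test_pas_overlapping_matches(self):
        assert scan_motif("AATAAATAAA", "A[AT]TAAA") == [0, 4]

    def test_no_match(self):
        assert scan_motif("AAAAAA", "ACUAAY") == []

    def test_pattern_longer_than_sequence(self):
        assert scan_motif("ACU", "ACUAAY") == []

    def test_n_matches_nothing(self):
        assert scan_motif("ACTNAC", "ACTAAC") == []

    @pytest.mark.parametrize("pattern", ["ACUAAY", "YAAY", "A[AT]TAAA"])
    def test_matches_brute_force_on_random_sequences(self, pattern, rng):
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            assert scan_motif(seq, pattern) == brute_force_scan(seq, pattern)

    @given(st.text(alphabet="ACGTU", min_size=0, max_size=80))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_t_u_equivalence(self, seq):
        swapped = seq.replace("T", "t").replace("U", "T").replace("t", "U")
        for pat in ("ACUAAY", "YAAY", "A[AT]TAAA"):
            assert scan_motif(seq, pat) == scan_motif(swapped, pat)


class TestFindQres:
    def test_cpe_style_example(self):
        hits = find_qres("GGACUAACGGGGUAAUGG")
        assert len(hits) == 1
        h = hits[0]
        assert (h.full_start, h.half_start, h.gap) == (2, 12, 4)

    def test_lone_full_site_self_pairing_forbidden(self):
        assert find_qres("ACUAAU") == []

    def test_half_site_upstream_allowed(self):
        hits = find_qres("UAAUGGGGACUAAC")
        assert len(hits) == 1
        assert hits[0].half_start == 0 and hits[0].gap == 4

    def test_gap_limit(self):
        seq = "ACUAAC" + "G" * 21 + "UAAU"
        assert find_qres(seq) == []
        seq = "ACUAAC" + "G" * 20 + "UAAU"
        assert len(find_qres(seq)) == 1

    def test_matches_brute_force_double_loop(self, rng):
        cfg = MotifConfig()
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            fulls = brute_force_scan(seq, cfg.qbm_full)
            halves = brute_force_scan(seq, cfg.qbm_half)
            want = set()
            for f in fulls:
                for h in halves:
                    if h + 4 <= f and f - (h + 4) <= cfg.max_gap:
                        want.add((f, h))
                    elif h >= f + 6 and h - (f + 6) <= cfg.max_gap:
                        want.add((f, h))
            got = {(q.full_start, q.half_start) for q in find_qres(seq, cfg)}
            assert got == want


class TestCountPas:
    @pytest.mark.parametrize("seq,n", [
        ("GCAATAAAGC", 1),
        ("ATTAAA", 1),
        ("AATAAATAAA", 2),
        ("GGGGGG", 0),
    ])
    def test_examples(self, seq, n):
        assert count_pas(seq) == n


class TestMatchedControls:
    def _records(self, lengths, prefix):
        return [
            UTRRecord(transcript_id=f"{prefix}{i}", utr_sequence="A" * L)
            for i, L in enumerate(lengths)
        ]

    def test_exact_length_pool(self):
        targets = self._records([100, 200, 300], "t")
        pool = self._records([100, 200, 300, 400, 500], "c")
        ctl = select_matched_controls(targets, pool, seed=0)
        assert sorted(c.length for c in ctl) == [100, 200, 300]
        for c in ctl:
            assert c.site is not None and 0 <= c.site < c.length

    def test_deterministic(self):
        targets = self._records([120, 260, 340], "t")
        pool = self._records(list(range(100, 400, 17)), "c")
        c1 = select_matched_controls(targets, pool, seed=7)
        c2 = select_matched_controls(targets, pool, seed=7)
        assert [(c.transcript_id, c.site) for c in c1] == \
            [(c.transcript_id, c.site) for c in c2]

    def test_length_distribution_not_significant(self, rng):
        tl = rng.lognormal(6, 0.5, size=60).astype(int) + 50
        pl = rng.lognormal(6, 0.5, size=600).astype(int) + 50
        targets = self._records(tl, "t")
        pool = self._records(pl, "c")
        ctl = select_matched_controls(targets, pool, seed=1)
        _, p = utr_length_test([t.length for t in targets],
                               [c.length for c in ctl])
        assert p > 0.05

    def test_pool_too_small(self):
        with pytest.raises(UtrFeatureError, match="pool"):
            select_matched_controls(self._records([100, 200], "t"),
                                    self._records([100], "c"))

    def test_expression_filter(self):
        targets = self._records([100], "t")
        pool = self._records([100, 100], "c")
        expr = pd.Series({"c0": 5.0, "c1": 50.0})
        ctl = select_matched_controls(targets, pool, expression=expr, seed=0)
        assert ctl[0].transcript_id == "c1"

    def test_min_length_filter(self):
        targets = self._records([100], "t")
        pool = self._records([30, 100], "c")
        ctl = select_matched_controls(targets, pool, min_len=50, seed=0)
        assert ctl[0].transcript_id == "c1"


class TestRelativePosition:
    @pytest.mark.parametrize("site,want", [(1000, 100.0), (1500, 0.0),
                                           (1250, 50.0)])
    def test_plus_strand(self, site, want):
        r = relative_position(site, pas_pos=1500, stop_pos=1000, strand="+")
        assert r.percent == pytest.approx(want) and r.valid

    def test_minus_strand(self):
        r = relative_position(1750, pas_pos=1500, stop_pos=2000, strand="-")
        assert r.percent == pytest.approx(50.0) and r.valid

    def test_outside_span_invalid(self):
        r = relative_position(900, pas_pos=1500, stop_pos=1000, strand="+")
        assert not r.valid

    def test_degenerate_raises(self):
        with pytest.raises(UtrFeatureError):
            relative_position(10, pas_pos=5, stop_pos=5, strand="+")

    @given(st.integers(-10_000, 10_000), st.integers(0, 5000),
           st.integers(0, 5000), st.integers(0, 5000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_reflection_symmetry(self, pivot, a, b, c):
        """Reflecting all coordinates through a pivot and flipping strand
        leaves the percentage unchanged (exact)."""
        stop, pas, site = a, b, c
        if pas == stop:
            return
        r1 = relative_position(site, pas, stop, "+")
        r2 = relative_position(2 * pivot - site, 2 * pivot - pas,
                               2 * pivot - stop, "-")
        assert r1.percent == pytest.approx(r2.percent, abs=1e-9)
        assert r1.valid == r2.valid


class TestConservation:
    def _track(self, chrom="c", start=0, end=2000, value=1.5):
        return ConservationTrack(pd.DataFrame({
            "chrom": [chrom], "start": [start], "end": [end],
            "score": [value],
        }))

    def test_constant_track_t_zero(self):
        tr = self._track()
        sites = pd.DataFrame({"chrom": "c", "pos": [500, 700], "strand": "+"})
        ctl = pd.DataFrame({"chrom": "c", "pos": [900, 1100], "strand": "+"})
        res = conservation_flank_compare(sites, ctl, tr, flank=100)
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)
        assert np.allclose(res["target_profile"], 1.5)

    def test_missing_bases_are_zero(self):
        tr = self._track(start=0, end=10)
        v = tr.values("c", 0, 20)
        assert np.allclose(v[:10], 1.5) and np.allclose(v[10:], 0.0)
        assert tr.n_missing_queried == 10

    def test_t_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.5, 3.5, 1.0, 4.0])
        nx, ny = len(x), len(y)
        sp = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
        t_hand = (x.mean() - y.mean()) / (sp * np.sqrt(1 / nx + 1 / ny))
        p_hand = 2 * stats.t.sf(abs(t_hand), nx + ny - 2)
        t_got, p_got = stats.ttest_ind(x, y, equal_var=True)
        assert t_got == pytest.approx(t_hand, abs=1e-12)
        assert p_got == pytest.approx(p_hand, abs=1e-12)

    def test_planted_bump_recovered(self, default_genome):
        """Conservation is higher around planted sites than around random
        control positions in non-target 3'UTRs."""
        g = default_genome
        idx = g.index()
        tr = ConservationTrack(g.conservation)
        tsites = pd.DataFrame({
            "chrom": [s.chrom for s in g.truth.planted_qbm_sites],
            "pos": [s.midpoint for s in g.truth.planted_qbm_sites],
            "strand": [s.strand for s in g.truth.planted_qbm_sites],
        })
        rng = np.random.default_rng(3)
        rows = []
        for t in idx.coding_transcripts():
            if t.gene_id in g.truth.target_genes or not t.three_utr:
                continue
            s, e = t.three_utr[0]
            rows.append({"chrom": t.chrom,
                         "pos": int(rng.integers(s, e)), "strand": t.strand})
            if len(rows) == 100:
                break
        res = conservation_flank_compare(tsites, pd.DataFrame(rows), tr,
                                         flank=200)
        assert res["t"] > 0 and res["p"] < 0.01


class TestUtrLengthTest:
    def test_exact_example(self):
        _, p = utr_length_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = utr_length_test([5, 6, 7, 8], [5, 6, 7, 8])
        assert p >= 0.99

    def test_asymptotic_close_to_exact_at_n8(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        _, p_exact = _exact_mwu(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        assert res.pvalue == pytest.approx(p_exact, rel=0.10)

    def test_empty_raises(self):
        with pytest.raises(UtrFeatureError):
            utr_length_test([], [1, 2])
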