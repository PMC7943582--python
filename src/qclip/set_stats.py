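"""Gene-set overlap and abundance-shift statistics.

Fisher's exact tests on 2x2 set-overlap tables with cross-product odds
ratios (Haldane-corrected) and Woolf log-interval CIs; the CLIP-target
abundance-shift t test (mean percent change of target transcripts after
knockout); maturation-set overlap tests (knockout-up vs immature, and
knockout-down vs mature gene sets); and simple proportion summaries with
Wilson score intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .count_model import nb_glm_lrt


class SetStatsError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """a = |A and B|, b = |A only|, c = |B only|, d = |neither|."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise SetStatsError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class OverlapResult:
    table: ContingencyTable
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    alternative: str
    pct_b_in_a: float     # |A ∩ B| / |B| * 100 ("x% of B are also in A")
    pct_a_in_b: float


def fisher_exact(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher's exact p by hypergeometric summation; 'two_sided' sums all
    tables with probability <= the observed one."""
    alt = {"two_sided": "two-sided"}.get(alternative, alternative)
    if alt not in ("greater", "less", "two-sided"):
        raise SetStatsError(f"unknown alternative {alternative!r}")
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=alt
    )
    return float(p)


def _odds_ratio_ci(t: ContingencyTable) -> tuple[float, tuple[float, float]]:
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:  # Haldane correction
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
    return float(orr), (float(lo), float(hi))


def overlap_test(
    set_a: set, set_b: set, universe: set, alternative: str = "greater"
) -> OverlapResult:
    """Fisher overlap test of two gene sets within an explicit universe."""
    if not universe:
        raise SetStatsError("empty universe")
    stray = (set_a | set_b) - set(universe)
    if stray:
        raise SetStatsError(
            f"set elements outside the universe: {sorted(stray)[:10]}"
        )
    A, B, U = set(set_a), set(set_b), set(universe)
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(U) - a - b - c
    table = ContingencyTable(a, b, c, d)
    orr, ci = _odds_ratio_ci(table)
    p = fisher_exact(table, alternative)
    return OverlapResult(
        table=table, odds_ratio=orr, ci95=ci, p=p, alternative=alternative,
        pct_b_in_a=100.0 * a / len(B) if B else float("nan"),
        pct_a_in_b=100.0 * a / len(A) if A else float("nan"),
    )


@dataclass
class ShiftResult:
    mean_log2fc_targets: float
    mean_log2fc_background: float
    mean_percent_change: float
    t: float
    p: float
    n_targets: int
    n_background: int
    ecdf_targets: np.ndarray      # sorted log2FCs (x of the ECDF)
    ecdf_background: np.ndarray


def clip_target_shift(de: pd.DataFrame, targets: set[str]) -> ShiftResult:
    """Two-sided Student's t test of target vs non-target log2 fold changes,
    with the mean shift expressed as a percent change
    (100 * (2^mean_log2FC - 1))."""
    idx_t = [g for g in de.index if g in targets]
    idx_b = [g for g in de.index if g not in targets]
    if len(idx_t) < 3:
        raise SetStatsError("fewer than 3 targets among tested features")
    x = de.loc[idx_t, "log2FC"].to_numpy(dtype=float)
    y = de.loc[idx_b, "log2FC"].to_numpy(dtype=float)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    mt = float(x.mean())
    return ShiftResult(
        mean_log2fc_targets=mt,
        mean_log2fc_background=float(y.mean()),
        mean_percent_change=100.0 * (2.0 ** mt - 1.0),
        t=float(t), p=float(p),
        n_targets=x.size, n_background=y.size,
        ecdf_targets=np.sort(x), ecdf_background=np.sort(y),
    )


def derive_de_sets(
    counts: pd.DataFrame, groups: pd.Series, contrast: tuple[str, str],
    p_threshold: float = 0.05, dispersion=0.1, norm_factors=None,
) -> tuple[set[str], set[str]]:
    """Up/down gene sets at unadjusted p < threshold for the contrast
    (used to derive immature/mature maturation sets from count matrices)."""
    de = nb_glm_lrt(counts, groups, contrast, norm_factors=norm_factors,
                    dispersion=dispersion)
    sig = de[de["p"] < p_threshold]
    up = set(sig.index[sig["log2FC"] > 0])
    down = set(sig.index[sig["log2FC"] < 0])
    return up, down


def maturation_shift(
    ko_up: set[str], ko_down: set[str],
    p7_set: set[str], p32_set: set[str],
    universe: set[str],
) -> dict:
    """Test whether knockout-up genes over-represent the immature (P7-like)
    set and knockout-down genes the mature (P32-like) set (one-sided Fisher),
    and list the genes falling in both a knockout set and a maturation set."""
    up_res = overlap_test(ko_up, p7_set, universe, alternative="greater")
    down_res = overlap_test(ko_down, p32_set, universe, alternative="greater")
    table = pd.DataFrame(
        [
            *[{"gene": g, "ko_direction": "up", "maturation_set": "P7"}
              for g in sorted(ko_up & p7_set)],
            *[{"gene": g, "ko_direction": "down", "maturation_set": "P32"}
              for g in sorted(ko_down & p32_set)],
        ],
        columns=["gene", "ko_direction", "maturation_set"],
    )
    return {"up_vs_p7": up_res, "down_vs_p32": down_res, "genes": table}


def proportion_summary(positive: int, total: int) -> dict:
    """Percent positive with a Wilson 95% score interval."""
    if total <= 0:
        raise SetStatsError("total must be positive")
    if not 0 <= positive <= total:
        raise SetStatsError("positive must lie in [0, total]")
    lo, hi = proportion_confint(positive, total, alpha=0.05, method="wilson")
    return {
        "percent": 100.0 * positive / total,
        "ci_lo": 100.0 * float(lo),
        "ci_hi": 100.0 * float(hi),
        "positive": positive,
        "total": total,
    }
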