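"""Shared count-statistics engine for enrichment and differential expression.

Implements the edgeR-style gene/peak count workflow: low-count filtering,
TMM (trimmed mean of M-values) normalization, negative-binomial dispersion
estimation by Cox-Reid adjusted profile likelihood, and NB log-linear GLM
fits with likelihood-ratio tests.  Used both for dual-background CLIP peak
enrichment (CLIP replicates vs IgG, vs Input) and for TRAP knockout /
TRAP-vs-Input differential expression.

GLM fits use an in-package Newton solver specialized to one-way (group)
designs, vectorized across features; coefficients for a one-way layout are
separable per group, so each group mean is a one-dimensional root-finding
problem solved simultaneously for all features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class CountModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_min_count(
    counts: pd.DataFrame, min_count: int = 5, min_samples: int = 2
) -> pd.DataFrame:
    """Retain features with raw count >= min_count in >= min_samples samples."""
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    logger.info("filter_min_count: retained %d / %d features",
                int(keep.sum()), len(counts))
    if keep.sum() == 0:
        raise CountModelError(
            "no features pass the count filter; review min_count/min_samples"
        )
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame, m_trim: float = 0.30, a_trim: float = 0.05,
    lib_sizes: pd.Series | None = None,
) -> pd.Series:
    """TMM normalization factors (geometric mean 1).

    Reference sample: the one whose upper-quartile of library-size-scaled
    counts is closest to the mean upper-quartile.  Per sample, the factor is
    the inverse-variance-weighted mean of M-values against the reference
    after two-sided trimming of the most extreme 30% of M-values and 5% of
    A-values, exponentiated.
    """
    if counts.shape[1] < 2:
        raise CountModelError("TMM requires at least 2 samples")
    Y = counts.to_numpy(dtype=float)
    lib = (
        lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
        if lib_sizes is not None
        else Y.sum(axis=0)
    )
    if np.any(lib <= 0):
        raise CountModelError("TMM: sample with zero library size")
    uq = np.array([np.quantile(Y[:, j] / lib[j], 0.75) for j in range(Y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(Y.shape[1])
    yr, Nr = Y[:, ref], lib[ref]
    for j in range(Y.shape[1]):
        if j == ref:
            continue
        y, N = Y[:, j], lib[j]
        ok = (y > 0) & (yr > 0)
        if not ok.any():
            logger.warning("TMM: sample %s shares no expressed features with "
                           "reference; factor set to 1", counts.columns[j])
            continue
        yk, yrk = y[ok], yr[ok]
        M = np.log2((yk / N) / (yrk / Nr))
        A = 0.5 * np.log2((yk / N) * (yrk / Nr))
        w = (N - yk) / (N * yk) + (Nr - yrk) / (Nr * yrk)
        n = M.size
        loM = np.floor(n * m_trim) + 1
        hiM = n + 1 - loM
        loA = np.floor(n * a_trim) + 1
        hiA = n + 1 - loA
        rM = stats.rankdata(M)
        rA = stats.rankdata(A)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if keep.any() and w[keep].sum() > 0:
            f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
            factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# NB likelihood machinery (one-way designs, vectorized across features)
# ---------------------------------------------------------------------------

def nb_loglik(Y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-feature NB log-likelihood summed over samples.

    ``phi`` may be a scalar or per-feature array; phi = 0 gives Poisson.
    """
    Y = np.asarray(Y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-10)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    pois = Y * np.log(mu) - mu - special.gammaln(Y + 1.0)
    if np.all(phi == 0):
        return pois.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(phi > 0, 1.0 / np.maximum(phi, 1e-300), np.inf)
        nb = (
            special.gammaln(Y + r) - special.gammaln(r) - special.gammaln(Y + 1.0)
            + Y * np.log(phi * mu / (1.0 + phi * mu))
            - r * np.log1p(phi * mu)
        )
    ll = np.where(phi > 0, nb, pois)
    return ll.sum(axis=1)


def _fit_group_means(
    Y: np.ndarray, offsets: np.ndarray, codes: np.ndarray, phi,
    tol: float = 1e-10, maxiter: int = 100,
):
    """MLE group coefficients for mu = exp(offset + b_group), NB dispersion
    phi (scalar or per-feature).  Returns (beta [G x K], mu [G x S],
    converged [G])."""
    G, S = Y.shape
    K = int(codes.max()) + 1
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1, 1), (G, 1))
    beta = np.zeros((G, K))
    eo = np.exp(offsets)
    converged = np.ones(G, dtype=bool)
    for k in range(K):
        cols = np.where(codes == k)[0]
        yk = Y[:, cols]
        eok = eo[cols]
        zero = yk.sum(axis=1) == 0      # MLE mean is 0; pin at the floor
        b = np.log((yk.sum(axis=1) + 0.5) / eok.sum())
        step = np.zeros_like(b)
        for _ in range(maxiter):
            mu = np.exp(b[:, None] + offsets[cols][None, :])
            denom = 1.0 + phi_arr * mu
            score = ((yk - mu) / denom).sum(axis=1)
            info = (mu * (1.0 + phi_arr * yk) / denom**2).sum(axis=1)
            step = np.clip(score / np.maximum(info, 1e-12), -5.0, 5.0)
            step[zero] = 0.0
            b = b + step
            if np.max(np.abs(step)) < tol:
                break
        else:
            converged &= (np.abs(step) < 1e-4) | zero
        b[zero] = -50.0
        beta[:, k] = np.clip(b, -50.0, 50.0)
    mu = np.exp(beta[:, codes] + offsets[None, :])
    return beta, mu, converged


def _adjusted_profile_loglik(
    Y: np.ndarray, offsets: np.ndarray, codes: np.ndarray, phi,
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per feature at dispersion phi:
    ll(beta_hat) - 0.5 * sum_k log(sum_{s in k} W_s), W = mu/(1+phi*mu)."""
    G = Y.shape[0]
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1, 1), (G, 1))
    _, mu, _ = _fit_group_means(Y, offsets, codes, phi)
    ll = nb_loglik(Y, mu, phi_arr[:, 0])
    W = mu / (1.0 + phi_arr * mu)
    adj = np.zeros(G)
    for k in range(int(codes.max()) + 1):
        cols = np.where(codes == k)[0]
        adj += 0.5 * np.log(np.maximum(W[:, cols].sum(axis=1), 1e-12))
    return ll - adj


@dataclass
class DispersionEstimate:
    common: float
    tagwise: np.ndarray          # per retained feature, aligned to the matrix
    prior_df: float
    feature_ids: list


def estimate_dispersion(
    counts: pd.DataFrame, groups: pd.Series,
    norm_factors: pd.Series | None = None, prior_df: float = 50.0,
    lib_sizes: pd.Series | None = None,
) -> DispersionEstimate:
    """Common and tagwise NB dispersions.

    The common dispersion maximizes the mean Cox-Reid adjusted profile
    likelihood across features; tagwise values maximize the per-feature APL
    plus a common-likelihood penalty with weight prior_df / residual_df
    (shrinkage toward the common value), on a fixed dispersion grid.
    """
    Y = counts.to_numpy(dtype=float)
    codes, K = _group_codes(counts, groups)
    S = Y.shape[1]
    df_res = S - K
    if df_res < 1:
        raise CountModelError("no residual degrees of freedom; replicates required")
    offsets = _offsets(counts, norm_factors, lib_sizes)

    grid = np.concatenate([[1e-6], np.geomspace(1e-4, 5.0, 40)])
    apl = np.empty((Y.shape[0], grid.size))
    for i, phi in enumerate(grid):
        apl[:, i] = _adjusted_profile_loglik(Y, offsets, codes, phi)
    mean_apl = apl.mean(axis=0)
    i0 = int(np.argmax(mean_apl))
    # local quadratic refinement of the common estimate on log(phi)
    if 0 < i0 < grid.size - 1:
        lg = np.log(grid[i0 - 1 : i0 + 2])
        v = mean_apl[i0 - 1 : i0 + 2]
        d1 = (v[2] - v[0]) / (lg[2] - lg[0])
        d2 = (v[2] - 2 * v[1] + v[0]) / ((lg[2] - lg[1]) * (lg[1] - lg[0]))
        common = float(np.exp(lg[1] - d1 / d2)) if d2 < 0 else float(grid[i0])
        common = float(np.clip(common, grid[0], grid[-1]))
    else:
        common = float(grid[i0])
    weight = prior_df / df_res
    score = apl + weight * mean_apl[None, :]
    tag_idx = np.argmax(score, axis=1)
    tagwise = grid[tag_idx]
    return DispersionEstimate(
        common=common, tagwise=tagwise, prior_df=prior_df,
        feature_ids=list(counts.index),
    )


def _group_codes(counts: pd.DataFrame, groups: pd.Series):
    g = groups.reindex(counts.columns)
    if g.isna().any():
        missing = list(g.index[g.isna()])
        raise CountModelError(f"samples without group labels: {missing}")
    levels = list(dict.fromkeys(g))
    codes = np.array([levels.index(v) for v in g], dtype=np.int64)
    return codes, len(levels)


def _offsets(
    counts: pd.DataFrame, norm_factors: pd.Series | None,
    lib_sizes: pd.Series | None = None,
) -> np.ndarray:
    if lib_sizes is not None:
        lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    else:
        lib = counts.sum(axis=0).to_numpy(dtype=float)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(counts.columns).to_numpy(dtype=float)
    return np.log(lib)


# ---------------------------------------------------------------------------
# NB GLM likelihood-ratio test
# ---------------------------------------------------------------------------

def nb_glm_lrt(
    counts: pd.DataFrame, groups: pd.Series, contrast: tuple[str, str],
    norm_factors: pd.Series | None = None,
    dispersion: DispersionEstimate | float | np.ndarray = 0.1,
    prior_count: float = 0.5,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group NB GLM likelihood-ratio test.

    ``contrast = (A, B)`` tests group A against baseline group B.  Offsets
    are log(library size x TMM factor); per-feature dispersions come from
    ``dispersion`` (tagwise if a DispersionEstimate).  The LR statistic
    compares the two-group fit with the pooled fit on the contrast samples
    (other groups' coefficients cancel in a one-way layout); p from chi^2(1);
    FDR by Benjamini-Hochberg; log2FC from prior-augmented normalized group
    means (prior_count keeps zero-count fold changes finite).
    """
    a, b = contrast
    in_contrast = groups.reindex(counts.columns).isin([a, b]).to_numpy()
    if in_contrast.sum() < 3:
        raise CountModelError(f"contrast {contrast}: too few samples")
    sub = counts.loc[:, counts.columns[in_contrast]]
    g = groups.reindex(sub.columns)
    Y = sub.to_numpy(dtype=float)
    offsets = _offsets(counts, norm_factors, lib_sizes)[in_contrast]
    codes = (g == a).to_numpy().astype(np.int64)  # B=0, A=1

    if isinstance(dispersion, DispersionEstimate):
        phi = np.asarray(dispersion.tagwise, dtype=float)
        if phi.size != len(counts):
            raise CountModelError("dispersion estimate does not match matrix")
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (len(counts),))
    phi = np.ascontiguousarray(phi, dtype=float)

    _, mu_full, conv_full = _fit_group_means(Y, offsets, codes, phi)
    _, mu_red, conv_red = _fit_group_means(
        Y, offsets, np.zeros_like(codes), phi
    )
    ll_full = nb_loglik(Y, mu_full, phi)
    ll_red = nb_loglik(Y, mu_red, phi)
    lr = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    converged = conv_full & conv_red
    p = np.where(converged, stats.chi2.sf(lr, df=1), np.nan)

    fdr = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]

    # prior-augmented normalized group means for the fold change
    lib_eff = np.exp(offsets)
    scale = lib_eff.mean()
    norm = Y / lib_eff[None, :] * scale
    mA = norm[:, codes == 1].mean(axis=1)
    mB = norm[:, codes == 0].mean(axis=1)
    log2fc = np.log2((mA + prior_count) / (mB + prior_count))

    n_bad = int((~converged).sum())
    if n_bad:
        logger.warning("nb_glm_lrt: %d features failed to converge", n_bad)
    return pd.DataFrame({
        "log2FC": log2fc, "LR": lr, "p": p, "FDR": fdr,
        "converged": converged,
    }, index=counts.index)


# ---------------------------------------------------------------------------
# high-confidence dual-background calls
# ---------------------------------------------------------------------------

def call_high_confidence(
    de_vs_igg: pd.DataFrame, de_vs_input: pd.DataFrame,
    fc_threshold: float = 2.0, fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Intersect the two enrichment contrasts: a peak passes when its fold
    change exceeds ``fc_threshold`` and its FDR is below ``fdr_threshold``
    against both the IgG and the Input background."""
    missing = set(de_vs_igg.index).symmetric_difference(de_vs_input.index)
    if missing:
        raise CountModelError(
            f"peak id mismatch between contrasts: {sorted(missing)[:10]}..."
            if len(missing) > 10 else
            f"peak id mismatch between contrasts: {sorted(missing)}"
        )
    lfc_thr = np.log2(fc_threshold)
    out = pd.DataFrame({
        "log2FC_vs_igg": de_vs_igg["log2FC"],
        "log2FC_vs_input": de_vs_input.loc[de_vs_igg.index, "log2FC"],
        "fdr_vs_igg": de_vs_igg["FDR"],
        "fdr_vs_input": de_vs_input.loc[de_vs_igg.index, "FDR"],
    })
    out["pass"] = (
        (out["log2FC_vs_igg"] > lfc_thr)
        & (out["log2FC_vs_input"] > lfc_thr)
        & (out["fdr_vs_igg"] < fdr_threshold)
        & (out["fdr_vs_input"] < fdr_threshold)
    )
    return out


def astrocyte_enrichment_check(
    trap_vs_input: pd.DataFrame, positive_set: set[str], negative_set: set[str],
) -> dict:
    """TRAP quality gate: median log2FC (TRAP vs Input) of positive
    (astrocyte) and negative (e.g. neuron) marker sets, and a two-sided
    rank-sum p for their separation."""
    tested = set(trap_vs_input.index)
    pos = sorted(positive_set & tested)
    neg = sorted(negative_set & tested)
    if not pos or not neg:
        raise CountModelError("marker set has no overlap with tested features")
    x = trap_vs_input.loc[pos, "log2FC"].to_numpy()
    y = trap_vs_input.loc[neg, "log2FC"].to_numpy()
    if np.array_equal(np.sort(x), np.sort(y)):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return {
        "median_log2fc_positive": float(np.median(x)),
        "median_log2fc_negative": float(np.median(y)),
        "n_positive": len(pos), "n_negative": len(neg),
        "p_separation": p,
    }
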