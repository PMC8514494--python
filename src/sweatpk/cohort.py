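"""Cohort-level statistics for sweat metabolomics time-course studies.

Covers the pre/post comparisons used on the intervention cohorts:
paired Wilcoxon signed-rank (exact, tie-aware) and paired t tests,
normality checks (D'Agostino-Pearson omnibus, Lilliefors KS), a
Perseus-style s0-moderated volcano with permutation-based FDR control,
shared-control bootstrap effect sizes, PCA of metabolite profiles or of
fitted kinetic constants, and pairwise correlation of the caffeine
conversion constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import DomainError, InputError

__all__ = [
    "WilcoxonResult",
    "VolcanoConfig",
    "PCAResult",
    "wilcoxon_signed_rank",
    "paired_t",
    "dagostino_pearson",
    "lilliefors_ks",
    "s0_volcano",
    "shared_control_bootstrap",
    "pca",
    "k_correlation_summary",
]


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    w_minus: float
    p_value: float
    n_used: int  # pairs remaining after zero-difference removal
    mode: str


def _signed_rank_setup(pre, post) -> tuple[np.ndarray, np.ndarray]:
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise InputError("pre and post must be 1-D arrays of equal length")
    if pre.size < 2:
        raise InputError("need at least 2 pairs")
    d = post - pre
    d = d[d != 0]  # zero differences discarded
    if d.size == 0:
        raise DomainError("degenerate: all differences are zero")
    ranks = stats.rankdata(np.abs(d))  # midranks for ties
    return d, ranks


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-tailed p by convolution over the (doubled) midranks.

    Enumerates the null distribution of W+ over all 2^n sign
    assignments; midranks are doubled so all achievable rank sums are
    integers even with ties.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _approx_signed_rank_p(d: np.ndarray, ranks: np.ndarray,
                          w_plus: float) -> float:
    """Normal approximation with tie and continuity corrections."""
    n = d.size
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 \
        - np.sum(tie_counts ** 3 - tie_counts) / 48.0
    dev = w_plus - mu
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wilcoxon_signed_rank(pre, post, mode: str = "auto") -> WilcoxonResult:
    """Two-tailed paired Wilcoxon signed-rank test.

    Zero differences are discarded; tied absolute differences receive
    midranks.  ``mode='exact'`` enumerates all sign assignments (used
    automatically for n <= 25); ``'approx'`` uses the normal
    approximation with continuity and tie corrections.
    """
    d, ranks = _signed_rank_setup(pre, post)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if mode == "auto":
        mode = "exact" if d.size <= 25 else "approx"
    if mode == "exact":
        p = _exact_signed_rank_p(ranks, w_plus)
    elif mode == "approx":
        p = _approx_signed_rank_p(d, ranks, w_plus)
    else:
        raise InputError("mode must be 'auto', 'exact' or 'approx'")
    return WilcoxonResult(w_plus, w_minus, p, d.size, mode)


def paired_t(pre, post) -> tuple[float, int, float]:
    """Two-tailed paired t test; returns (t, df, p)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise InputError("pre and post must be 1-D arrays of equal length")
    n = pre.size
    if n < 2:
        raise InputError("need at least 2 pairs")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return float(t), df, p


def dagostino_pearson(values) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test; returns (K^2, p)."""
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise InputError("D'Agostino-Pearson requires n >= 8")
    if np.ptp(v) == 0:
        raise InputError("constant sample: test undefined")
    k2, p = stats.normaltest(v)
    return float(k2), float(p)


def lilliefors_ks(values) -> float:
    """Lilliefors Kolmogorov-Smirnov normality test p-value
    (Dallal-Wilkinson approximation)."""
    from statsmodels.stats.diagnostic import lilliefors

    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InputError("Lilliefors test requires n >= 4")
    if np.ptp(v) == 0:
        raise InputError("constant sample: test undefined")
    _, p = lilliefors(v, dist="norm", pvalmethod="approx")
    return float(p)


@dataclass(frozen=True)
class VolcanoConfig:
    """s0-volcano settings: minimal fold change s0 added to the SEM,
    target FDR, number of sign-flip permutations (full enumeration is
    used when 2^n does not exceed it), RNG seed."""

    s0: float = 0.1
    fdr: float = 0.05
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise DomainError("s0 must be >= 0")
        if not 0 < self.fdr < 1:
            raise DomainError("fdr must be in (0, 1)")
        if self.n_permutations < 1:
            raise DomainError("n_permutations must be >= 1")


def _t_s0(d: np.ndarray, s0: float) -> np.ndarray:
    """Moderated paired statistic mean(d) / (SEM(d) + s0) per row."""
    n = d.shape[1]
    mean = d.mean(axis=1)
    sem = d.std(axis=1, ddof=1) / np.sqrt(n)
    return mean / (sem + s0)


def s0_volcano(pre_matrix, post_matrix,
               config: VolcanoConfig = VolcanoConfig()) -> pd.DataFrame:
    """Perseus-style paired volcano with permutation-based FDR.

    Inputs are metabolite x subject matrices of matched pre/post
    values.  For each metabolite the moderated statistic
    t_s0 = mean(d) / (SEM(d) + s0) is computed on the paired
    differences; the reported p is the parametric two-tailed t
    probability of t_s0 (df = n-1), and significance is decided by a
    SAM-type procedure: subject-wise sign-flip permutations build the
    null of |t_s0|, and the widest |t| cutoff whose estimated FDR stays
    at or below the configured level is applied.

    Returns a DataFrame with mean_diff, t_s0, neg_log10_p, significant;
    the chosen cutoff is stored in ``.attrs['t_cutoff']``.
    """
    pre = np.atleast_2d(np.asarray(pre_matrix, dtype=float))
    post = np.atleast_2d(np.asarray(post_matrix, dtype=float))
    if pre.shape != post.shape:
        raise InputError("pre and post matrices must have the same shape")
    n_met, n = pre.shape
    if n < 2:
        raise InputError("need at least 2 subjects")
    d = post - pre

    t_obs = _t_s0(d, config.s0)
    p = 2.0 * stats.t.sf(np.abs(t_obs), n - 1)

    # sign-flip null, shared flips across metabolites within a permutation
    if 2 ** n <= config.n_permutations:
        signs = np.array(
            [[1 if (b >> j) & 1 else -1 for j in range(n)]
             for b in range(2 ** n)], dtype=float)
    else:
        rng = np.random.default_rng(config.seed)
        signs = rng.choice([-1.0, 1.0], size=(config.n_permutations, n))
    B = signs.shape[0]
    mean_b = (d @ signs.T) / n                      # (n_met, B)
    ss = np.sum(d * d, axis=1, keepdims=True)       # invariant to flips
    var_b = np.maximum(ss - n * mean_b ** 2, 0.0) / (n - 1)
    sem_b = np.sqrt(var_b) / np.sqrt(n)
    null_abs = np.abs(mean_b / (sem_b + config.s0))  # (n_met, B)

    abs_obs = np.abs(t_obs)
    null_sorted = np.sort(null_abs.ravel())
    cutoff = np.inf
    for c in np.sort(np.unique(abs_obs))[::-1]:
        n_disc = int(np.sum(abs_obs >= c))
        n_null = null_sorted.size - np.searchsorted(null_sorted, c, "left")
        est_fdr = (n_null / B) / max(n_disc, 1)
        if est_fdr <= config.fdr:
            cutoff = c  # widen the rejection region while FDR holds
        else:
            break
    significant = abs_obs >= cutoff

    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(p)
    out = pd.DataFrame(
        {
            "mean_diff": d.mean(axis=1),
            "t_s0": t_obs,
            "neg_log10_p": neg_log10_p,
            "significant": significant,
        }
    )
    out.attrs["t_cutoff"] = float(cutoff)
    out.attrs["seed"] = config.seed
    out.attrs["s0"] = config.s0
    out.attrs["fdr"] = config.fdr
    return out


def shared_control_bootstrap(control, groups: dict, n_boot: int = 5000,
                             seed: int = 0) -> pd.DataFrame:
    """Percentile-bootstrap effect sizes against a shared control.

    For each group, the difference of means group - control is
    bootstrapped (both samples resampled with replacement) and the 95%
    percentile interval reported.  Deterministic given the seed.
    """
    control = np.asarray(control, dtype=float)
    if control.size == 0:
        raise InputError("control must be non-empty")
    if n_boot < 1000:
        raise InputError("n_boot must be >= 1000")
    rng = np.random.default_rng(seed)
    rows = []
    for name, values in groups.items():
        g = np.asarray(values, dtype=float)
        if g.size == 0:
            raise InputError(f"group '{name}' is empty")
        g_means = g[rng.integers(0, g.size, (n_boot, g.size))].mean(axis=1)
        c_means = control[
            rng.integers(0, control.size, (n_boot, control.size))
        ].mean(axis=1)
        diffs = g_means - c_means
        lo, hi = np.percentile(diffs, [2.5, 97.5])
        rows.append((name, g.mean() - control.mean(), float(lo), float(hi)))
    return pd.DataFrame(
        rows, columns=["group", "mean_diff", "ci_low", "ci_high"]
    ).set_index("group")


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray              # (n_rows, n_components)
    loadings: np.ndarray            # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    kept_rows: np.ndarray           # indices surviving the NaN-row drop


def pca(matrix, n_components: int | None = None,
        standard_scale: bool = True) -> PCAResult:
    """PCA with optional column standardization (z-scores).

    Rows containing missing values are dropped before decomposition;
    a constant column under scaling raises an error.
    """
    from sklearn.decomposition import PCA as SKPCA

    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise InputError("matrix must be 2-D")
    kept = np.where(~np.isnan(X).any(axis=1))[0]
    X = X[kept]
    if X.shape[0] < 2:
        raise InputError("need at least 2 complete rows")
    if standard_scale:
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise InputError("constant column: cannot standard-scale")
        X = (X - X.mean(axis=0)) / sd
    model = SKPCA(n_components=n_components)
    scores = model.fit_transform(X)
    return PCAResult(
        scores=scores,
        loadings=model.components_,
        explained_variance_ratio=model.explained_variance_ratio_,
        kept_rows=kept,
    )


def k_correlation_summary(matrix) -> pd.DataFrame:
    """Pearson correlations among the caffeine conversion/elimination
    constants k2-k5 across volunteer profiles."""
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        X = np.asarray(matrix, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise InputError("expected a (profiles x 4) matrix of k2..k5")
        df = pd.DataFrame(X, columns=["k2", "k3", "k4", "k5"])
    return df.corr(method="pearson")
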