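"""Molecular predictors of morphological clusters and features.

Two complementary screens link gene expression to colony morphology:

1. **Cluster discrimination** — for each morphological cluster, genes are
   ranked one-vs-rest by the moderated t-statistic: ordinary per-gene
   residual variances ``s_g^2`` (``d_g`` degrees of freedom) are shrunk
   toward an empirical-Bayes prior fitted across all genes, giving posterior
   variances

       s_tilde_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

   with the prior ``(d0, s0^2)`` estimated by closed-form moment matching on
   log-variances (Smyth's estimator).  P-values come from the t distribution
   with ``d0 + d_g`` degrees of freedom and are Benjamini-Hochberg adjusted.

2. **Feature regression** — each gene is screened against a per-line
   morphological feature (median colony size by default).  The linear screen
   uses the Pearson correlation r (the square root of the coefficient of
   determination of the least-squares line).  The logistic screen first
   min-max normalizes the feature into (eps, 1-eps) and applies the logit
   transform z = ln(y / (1 - y)); the Pearson correlation between expression
   and z measures the quality of the logistic fit.  P-values are computed by
   permutation within a sign taxonomy: for observed r > 0,
   p = (1/M) * #{permuted r >= r}; for observed r < 0,
   p = (1/M) * #{permuted r <= r}; BH adjustment is applied within each
   taxonomy.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "collapse_replicates",
    "squeeze_variances",
    "moderated_t_one_vs_rest",
    "linear_association",
    "logistic_association",
    "normalize_feature",
    "permutation_pvalue",
    "permutation_screen",
    "bh_fdr",
    "ModeratedTTest",
    "PermutationAssociation",
]


def collapse_replicates(raw: pd.DataFrame, line_of: Mapping[str, str],
                        method: str = "mean") -> pd.DataFrame:
    """Collapse replicate columns to one column per line (mean or median)."""
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    missing = set(raw.columns) - set(line_of)
    if missing:
        raise ValueError(f"no line assignment for columns: {sorted(missing)}")
    lines = list(dict.fromkeys(line_of[c] for c in raw.columns))
    cols = {}
    for ln in lines:
        reps = [c for c in raw.columns if line_of[c] == ln]
        if not reps:
            raise ValueError(f"line {ln!r} has zero replicates")
        block = raw[reps]
        cols[ln] = block.mean(axis=1) if method == "mean" else block.median(axis=1)
    return pd.DataFrame(cols)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-gene variances.

    Fits a scaled inverse chi-square prior with ``d0`` degrees of freedom and
    scale ``s0^2`` to the observed variances ``s2`` (each with ``df`` residual
    degrees of freedom) by moment matching on log-variances, then returns
    ``(d0, s0^2, posterior variances)``.  ``d0`` may be ``inf``, in which
    case every posterior variance equals ``s0^2``.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all gene variances are zero; cannot fit prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = e.size
    if n < 2:
        warnings.warn("too few genes to estimate the variance prior; "
                      "falling back to ordinary t (d0 = 0)")
        return 0.0, float(np.exp(e.mean())) if n else 1.0, s2.copy()
    e_bar = float(e.mean())
    var_e = float(np.sum((e - e_bar) ** 2) / (n - 1))
    resid = var_e - float(special.polygamma(1, df / 2.0))
    if resid <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_bar))
        post = np.full_like(s2, s0_2)
        return d0, s0_2, post
    d0 = 2.0 * _trigamma_inverse(resid)
    s0_2 = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return float(d0), s0_2, post


def moderated_t_one_vs_rest(
    expr: pd.DataFrame,
    labels: Mapping[str, int] | pd.Series,
    target_cluster: int,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group t-test of ``target_cluster`` vs all other lines.

    ``expr`` is genes x lines (normalized log scale, replicates collapsed);
    ``labels`` maps each line to its morphological cluster.  Returns a table
    sorted by p-value with columns: beta (group mean difference), s2, df,
    d0, s0_2, s2_post, t, p_value, fdr, direction.

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary t-test; ``inf`` fully shrinks every variance to the prior).
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    lines = [c for c in expr.columns]
    missing = set(lines) - set(labels.index)
    if missing:
        raise ValueError(f"no cluster label for lines: {sorted(missing)}")
    in_target = np.array([labels[ln] == target_cluster for ln in lines])
    n1, n2 = int(in_target.sum()), int((~in_target).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both the target cluster and the rest need >= 2 lines")

    X = expr.to_numpy(dtype=float)
    x1, x2 = X[:, in_target], X[:, ~in_target]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    beta = m1 - m2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = ss / df

    if X.shape[0] == 1:
        warnings.warn("single gene: prior estimation impossible; using ordinary t")
        d0, s0_2, s2_post = 0.0, float(s2[0]), s2.copy()
    elif d0_override is not None:
        d0 = float(d0_override)
        _, s0_2, _ = squeeze_variances(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
        elif d0 == 0:
            s2_post = s2.copy()
        else:
            s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0, s0_2, s2_post = squeeze_variances(s2, df)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    df_total = d0 + df
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isfinite(t), p, 1.0)

    out = pd.DataFrame({
        "gene_id": expr.index,
        "beta": beta,
        "s2": s2,
        "df": df,
        "d0": d0,
        "s0_2": s0_2,
        "s2_post": s2_post,
        "t": t,
        "p_value": p,
        "fdr": bh_fdr(p),
        "direction": np.where(beta >= 0, "+", "-"),
    }).set_index("gene_id")
    return out.sort_values("p_value")


def linear_association(expr_row: np.ndarray, feature: np.ndarray
                       ) -> tuple[float, float, float, float]:
    """Least-squares fit of feature = a + b * expression; returns (a, b, r, R^2).

    The Pearson product-moment correlation r is the signed square root of the
    coefficient of determination of the least-squares line.
    """
    x = np.asarray(expr_row, dtype=float)
    y = np.asarray(feature, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.sum((x - x.mean()) * (y - y.mean())) / ((x.size - 1) * sx * sy))
    b = r * sy / sx
    a = float(y.mean() - b * x.mean())
    return a, float(b), r, r * r


def normalize_feature(y: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Min-max normalize a feature into the open interval (eps, 1 - eps)."""
    y = np.asarray(y, dtype=float)
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise ValueError("constant feature cannot be normalized for the logistic model")
    return eps + (1.0 - 2.0 * eps) * (y - lo) / (hi - lo)


def logistic_association(expr_row: np.ndarray, feature01: np.ndarray
                         ) -> tuple[float, float, float]:
    """Logistic-fit quality via the logit transform; returns (a, b, r_logistic).

    ``feature01`` must lie strictly inside (0, 1).  The transform
    z = ln(y / (1 - y)) linearizes the logistic curve y = 1/(1 + exp(-(a + b x)));
    (a, b) are the least-squares coefficients of z on x, and the Pearson r
    between x and z measures the logistic fit quality.
    """
    y = np.asarray(feature01, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("logistic feature values must lie strictly in (0, 1); "
                         "normalize (and clip) first")
    z = special.logit(y)
    x = np.asarray(expr_row, dtype=float)
    sx, sz = x.std(ddof=1), z.std(ddof=1)
    if sx == 0 or sz == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.sum((x - x.mean()) * (z - z.mean())) / ((x.size - 1) * sx * sz))
    b = r * sz / sx
    a = float(z.mean() - b * x.mean())
    return a, float(b), r


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / ((x.size - 1) * x.std(ddof=1) * y.std(ddof=1)))


def permutation_pvalue(observed_r: float, expr_row: np.ndarray,
                       feature: np.ndarray, M: int = 10_000, seed=None,
                       exhaustive: bool = False) -> float:
    """One-sided permutation p-value for a correlation, by sign taxonomy.

    The feature-to-line assignment is permuted M times (or exhaustively over
    all n! permutations when ``exhaustive``); for observed r > 0 the p-value
    counts permuted correlations >= r, for observed r < 0 it counts permuted
    correlations <= r.  Genes with r exactly 0 use the positive taxonomy.
    """
    if not exhaustive and M < 1:
        raise ValueError("M must be >= 1")
    x = np.asarray(expr_row, dtype=float)
    y = np.asarray(feature, dtype=float)
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(y.size))))
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perms = np.array([rng.permutation(y.size) for _ in range(M)])
    r_perm = np.array([_pearson(x, y[p]) for p in perms])
    # tolerance so that exact ties (e.g. the identity permutation) count
    # regardless of floating-point round-off
    if observed_r >= 0:
        return float(np.mean(r_perm >= observed_r - 1e-12))
    return float(np.mean(r_perm <= observed_r + 1e-12))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permutation_screen(
    expr: pd.DataFrame,
    feature: pd.Series | Mapping[str, float],
    link: str = "linear",
    M: int = 10_000,
    seed=None,
    eps: float = 1e-3,
) -> pd.DataFrame:
    """Screen every gene against a per-line feature with permutation p-values.

    ``expr`` is genes x lines; ``feature`` is indexed by line.  With the
    logistic link the feature is min-max normalized into (eps, 1-eps) and
    logit-transformed before correlating.  Returns a table with columns
    r, p_value (one-sided within sign taxonomy; 0 is reported as the literal
    permutation count, with ``p_lt_1_over_M`` marking values below 1/M),
    fdr (BH within taxonomy) and taxonomy, sorted by p then |r| descending.
    """
    if link not in ("linear", "logistic"):
        raise ValueError("link must be 'linear' or 'logistic'")
    feature = pd.Series(dict(feature)) if not isinstance(feature, pd.Series) else feature
    lines = list(expr.columns)
    missing = set(lines) - set(feature.index)
    if missing:
        raise ValueError(f"feature missing for lines: {sorted(missing)}")
    y = feature.loc[lines].to_numpy(dtype=float)
    if link == "logistic":
        y = special.logit(normalize_feature(y, eps=eps))

    X = expr.to_numpy(dtype=float)
    L = len(lines)
    sx = X.std(axis=1, ddof=1)
    keep = sx > 0
    if not keep.all():
        logger.info("permutation_screen: skipping %d zero-variance genes",
                    int((~keep).sum()))
    Xz = np.zeros_like(X)
    Xz[keep] = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sx[keep, None]
    sy = y.std(ddof=1)
    if sy == 0:
        raise ValueError("feature has zero variance")
    yz = (y - y.mean()) / sy

    r_obs = Xz @ yz / (L - 1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if M < 1:
        raise ValueError("M must be >= 1")
    P = np.empty((M, L))
    for i in range(M):
        P[i] = yz[rng.permutation(L)]
    r_perm = Xz @ P.T / (L - 1)  # genes x M

    pos = r_obs >= 0
    p = np.empty(X.shape[0])
    p[pos] = (r_perm[pos] >= r_obs[pos, None] - 1e-12).mean(axis=1)
    p[~pos] = (r_perm[~pos] <= r_obs[~pos, None] + 1e-12).mean(axis=1)
    p[~keep] = np.nan

    fdr = np.full_like(p, np.nan)
    for taxo in (pos & keep, (~pos) & keep):
        if taxo.any():
            fdr[taxo] = bh_fdr(p[taxo])

    out = pd.DataFrame({
        "gene_id": expr.index,
        "r": np.where(keep, r_obs, np.nan),
        "p_value": p,
        "p_lt_1_over_M": p < 1.0 / M,
        "fdr": fdr,
        "taxonomy": np.where(pos, "positive", "negative"),
    }).set_index("gene_id")
    return out.sort_values(["p_value", "r"], key=lambda s: -s.abs() if s.name == "r" else s)


class ModeratedTTest(BaseEstimator):
    """One-vs-rest moderated t differential screen as an sklearn estimator.

    ``fit(X, y)`` takes lines x genes data and per-line cluster labels; the
    ranked table for ``target_cluster`` is stored in ``results_``.
    """

    def __init__(self, target_cluster: int = 0, d0_override: float | None = None,
                 fdr_threshold: float = 0.001):
        self.target_cluster = target_cluster
        self.d0_override = d0_override
        self.fdr_threshold = fdr_threshold

    def fit(self, X, y, feature_names: Sequence[str] | None = None,
            sample_names: Sequence[str] | None = None) -> "ModeratedTTest":
        X = np.asarray(X, dtype=float)
        n_lines, n_genes = X.shape
        genes = list(feature_names) if feature_names is not None else \
            [f"g{i}" for i in range(n_genes)]
        lines = list(sample_names) if sample_names is not None else \
            [f"s{i}" for i in range(n_lines)]
        expr = pd.DataFrame(X.T, index=genes, columns=lines)
        labels = dict(zip(lines, np.asarray(y)))
        self.results_ = moderated_t_one_vs_rest(
            expr, labels, self.target_cluster, d0_override=self.d0_override)
        self.d0_ = float(self.results_["d0"].iloc[0])
        self.s0_2_ = float(self.results_["s0_2"].iloc[0])
        self.significant_ = self.results_[self.results_["fdr"] < self.fdr_threshold]
        return self


class PermutationAssociation(BaseEstimator):
    """Linear/logistic feature-association screen as an sklearn estimator.

    ``fit(X, y)`` takes lines x genes expression and the per-line
    morphological feature; the ranked table is stored in ``results_``.
    """

    def __init__(self, link: str = "linear", n_permutations: int = 10_000,
                 eps: float = 1e-3, fdr_threshold: float = 0.05,
                 random_state: int | None = None):
        self.link = link
        self.n_permutations = n_permutations
        self.eps = eps
        self.fdr_threshold = fdr_threshold
        self.random_state = random_state

    def fit(self, X, y, feature_names: Sequence[str] | None = None,
            sample_names: Sequence[str] | None = None) -> "PermutationAssociation":
        X = np.asarray(X, dtype=float)
        n_lines, n_genes = X.shape
        genes = list(feature_names) if feature_names is not None else \
            [f"g{i}" for i in range(n_genes)]
        lines = list(sample_names) if sample_names is not None else \
            [f"s{i}" for i in range(n_lines)]
        expr = pd.DataFrame(X.T, index=genes, columns=lines)
        feature = pd.Series(np.asarray(y, dtype=float), index=lines)
        self.results_ = permutation_screen(
            expr, feature, link=self.link, M=self.n_permutations,
            seed=self.random_state, eps=self.eps)
        self.significant_ = self.results_[self.results_["fdr"] < self.fdr_threshold]
        return self
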