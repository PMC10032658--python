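"""Phylogenetic comparative statistics.

Implements the comparative toolkit used to relate molecular quantities
(substitution rates, regulatory activities, protein activities) to continuous
traits across species while accounting for shared ancestry:

* Brownian-motion covariance matrices and generalized least squares (PGLS)
  with maximum-likelihood fits, likelihood-ratio tests and residual R^2;
* Felsenstein's phylogenetically independent contrasts (PIC) as a fast
  rate--trait correlation estimator;
* partial correlations from precision matrices;
* an empirical permutation null for a focal regulatory element against a pool
  of alternative elements;
* percentile ranking of a focal gene against a control-gene cohort;
* post-processing of Bayesian MCMC trace files (burn-in removal, posterior
  sign probabilities, between-run convergence diagnostics with effective
  sample sizes).

Under a Brownian-motion model of trait evolution the expected covariance of
two tips equals the branch length shared on their root-to-tip paths, i.e. the
depth of their most recent common ancestor.  All GLS fits here use that
covariance (up to the scalar rate, which is profiled out by ML).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from coevoscan.tree import Phylogeny

__all__ = [
    "parse_newick",
    "write_newick",
    "brownian_cov",
    "PGLSFit",
    "pgls_fit",
    "lrt",
    "residual_r2",
    "pic_correlation",
    "partial_correlation",
    "PermutationNull",
    "permutation_null",
    "GeneEvolSummary",
    "rank_focal",
    "parse_coevol_trace",
    "posterior_summary",
    "effective_sample_size",
    "convergence_diagnostics",
    "adjust_pvalues",
]

#: branch-length floor applied before covariance / contrast computation so
#: zero-length branches do not produce singular matrices or 0/0 contrasts
ZERO_BRANCH_EPS = 1e-8


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string (branch lengths required) into a :class:`Phylogeny`."""
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


def brownian_cov(tree: Phylogeny, species=None) -> pd.DataFrame:
    """Expected Brownian trait covariance among tips.

    ``C[a, b]`` is the root-to-MRCA path length of tips a and b; the diagonal
    holds root-to-tip distances.  Always symmetric positive semi-definite.
    """
    leaf_map = tree.leaf_index_map()
    if species is None:
        species = tree.leaf_labels
    missing = [s for s in species if s not in leaf_map]
    if missing:
        raise KeyError(f"species not in tree: {missing}")
    depths = tree.depths()
    # ancestor sets per requested leaf
    anc = {}
    for s in species:
        path = []
        node = leaf_map[s]
        while node >= 0:
            path.append(node)
            node = tree.parent[node]
        anc[s] = path
    anc_sets = {s: set(p) for s, p in anc.items()}
    k = len(species)
    C = np.zeros((k, k))
    for i, a in enumerate(species):
        C[i, i] = depths[leaf_map[a]]
        for j in range(i + 1, k):
            b = species[j]
            # deepest node on a's root path that is also ancestral to b
            shared = next(n for n in anc[a] if n in anc_sets[b])
            C[i, j] = C[j, i] = depths[shared]
    return pd.DataFrame(C, index=list(species), columns=list(species))


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------


@dataclass
class PGLSFit:
    """Maximum-likelihood GLS fit of y = X beta + eps, eps ~ N(0, sigma^2 C)."""

    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_params: int  # regression coefficients + 1 for sigma^2
    grss: float  # generalized residual sum of squares y' C^-1 y residual
    names: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        names = self.names or [f"b{i}" for i in range(len(self.coef))]
        return pd.DataFrame({"coef": self.coef, "se": self.se}, index=names)


def _chol_whiten(cov: np.ndarray):
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "covariance matrix is singular; consider adding a small ridge "
            "epsilon to its diagonal"
        ) from exc
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return L, logdet


def pgls_fit(y, X, cov, names=None) -> PGLSFit:
    """Fit a phylogenetic GLS model by maximum likelihood.

    Parameters
    ----------
    y : (n,) response over species.
    X : (n, p) design matrix (include the intercept column explicitly).
    cov : (n, n) phylogenetic covariance (e.g. from :func:`brownian_cov`),
        rows/columns in the same species order as ``y`` and ``X``.

    The scalar evolutionary rate sigma^2 is profiled out analytically, so the
    reported log-likelihood is the ML value and LRTs between nested fits that
    share ``cov`` are valid.  With ``cov`` proportional to the identity the
    estimates coincide with OLS.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    cov = np.asarray(getattr(cov, "values", cov), dtype=float)
    n, p = X.shape
    if len(y) != n or cov.shape != (n, n):
        raise ValueError("y, X and cov have incompatible shapes")
    if n <= p:
        raise ValueError(f"need more observations (n={n}) than parameters (p={p})")
    from scipy.linalg import solve_triangular

    L, logdet = _chol_whiten(cov)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    coef, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        raise ValueError("singular design matrix")
    resid = yw - Xw @ coef
    grss = float(resid @ resid)
    # floor the variance relative to the response scale so numerically
    # perfect fits (grss ~ float noise) yield stable, comparable likelihoods
    floor = 1e-24 * float(yw @ yw) / n + np.finfo(float).tiny
    sigma2 = max(grss / n, floor)
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    # coefficient covariance at the ML variance estimate
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    return PGLSFit(
        coef=coef,
        se=se,
        loglik=loglik,
        n=n,
        n_params=p + 1,
        grss=grss,
        names=list(names) if names is not None else [],
    )


def lrt(full: PGLSFit, null: PGLSFit):
    """Likelihood-ratio test of nested ML fits: (statistic, df, p)."""
    if full.n != null.n:
        raise ValueError("fits are not on the same data (different n)")
    df = full.n_params - null.n_params
    if df < 0:
        raise ValueError("'full' has fewer parameters than 'null'")
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


def residual_r2(full: PGLSFit, null: PGLSFit) -> float:
    """Residual R^2 for GLS: 1 - GRSS(full) / GRSS(null) under shared cov."""
    if full.n != null.n:
        raise ValueError("fits are not on the same data")
    if null.grss <= 0:
        return 0.0
    return 1.0 - full.grss / null.grss


# ---------------------------------------------------------------------------
# independent contrasts
# ---------------------------------------------------------------------------


def _contrasts(tree: Phylogeny, values: np.ndarray) -> np.ndarray:
    """Felsenstein independent contrasts for tip values in tree leaf order.

    Multifurcations are resolved by sequential pairing, which preserves the
    contrast count (n_leaves - 1) and independence under Brownian motion.
    """
    n = tree.n_nodes
    state = np.full(n, np.nan)
    extra = np.zeros(n)  # branch-length inflation from averaging below
    leaf_idx = tree.leaf_indices()
    state[leaf_idx] = values
    lengths = np.maximum(tree.lengths, ZERO_BRANCH_EPS)
    contrasts = []
    for node in tree.postorder():
        kids = tree.children[node]
        if not kids:
            continue
        x, v = state[kids[0]], lengths[kids[0]] + extra[kids[0]]
        for k in kids[1:]:
            xk, vk = state[k], lengths[k] + extra[k]
            contrasts.append((x - xk) / np.sqrt(v + vk))
            x = (x / v + xk / vk) / (1 / v + 1 / vk)
            v = v * vk / (v + vk)
        state[node] = x
        extra[node] = v
    return np.asarray(contrasts)


def pic_correlation(tree: Phylogeny, trait_a, trait_b, n_perm: int = 0, seed=None):
    """Correlation of two traits via phylogenetically independent contrasts.

    ``trait_a``/``trait_b`` map species -> value for every leaf.  The
    correlation of contrasts is computed through the origin (contrast signs
    are arbitrary, so no centring).  Returns ``(r, p)``; p is a parametric
    t-test on the contrasts, or a sign-flip permutation p when
    ``n_perm > 0``.
    """
    species = tree.leaf_labels
    a = np.array([trait_a[s] for s in species], dtype=float)
    b = np.array([trait_b[s] for s in species], dtype=float)
    ua = _contrasts(tree, a)
    ub = _contrasts(tree, b)
    denom = np.sqrt((ua @ ua) * (ub @ ub))
    if denom == 0:
        return 0.0, 1.0
    r = float(np.clip((ua @ ub) / denom, -1.0, 1.0))
    m = len(ua)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, m))
        null_r = (signs * ua) @ ub / denom
        p = float(np.mean(np.abs(null_r) >= abs(r) - 1e-15))
    else:
        df = m - 1
        if df <= 0 or abs(r) >= 1.0:
            p = 0.0 if abs(r) >= 1.0 else 1.0
        else:
            t = r * np.sqrt(df / (1 - r * r))
            p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def partial_correlation(corr) -> np.ndarray:
    """Partial correlation matrix from a full correlation matrix.

    Inverts the correlation matrix and standardizes:
    partial_ij = -P_ij / sqrt(P_ii P_jj) with P = corr^-1; the diagonal is 1.
    """
    labels = None
    if isinstance(corr, pd.DataFrame):
        labels = corr.index
    C = np.asarray(getattr(corr, "values", corr), dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    try:
        P = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular correlation matrix; consider shrinkage towards identity"
        ) from exc
    d = np.sqrt(np.diag(P))
    out = -P / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    if labels is not None:
        return pd.DataFrame(out, index=labels, columns=labels)
    return out


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


@dataclass
class PermutationNull:
    observed_p: float
    empirical_p: float  # k / n convention
    empirical_p_plus1: float  # (k + 1) / (n + 1) convention
    null_pvalues: np.ndarray


def _fast_gls_slope_pvalues(yw: np.ndarray, ones_w: np.ndarray, Xw: np.ndarray):
    """LRT p-values of slope-vs-intercept GLS models for many predictors.

    ``Xw``: (m, n) whitened predictor rows; returns m chi2(1) p-values using
    the ML likelihood-ratio statistic n*log(GRSS0/GRSS1).
    """
    n = len(yw)
    q = ones_w / np.linalg.norm(ones_w)
    y_perp = yw - (yw @ q) * q
    grss0 = float(y_perp @ y_perp)
    X_perp = Xw - np.outer(Xw @ q, q)
    xnorm2 = np.einsum("ij,ij->i", X_perp, X_perp)
    xy = X_perp @ y_perp
    with np.errstate(divide="ignore", invalid="ignore"):
        grss1 = grss0 - np.where(xnorm2 > 0, xy**2 / xnorm2, 0.0)
    grss1 = np.maximum(grss1, 1e-24 * grss0 + np.finfo(float).tiny)
    statv = n * np.log(np.maximum(grss0, np.finfo(float).tiny) / grss1)
    return stats.chi2.sf(statv, 1)


def permutation_null(
    focal_activity: dict,
    trait: dict,
    cov: pd.DataFrame,
    alternative_activities: dict,
    n_perm: int = 1000,
    scheme: str = "resample-permute",
    seed=None,
) -> PermutationNull:
    """Empirical null for a focal element's trait association.

    Fits trait ~ activity by PGLS (LRT against the intercept-only model) for
    the focal element, then ``n_perm`` times substitutes a resampled activity
    vector and refits.  Schemes:

    - ``"resample-permute"`` (default): draw a non-focal element uniformly
      from the pool and randomly permute its species-to-activity assignment;
    - ``"resample"``: draw a non-focal element, keep its assignment;
    - ``"label-permute"``: permute the focal vector's own species labels.

    The empirical p is k/n where k counts permutations whose LRT p is <= the
    observed p; the (k+1)/(n+1) convention is reported alongside.
    """
    if scheme not in {"resample-permute", "resample", "label-permute"}:
        raise ValueError(f"unknown scheme: {scheme}")
    species = [s for s in cov.index if s in focal_activity and s in trait]
    n = len(species)
    if n < 3:
        raise ValueError("need at least 3 species with focal activity and trait")
    pool = {
        k: v
        for k, v in alternative_activities.items()
        if all(s in v for s in species)
    }
    if scheme != "label-permute" and not pool:
        raise ValueError("alternative-activity pool is empty for these species")
    C = cov.loc[species, species].values
    from scipy.linalg import solve_triangular

    L, _ = _chol_whiten(C)
    y = np.array([trait[s] for s in species])
    yw = solve_triangular(L, y, lower=True)
    ones_w = solve_triangular(L, np.ones(n), lower=True)
    x_focal = np.array([focal_activity[s] for s in species])

    def whiten_rows(M):
        return solve_triangular(L, M.T, lower=True).T

    observed_p = float(
        _fast_gls_slope_pvalues(yw, ones_w, whiten_rows(x_focal[None, :]))[0]
    )
    rng = np.random.default_rng(seed)
    names = sorted(pool)
    X = np.empty((n_perm, n))
    for i in range(n_perm):
        if scheme == "label-permute":
            vec = x_focal.copy()
        else:
            vec = np.array([pool[names[rng.integers(len(names))]][s] for s in species])
        if scheme != "resample":
            vec = vec[rng.permutation(n)]
        X[i] = vec
    null_p = _fast_gls_slope_pvalues(yw, ones_w, whiten_rows(X))
    k = int(np.sum(null_p <= observed_p + 1e-15))
    return PermutationNull(
        observed_p=observed_p,
        empirical_p=k / n_perm,
        empirical_p_plus1=(k + 1) / (n_perm + 1),
        null_pvalues=null_p,
    )


# ---------------------------------------------------------------------------
# control-gene ranking
# ---------------------------------------------------------------------------


@dataclass
class GeneEvolSummary:
    """Per-gene evolutionary summary: rate, tree lengths, trait correlations."""

    gene_id: str
    omega: float = np.nan  # dN tree length / dS tree length
    dn_treelen: float = np.nan
    ds_treelen: float = np.nan
    marginal_r: dict = field(default_factory=dict)  # trait -> r
    partial_r: dict = field(default_factory=dict)  # trait -> r
    pp: dict = field(default_factory=dict)  # trait -> posterior probability


def rank_focal(controls, focal: GeneEvolSummary, trait: str, statistic: str = "marginal"):
    """Percentile of the focal gene among controls for a trait correlation.

    percentile = (#genes in the pooled set, focal included, whose statistic is
    >= the focal's) / (n_controls + 1) * 100.  Ties count against the focal
    gene (conservative).  Invariant to strictly monotone transforms of the
    statistic.
    """
    attr = {"marginal": "marginal_r", "partial": "partial_r"}[statistic]
    focal_val = getattr(focal, attr).get(trait)
    if focal_val is None or not np.isfinite(focal_val):
        raise ValueError(f"focal gene has no defined {statistic} r for {trait!r}")
    vals = [
        getattr(c, attr)[trait]
        for c in controls
        if trait in getattr(c, attr) and np.isfinite(getattr(c, attr)[trait])
    ]
    if len(vals) < 2:
        raise ValueError("need at least 2 controls with the statistic defined")
    n_ge = 1 + sum(v >= focal_val for v in vals)  # focal counts for itself
    return 100.0 * n_ge / (len(vals) + 1)


# ---------------------------------------------------------------------------
# MCMC trace post-processing
# ---------------------------------------------------------------------------


def parse_coevol_trace(files, burn_in: int = 1000):
    """Read >= 1 whitespace-delimited MCMC trace files; drop burn-in cycles.

    Returns ``(runs, pooled)``: per-run DataFrames (post burn-in) and their
    row-wise concatenation.  Headers must agree across runs.
    """
    runs = []
    header = None
    for f in files:
        df = pd.read_csv(f, sep=r"\s+")
        if header is None:
            header = list(df.columns)
        elif list(df.columns) != header:
            raise ValueError(
                f"trace {f} header {list(df.columns)} != first run's {header}"
            )
        if burn_in >= len(df):
            raise ValueError(
                f"burn-in {burn_in} >= trace length {len(df)} in {f}: empty posterior"
            )
        runs.append(df.iloc[burn_in:].reset_index(drop=True))
    pooled = pd.concat(runs, ignore_index=True)
    return runs, pooled


def posterior_summary(samples):
    """Posterior mean and sign probability for a correlation parameter.

    Returns ``(mean, pp, pp_display)`` where pp is the fraction of samples
    > 0 and pp_display = max(pp, 1 - pp): the support for the correlation in
    the direction of its posterior mean, comparable across signs.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("no posterior samples")
    mean = float(x.mean())
    pp = float(np.mean(x > 0))
    return mean, pp, max(pp, 1 - pp)


def effective_sample_size(x) -> float:
    """ESS from the integrated autocorrelation time.

    Uses Geyer's initial positive sequence on FFT-estimated autocorrelations:
    tau = 1 + 2 * sum(rho_k) truncated when consecutive-lag-pair sums turn
    negative; ESS = n / tau.  For iid draws ESS ~= n; for an AR(1) chain with
    coefficient rho, ESS ~= n (1 - rho) / (1 + rho).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return float(n)
    x = x - x.mean()
    if np.allclose(x, 0):
        return float(n)
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence over lag pairs (1,2), (3,4), ...
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        tau += 2 * pair
        k += 2
    return float(n / max(tau, 1.0 / n))


def convergence_diagnostics(
    runs, reldiff_max: float = 0.3, ess_min: float = 50.0
) -> pd.DataFrame:
    """Between-run convergence report for every traced parameter.

    For each parameter: ``reldiff`` is the largest absolute between-run
    difference in posterior means scaled by the pooled posterior standard
    deviation, and ``ess`` the smallest per-run effective sample size.  A
    parameter passes iff reldiff < ``reldiff_max`` and ess > ``ess_min``.
    With a single run reldiff is unavailable (NaN) and only ESS is assessed.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no runs provided")
    params = list(runs[0].columns)
    rows = []
    for p in params:
        chains = [np.asarray(r[p], dtype=float) for r in runs]
        pooled = np.concatenate(chains)
        sd = pooled.std(ddof=1) if len(pooled) > 1 else 0.0
        if len(chains) >= 2:
            means = [c.mean() for c in chains]
            spread = max(
                abs(a - b) for i, a in enumerate(means) for b in means[i + 1 :]
            )
            reldiff = 0.0 if spread == 0 else (np.inf if sd == 0 else spread / sd)
        else:
            reldiff = np.nan
        ess = min(effective_sample_size(c) for c in chains)
        ok_rd = True if np.isnan(reldiff) else reldiff < reldiff_max
        rows.append(
            {
                "parameter": p,
                "reldiff": reldiff,
                "ess": ess,
                "passed": bool(ok_rd and ess > ess_min),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: ``"bh"`` (Benjamini-Hochberg) or
    ``"bonferroni"``."""
    from statsmodels.stats.multitest import multipletests

    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(np.asarray(pvalues, dtype=float), method=key)[1]
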