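"""Proliferation-assay statistics.

The assay transfects orthologues of a gene into neural stem cells and counts
proliferating (Ki67+) among transfected (GFP+) cells per biological
replicate.  The proportion is modelled by binomial logistic regression with
the GFP+ totals as binomial trials; donor batch enters as a fixed effect
when a likelihood-ratio test supports it.  Per-condition proliferation rates
are back-calculated from a zero-intercept (cell-means) parameterisation via
the inverse logit, pairwise condition differences are tested with
single-step (max-|z|) multiplicity adjustment, and the rates are linked to
brain phenotypes by phylogenetic GLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from coevoscan import phylocomp
from coevoscan.tree import Phylogeny

__all__ = [
    "ProliferationFit",
    "fit_logistic",
    "select_model",
    "backcalc_rates",
    "pairwise_contrasts",
    "pairwise_condition_contrasts",
    "link_to_phenotype",
]


@dataclass
class ProliferationFit:
    coef: np.ndarray
    cov_params: np.ndarray
    loglik: float
    deviance: float
    deviance_trace: list
    names: list
    conditions: list
    batches: list
    include_batch: bool
    parameterization: str  # "cellmeans": one coefficient per condition, no intercept
    n_obs: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.coef, "se": self.se}, index=self.names)


def _binomial_deviance(y, n, p):
    eps = 1e-12
    mu = np.clip(p, eps, 1 - eps) * n
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - mu)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def _irls(X, y, n, tol: float = 1e-8, max_iter: int = 100):
    """Binomial IRLS with step-halving so the deviance is monotone.

    Returns (coef, cov_params, deviance_trace).  Convergence when the
    relative deviance change falls below ``tol``.
    """
    n_obs, p = X.shape
    beta = np.zeros(p)
    # initialize from the empirical logits
    p0 = (y + 0.5) / (n + 1.0)
    eta = np.log(p0 / (1 - p0))
    beta, *_ = np.linalg.lstsq(X, eta, rcond=None)
    dev = _binomial_deviance(y, n, expit(X @ beta))
    trace = [dev]
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = n * mu * (1 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - n * mu) / w
        WX = X * w[:, None]
        try:
            step_beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design in IRLS") from exc
        # step-halving keeps the deviance non-increasing
        new_beta, frac = step_beta, 1.0
        for _half in range(30):
            new_dev = _binomial_deviance(y, n, expit(X @ new_beta))
            if new_dev <= dev + 1e-12:
                break
            frac /= 2.0
            new_beta = beta + frac * (step_beta - beta)
        beta = new_beta
        trace.append(new_dev)
        if abs(dev - new_dev) <= tol * (abs(dev) + 1e-10):
            dev = new_dev
            break
        dev = new_dev
    mu = expit(X @ beta)
    w = np.maximum(n * mu * (1 - mu), 1e-10)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov, trace


def _design(data: pd.DataFrame, include_batch: bool):
    conditions = sorted(data["condition"].unique())
    batches = sorted(data["batch"].unique()) if "batch" in data else []
    cols, names = [], []
    for c in conditions:
        cols.append((data["condition"] == c).to_numpy(float))
        names.append(f"condition[{c}]")
    if include_batch:
        for b in batches[1:]:  # first batch is the reference level
            cols.append((data["batch"] == b).to_numpy(float))
            names.append(f"batch[{b}]")
    return np.column_stack(cols), names, conditions, batches


def fit_logistic(data: pd.DataFrame, include_batch: bool = False) -> ProliferationFit:
    """Weighted binomial logistic regression of proliferation counts.

    ``data`` needs columns condition, gfp_total, ki67_gfp (and batch when
    ``include_batch``).  Successes are ki67_gfp out of gfp_total trials.  The
    model is parameterised without an intercept (one coefficient per
    condition, batch dummies against the first batch), so each condition
    coefficient is directly its log-odds at the reference batch.
    """
    for col in ("condition", "gfp_total", "ki67_gfp"):
        if col not in data:
            raise ValueError(f"data missing column {col!r}")
    if include_batch and "batch" not in data:
        raise ValueError("include_batch=True requires a 'batch' column")
    y = data["ki67_gfp"].to_numpy(float)
    n = data["gfp_total"].to_numpy(float)
    if (n <= 0).any():
        raise ValueError("gfp_total must be positive")
    if (y < 0).any() or (y > n).any():
        raise ValueError("ki67_gfp must lie in [0, gfp_total]")
    # complete separation at the condition level makes the MLE infinite
    for cond, grp in data.groupby("condition"):
        tot = grp["gfp_total"].sum()
        suc = grp["ki67_gfp"].sum()
        if suc == 0 or suc == tot:
            raise ValueError(
                f"complete separation: condition {cond!r} has "
                f"{'no' if suc == 0 else 'only'} proliferating cells"
            )
    X, names, conditions, batches = _design(data, include_batch)
    coef, cov, trace = _irls(X, y, n)
    mu = np.clip(expit(X @ coef), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (n - y) * np.log(1 - mu)))
    return ProliferationFit(
        coef=coef,
        cov_params=cov,
        loglik=ll,
        deviance=trace[-1],
        deviance_trace=trace,
        names=names,
        conditions=conditions,
        batches=batches if include_batch else [],
        include_batch=include_batch,
        parameterization="cellmeans",
        n_obs=len(data),
    )


def select_model(fit_without_batch: ProliferationFit, fit_with_batch: ProliferationFit, alpha: float = 0.05):
    """Keep the batch term iff the LRT favours it at level ``alpha``.

    Returns ``(chosen fit, record)`` where record holds statistic/df/p.
    """
    f0, f1 = fit_without_batch, fit_with_batch
    if f0.n_obs != f1.n_obs or f0.conditions != f1.conditions:
        raise ValueError("fits are not nested on the same data")
    df = len(f1.coef) - len(f0.coef)
    if df <= 0:
        raise ValueError("batch fit must have more parameters")
    stat = max(2.0 * (f1.loglik - f0.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df))
    chosen = f1 if p < alpha else f0
    return chosen, {"statistic": stat, "df": df, "p": p, "batch_kept": p < alpha}


def backcalc_rates(fit: ProliferationFit, batch_handling: str = "reference") -> pd.Series:
    """Per-condition proliferation rates via the inverse logit.

    With the cell-means parameterisation each condition's coefficient is its
    log-odds with batch coefficients at the reference level (zero), so
    rate_i = expit(beta_i).  ``batch_handling="mean"`` instead evaluates at
    the average batch effect.
    """
    k = len(fit.conditions)
    beta = fit.coef[:k].copy()
    if fit.include_batch and batch_handling == "mean" and len(fit.coef) > k:
        # average over batch levels incl. the reference (coefficient 0)
        batch_coefs = np.concatenate([[0.0], fit.coef[k:]])
        beta = beta + batch_coefs.mean()
    elif batch_handling not in ("reference", "mean"):
        raise ValueError("batch_handling must be 'reference' or 'mean'")
    return pd.Series(expit(beta), index=fit.conditions, name="rate")


def pairwise_condition_contrasts(fit: ProliferationFit) -> dict:
    """All pairwise condition-difference contrast vectors (Tukey-style set)."""
    k = len(fit.conditions)
    p = len(fit.coef)
    out = {}
    for i, j in combinations(range(k), 2):
        v = np.zeros(p)
        v[i], v[j] = 1.0, -1.0
        out[f"{fit.conditions[i]} - {fit.conditions[j]}"] = v
    return out


def pairwise_contrasts(
    fit: ProliferationFit,
    contrasts: dict | None = None,
    adjust: str = "single-step",
    n_mc: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-sided multiple comparisons of linear contrasts of the coefficients.

    ``single-step`` adjusts via the joint distribution of the maximum
    absolute z statistic, approximated by Monte-Carlo sampling from the
    multivariate normal with the contrast correlation matrix (the semantics
    of multcomp's glht single-step adjustment); ``bonferroni`` is the
    deterministic fallback.  A zero contrast vector yields estimate 0, p = 1.
    """
    if contrasts is None:
        contrasts = pairwise_condition_contrasts(fit)
    names = list(contrasts)
    K = np.array([np.asarray(contrasts[nm], float) for nm in names])
    if K.shape[1] != len(fit.coef):
        raise ValueError(
            f"contrast length {K.shape[1]} != number of coefficients {len(fit.coef)}"
        )
    est = K @ fit.coef
    V = K @ fit.cov_params @ K.T
    sd = np.sqrt(np.maximum(np.diag(V), 0.0))
    nonzero = sd > 0
    z = np.where(nonzero, est / np.where(sd > 0, sd, 1.0), 0.0)
    raw = np.where(nonzero, 2 * stats.norm.sf(np.abs(z)), 1.0)
    if adjust == "bonferroni":
        adj = np.minimum(raw * int(nonzero.sum()), 1.0)
    elif adjust == "single-step":
        idx = np.flatnonzero(nonzero)
        adj = np.ones(len(names))
        if idx.size:
            R = V[np.ix_(idx, idx)] / np.outer(sd[idx], sd[idx])
            R = R + 1e-10 * np.eye(len(idx))
            rng = np.random.default_rng(seed)
            L = np.linalg.cholesky(R)
            draws = rng.standard_normal((n_mc, len(idx))) @ L.T
            maxabs = np.abs(draws).max(axis=1)
            for j, i in enumerate(idx):
                adj[i] = float(np.mean(maxabs >= abs(z[i])))
    else:
        raise ValueError("adjust must be 'single-step' or 'bonferroni'")
    return pd.DataFrame(
        {"estimate": est, "se": sd, "z": z, "p_raw": raw, "p_adj": adj}, index=names
    )


def link_to_phenotype(
    rates: pd.Series,
    condition_species: dict,
    traits: pd.DataFrame,
    tree: Phylogeny,
    trait_cols=("log_brain", "log_gi"),
) -> pd.DataFrame:
    """PGLS of each phenotype on the back-calculated proliferation rates.

    Each condition maps to a species; the Brownian covariance over those
    species is used, one model per trait, with Benjamini-Hochberg adjustment
    across the trait family.  Reports slope, LRT statistic/p, residual R^2
    and n.
    """
    unmatched = [c for c in rates.index if condition_species.get(c) not in traits.index]
    if unmatched:
        raise KeyError(f"conditions without trait data: {unmatched}")
    species = [condition_species[c] for c in rates.index]
    if len(set(species)) != len(species):
        raise ValueError("each condition must map to a distinct species")
    cov = phylocomp.brownian_cov(tree, species)
    x = rates.to_numpy(float)
    X_full = np.column_stack([np.ones(len(x)), x])
    rows = []
    for trait in trait_cols:
        y = traits.loc[species, trait].to_numpy(float)
        full = phylocomp.pgls_fit(y, X_full, cov, names=["intercept", "rate"])
        null = phylocomp.pgls_fit(y, X_full[:, :1], cov, names=["intercept"])
        stat, df, p = phylocomp.lrt(full, null)
        rows.append(
            {
                "trait": trait,
                "slope": full.coef[1],
                "slope_se": full.se[1],
                "lrt_stat": stat,
                "df": df,
                "p": p,
                "r2_resid": phylocomp.residual_r2(full, null),
                "n": full.n,
            }
        )
    out = pd.DataFrame(rows).set_index("trait")
    out["p_bh"] = phylocomp.adjust_pvalues(out["p"].to_numpy(), "bh")
    return out
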