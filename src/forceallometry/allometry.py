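"""Bivariate allometric exponents from individual records.

The interspecific model is a hierarchical Bayesian measurement-error
regression on the log10 scale. Individual observations within species are
bivariate normal about latent species means with an inverse-Wishart-prior
within-species covariance; latent y-means regress on latent x-means with a
phylogenetic residual covariance sigma^2 * Sigma_lambda, where

    Sigma_lambda = lambda * Sigma + (1 - lambda) * I

blends the Brownian shared-path correlation matrix Sigma (unit diagonal)
with independence via Pagel's lambda. The signal strength is estimated
separately for the latent x distribution (lambda_x) and the regression
residual (lambda): body size is usually strongly phylogenetic while
residuals need not be. Phylogenetic uncertainty is handled by drawing the
tree uniformly from a (replicated) posterior ensemble at each MCMC
iteration, which marginalises the posterior over the tree sample.

Intraspecific exponents use within-species centring: species means are
subtracted from both log variables, the centred points are pooled, and a
common slope is estimated with the same flat priors.

All samplers are Gibbs with a Metropolis step for lambda; conjugate
conditionals are used wherever the priors admit them. Uniform priors on
standard deviations induce truncated inverse-gamma conditionals on the
variances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .treespace import TreeEnsemble, depth_tables, normalise_label

log = logging.getLogger(__name__)


class ConvergenceWarning(UserWarning):
    """Split potential-scale-reduction exceeded its threshold."""


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass
class AllometryConfig:
    n_chains: int = 4
    n_iter: int = 10000
    burn_in: int = 5000
    slope_prior: tuple[float, float] = (0.0, 1e-6)   # (mean, precision)
    intercept_prior: tuple[float, float] = (0.0, 1e-6)
    sd_prior: float = 1000.0          # uniform upper bound on each sd
    wishart_df: Optional[int] = None  # default: dimension + 1
    wishart_scale: float = 1e-4       # prior scale matrix = wishart_scale * I
    variance_prior: str = "uniform_sd"   # or "gamma_precision"
    gamma_prior: tuple[float, float] = (1e-3, 1e-3)  # shape, rate
    characteristic_scale: str = "clade_mean"  # unit | clade_mean | species_mean
    tree_replicates: int = 4
    tree_assignment: str = "draw"     # "draw" (default) or "chain"
    drop_singletons: bool = False
    fix_lambda: Optional[float] = None
    fix_within_cov: Optional[np.ndarray] = None
    lambda_proposal_sd: float = 0.15
    rhat_threshold: float = 1.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.characteristic_scale not in ("unit", "clade_mean",
                                             "species_mean"):
            raise ValueError(
                f"unknown characteristic scale {self.characteristic_scale!r}")

    @property
    def n_draws(self) -> int:
        return self.n_chains * (self.n_iter - self.burn_in)


@dataclass
class AllometryFit:
    """Posterior draws and summaries for one bivariate log-log exponent."""

    posterior_b: np.ndarray
    posterior_a: np.ndarray
    posterior_lambda: Optional[np.ndarray]
    posterior_sds: dict[str, np.ndarray]
    summary: pd.DataFrame
    diagnostics: dict
    scope: str = "among"
    n_species: int = 0
    n_individuals: int = 0
    x_name: str = "x"
    y_name: str = "y"

    @property
    def slope_mean(self) -> float:
        return float(self.posterior_b.mean())

    @property
    def slope_ci(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.posterior_b, [0.025, 0.975])
        return float(lo), float(hi)

    def mcse(self, param: str = "b") -> float:
        draws = {"b": self.posterior_b, "a": self.posterior_a}[param]
        return batch_mcse(draws)


def batch_mcse(draws: np.ndarray, n_batches: int = 20) -> float:
    """Monte-Carlo standard error of the mean by non-overlapping batch means."""
    n = len(draws) // n_batches * n_batches
    means = draws[:n].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def split_rhat(chains: np.ndarray) -> float:
    """Split potential scale reduction factor; ``chains`` is (m, n)."""
    m, n = chains.shape
    half = n // 2
    seg = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    w = seg.var(axis=1, ddof=1).mean()
    b = seg.mean(axis=1).var(ddof=1) * half
    if w <= 0:
        return 1.0
    return float(np.sqrt(((half - 1) / half * w + b / half) / w))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def log_center(values, scale=1.0) -> np.ndarray:
    """log10(value / scale) for strictly positive values.

    ``scale`` may be a scalar, an array broadcastable against ``values``, or
    one of the strings ``"unit"`` (1), ``"geometric_mean"``. Centring on the
    geometric mean makes the returned values average exactly zero, so a
    fitted line passes through the origin.
    """
    v = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(v > 0))
    if bad.size:
        raise ValueError(f"non-positive values at positions {bad.tolist()}")
    logs = np.log10(v)
    if isinstance(scale, str):
        if scale == "unit":
            return logs
        if scale == "geometric_mean":
            return logs - logs.mean()
        raise ValueError(f"unknown scale {scale!r}")
    s = np.asarray(scale, dtype=float)
    if np.any(~(s > 0)):
        raise ValueError("scale must be strictly positive")
    return logs - np.log10(s)


def phylo_covariance(tree: dendropy.Tree, lam: float,
                     species: Optional[Sequence[str]] = None) -> np.ndarray:
    """Pagel-lambda species covariance lam*Sigma + (1-lam)*I.

    Sigma is the Brownian shared-path matrix of the rooted tree scaled to a
    unit diagonal; rows/columns follow ``species`` when given (tips must map
    1:1), otherwise the tree's sorted tip labels.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    labels, _, length, _ = depth_tables(tree)
    shared = np.array(length)
    d = np.sqrt(np.diag(shared))
    if np.any(d <= 0):
        raise ValueError("tree has zero root-to-tip path length")
    sigma = shared / np.outer(d, d)
    if species is not None:
        wanted = [normalise_label(s) for s in species]
        missing = sorted(set(wanted) - set(labels))
        if missing:
            raise ValueError(f"species not on the tree: {missing}")
        idx = [labels.index(s) for s in wanted]
        sigma = sigma[np.ix_(idx, idx)]
    n = sigma.shape[0]
    return lam * sigma + (1.0 - lam) * np.eye(n)


# ---------------------------------------------------------------------------
# internal sampler machinery
# ---------------------------------------------------------------------------

def _sample_mvn_prec(prec: np.ndarray, h: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw from N(prec^-1 h, prec^-1) via one Cholesky factorisation."""
    L = np.linalg.cholesky(prec)
    tmp = solve_triangular(L, h, lower=True, check_finite=False)
    mean = solve_triangular(L.T, tmp, lower=False, check_finite=False)
    z = rng.standard_normal(len(h))
    return mean + solve_triangular(L.T, z, lower=False, check_finite=False)


def _sample_variance(q: float, n: int, cfg: AllometryConfig,
                     rng: np.random.Generator) -> float:
    """Conditional draw of a variance given quadratic form q over n terms."""
    if cfg.variance_prior == "gamma_precision":
        a0, b0 = cfg.gamma_prior
        tau = rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * q))
        return 1.0 / tau
    # flat prior on the sd, truncated at sd_prior
    shape = 0.5 * (n - 1)
    bound = cfg.sd_prior ** 2
    for _ in range(100):
        v = (0.5 * q) / rng.gamma(max(shape, 0.5), 1.0)
        if v < bound:
            return v
    return min(v, bound)


def _inv2(m: np.ndarray) -> np.ndarray:
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


def _sample_invwishart2(df: float, scale: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Inverse-Wishart(df, scale) draw for a 2x2 matrix (Bartlett)."""
    prec_scale = _inv2(scale)
    L = np.linalg.cholesky(prec_scale)
    A = np.array([[np.sqrt(rng.chisquare(df)), 0.0],
                  [rng.standard_normal(), np.sqrt(rng.chisquare(df - 1))]])
    T = L @ A
    prec = T @ T.T
    return _inv2(prec)


def _prepare_trees(trees: TreeEnsemble, species: Sequence[str],
                   individuals: Optional[dict[str, Sequence[str]]],
                   replicates: int, rng: np.random.Generator):
    """Eigendecompose the Brownian correlation of every ensemble tree.

    Returns (eigenvectors, eigenvalues, replicate_index) where
    ``replicate_index`` maps each of ``len(trees) * replicates`` replicate
    slots to its source-tree decomposition. Replicates differ only in which
    individual is designated species representative (drawn here and logged);
    the latent-mean likelihood depends on the tree alone, so replicate slots
    share their source tree's covariance.
    """
    pruned = trees.pruned_to(species) if trees.tip_labels != frozenset(
        normalise_label(s) for s in species) else trees
    Vs, ds = [], []
    for t in pruned.trees:
        sigma = phylo_covariance(t, 1.0, species=species)
        d, V = np.linalg.eigh(sigma)
        Vs.append(V)
        ds.append(np.clip(d, 1e-12, None))
    n = len(pruned.trees)
    rep_index = np.repeat(np.arange(n), replicates)
    if individuals:
        for slot in rep_index:
            for sp in species:
                ids = individuals.get(sp, [])
                if len(ids) > 1:
                    rng.choice(len(ids))  # representative draw, recorded only
    return Vs, ds, rep_index


def _run_hierarchical_chain(seed, xs, ys, sp_idx, n_i, Sx, Sy, Vs, ds,
                            rep_index, cfg: AllometryConfig):
    """One MCMC chain of the latent-species-means measurement-error model."""
    rng = np.random.default_rng(seed)
    S = len(n_i)
    N = len(xs)
    ones = np.ones(S)
    xbar = Sx / n_i
    ybar = Sy / n_i

    # initial state, jittered per chain
    mx = xbar + 0.01 * rng.standard_normal(S)
    my = ybar + 0.01 * rng.standard_normal(S)
    X = np.column_stack([ones, mx])
    beta, *_ = np.linalg.lstsq(X, my, rcond=None)
    a, b = beta + 0.05 * rng.standard_normal(2)
    ax = float(mx.mean())
    s2 = max(float(np.var(my - X @ beta)), 1e-6)
    sx2 = max(float(np.var(mx)), 1e-6)
    # separate phylogenetic-signal strengths for the x-prior and the
    # regression residual; a single fix_lambda pins both
    lam_e = cfg.fix_lambda if cfg.fix_lambda is not None else rng.uniform()
    lam_x = cfg.fix_lambda if cfg.fix_lambda is not None else rng.uniform()
    if cfg.fix_within_cov is not None:
        omega = np.array(cfg.fix_within_cov, dtype=float)
    else:
        omega = np.eye(2) * 0.01
    wish_df = cfg.wishart_df if cfg.wishart_df is not None else 3
    wish_scale = cfg.wishart_scale * np.eye(2)

    am, ap = cfg.intercept_prior
    bm, bp = cfg.slope_prior
    prior_prec = np.array([ap, bp])
    prior_mean = np.array([am, bm])

    n_unique = len(Vs)
    tree_slot = int(rng.integers(len(rep_index)))
    keep = cfg.n_iter - cfg.burn_in
    out_b = np.empty(keep)
    out_a = np.empty(keep)
    out_lam = np.empty(keep)
    out_lam_x = np.empty(keep)
    out_s = np.empty(keep)
    out_sx = np.empty(keep)
    out_oxx = np.empty(keep)
    out_oyy = np.empty(keep)
    out_oxy = np.empty(keep)

    V = Vs[rep_index[tree_slot]]
    d = ds[rep_index[tree_slot]]

    for it in range(cfg.n_iter):
        if cfg.tree_assignment == "draw" and n_unique > 1:
            tree_slot = int(rng.integers(len(rep_index)))
            V = Vs[rep_index[tree_slot]]
            d = ds[rep_index[tree_slot]]

        w_e = 1.0 / (lam_e * d + (1.0 - lam_e))
        w_x = 1.0 / (lam_x * d + (1.0 - lam_x))
        Sinv_e = (V * w_e) @ V.T
        Sinv_x = (V * w_x) @ V.T
        Sinvx_ones = Sinv_x @ ones

        P2 = _inv2(omega)
        pxx, pxy, pyy = P2[0, 0], P2[0, 1], P2[1, 1]

        # latent x means
        prec = Sinv_x / sx2 + Sinv_e * (b * b / s2)
        prec[np.diag_indices(S)] += n_i * pxx
        h = (pxx * Sx + pxy * (Sy - n_i * my)
             + Sinvx_ones * (ax / sx2) + (b / s2) * (Sinv_e @ (my - a)))
        mx = _sample_mvn_prec(prec, h, rng)

        # latent y means
        prec = Sinv_e / s2
        prec[np.diag_indices(S)] += n_i * pyy
        h = (pyy * Sy + pxy * (Sx - n_i * mx) + Sinv_e @ (a + b * mx) / s2)
        my = _sample_mvn_prec(prec, h, rng)

        # regression coefficients
        X = np.column_stack([ones, mx])
        XtS = X.T @ Sinv_e
        A = XtS @ X / s2 + np.diag(prior_prec)
        hv = XtS @ my / s2 + prior_prec * prior_mean
        a, b = _sample_mvn_prec(A, hv, rng)

        # x-mean intercept
        pa = float(ones @ Sinvx_ones) / sx2 + 1e-6
        ha = float(Sinvx_ones @ mx) / sx2
        ax = ha / pa + rng.standard_normal() / np.sqrt(pa)

        # variances
        e = my - a - b * mx
        ex = mx - ax
        te = V.T @ e
        tx = V.T @ ex
        s2 = _sample_variance(float(np.sum(te * te * w_e)), S, cfg, rng)
        sx2 = _sample_variance(float(np.sum(tx * tx * w_x)), S, cfg, rng)

        # Pagel's lambdas (Metropolis with reflection at the bounds)
        if cfg.fix_lambda is None:
            def _step(lam, t, v2):
                prop = lam + cfg.lambda_proposal_sd * rng.standard_normal()
                while prop < 0.0 or prop > 1.0:
                    prop = -prop if prop < 0 else 2.0 - prop
                def _lp(lv):
                    wv = 1.0 / (lv * d + (1.0 - lv))
                    return (0.5 * float(np.sum(np.log(wv)))
                            - 0.5 * float(np.sum(t * t * wv)) / v2)
                if np.log(rng.uniform()) < _lp(prop) - _lp(lam):
                    return prop
                return lam
            lam_e = _step(lam_e, te, s2)
            lam_x = _step(lam_x, tx, sx2)

        # within-species covariance
        if cfg.fix_within_cov is None:
            rx = xs - mx[sp_idx]
            ry = ys - my[sp_idx]
            srr = np.array([[rx @ rx, rx @ ry], [rx @ ry, ry @ ry]])
            omega = _sample_invwishart2(wish_df + N, wish_scale + srr, rng)

        j = it - cfg.burn_in
        if j >= 0:
            out_b[j] = b
            out_a[j] = a
            out_lam[j] = lam_e
            out_lam_x[j] = lam_x
            out_s[j] = np.sqrt(s2)
            out_sx[j] = np.sqrt(sx2)
            out_oxx[j] = omega[0, 0]
            out_oyy[j] = omega[1, 1]
            out_oxy[j] = omega[0, 1]

    return dict(b=out_b, a=out_a, lam=out_lam, lambda_x=out_lam_x,
                sigma_resid=out_s, sigma_x=out_sx, omega_xx=out_oxx,
                omega_yy=out_oyy, omega_xy=out_oxy)


def _pool_and_summarise(chain_results, cfg: AllometryConfig, scope: str,
                        n_species: int, n_individuals: int,
                        x_name: str, y_name: str,
                        with_lambda: bool) -> AllometryFit:
    pooled = {k: np.concatenate([c[k] for c in chain_results])
              for k in chain_results[0]}
    b_chains = np.vstack([c["b"] for c in chain_results])
    rhat = split_rhat(b_chains)
    converged = rhat < cfg.rhat_threshold
    if not converged:
        warnings.warn(
            f"slope split-Rhat {rhat:.3f} exceeds {cfg.rhat_threshold}; "
            "inspect chains", ConvergenceWarning)

    params = {"b": pooled["b"], "a": pooled["a"]}
    if with_lambda:
        params["lambda"] = pooled["lam"]
        if "lambda_x" in pooled:
            params["lambda_x"] = pooled["lambda_x"]
    for k in ("sigma_resid", "sigma_x", "omega_xx", "omega_yy", "omega_xy"):
        if k in pooled:
            params[k] = pooled[k]
    rows = {}
    for name, draws in params.items():
        lo, hi = np.quantile(draws, [0.025, 0.975])
        rows[name] = dict(mean=float(draws.mean()), ci_low=float(lo),
                          ci_high=float(hi))
    summary = pd.DataFrame(rows).T

    return AllometryFit(
        posterior_b=pooled["b"], posterior_a=pooled["a"],
        posterior_lambda=pooled["lam"] if with_lambda else None,
        posterior_sds={k: pooled[k] for k in pooled
                       if k.startswith(("sigma", "omega"))},
        summary=summary,
        diagnostics=dict(rhat_b=rhat, converged=converged,
                         chain_means_b=b_chains.mean(axis=1).tolist()),
        scope=scope, n_species=n_species, n_individuals=n_individuals,
        x_name=x_name, y_name=y_name)


def _prepare_xy(x, y, species, cfg: AllometryConfig):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    species = np.asarray(species)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, species = x[ok], y[ok], species[ok]
    scale = "geometric_mean" if cfg.characteristic_scale != "unit" else "unit"
    lx = log_center(x, scale)
    ly = log_center(y, scale)
    return lx, ly, species


# ---------------------------------------------------------------------------
# public fits
# ---------------------------------------------------------------------------

def fit_interspecific(x, y, species, trees: Optional[TreeEnsemble],
                      config: Optional[AllometryConfig] = None,
                      x_name: str = "x", y_name: str = "y",
                      ) -> AllometryFit:
    """Interspecific allometric exponent of ``y`` on ``x`` (natural scale).

    ``x``/``y`` are positive per-individual values, ``species`` the matching
    species labels. Both are log10-transformed (centred on the clade
    geometric mean unless ``config.characteristic_scale == "unit"``). The
    tree ensemble is replicated ``config.tree_replicates`` times and a tree
    is drawn uniformly per MCMC iteration (or per chain with
    ``tree_assignment="chain"``).
    """
    cfg = config or AllometryConfig()
    lx, ly, species = _prepare_xy(x, y, species, cfg)

    sp_list = sorted(set(species))
    if cfg.drop_singletons:
        counts = {s: int(np.sum(species == s)) for s in sp_list}
        dropped = [s for s in sp_list if counts[s] < 2]
        if dropped:
            log.info("dropping singleton species: %s", dropped)
        sp_list = [s for s in sp_list if counts[s] >= 2]
        keep = np.isin(species, sp_list)
        lx, ly, species = lx[keep], ly[keep], species[keep]
    if len(sp_list) < 3:
        raise ValueError("need at least 3 species for an interspecific fit")

    sp_index = {s: i for i, s in enumerate(sp_list)}
    sp_idx = np.array([sp_index[s] for s in species])
    S = len(sp_list)
    n_i = np.bincount(sp_idx, minlength=S).astype(float)
    Sx = np.bincount(sp_idx, weights=lx, minlength=S)
    Sy = np.bincount(sp_idx, weights=ly, minlength=S)

    if trees is None:
        # star phylogeny: Sigma = I, lambda unidentifiable
        Vs, ds, rep_index = [np.eye(S)], [np.ones(S)], np.array([0])
    else:
        prep_rng = np.random.default_rng(cfg.seed)
        individuals = {s: list(np.flatnonzero(species == s)) for s in sp_list}
        Vs, ds, rep_index = _prepare_trees(trees, sp_list, individuals,
                                           cfg.tree_replicates, prep_rng)

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains = [_run_hierarchical_chain(s, lx, ly, sp_idx, n_i, Sx, Sy,
                                      Vs, ds, rep_index, cfg)
              for s in seeds]
    return _pool_and_summarise(chains, cfg, "among", S, len(lx),
                               x_name, y_name,
                               with_lambda=cfg.fix_lambda is None)


def fit_intraspecific(x, y, species,
                      config: Optional[AllometryConfig] = None,
                      x_name: str = "x", y_name: str = "y",
                      ) -> AllometryFit:
    """Common within-species exponent by within-species centring.

    Species empirical means are subtracted from log10(x) and log10(y), the
    centred points are pooled and a single slope is estimated with the same
    flat priors as the interspecific model. Species with fewer than two
    individuals carry no within-species information and are excluded.
    """
    cfg = config or AllometryConfig()
    lx, ly, species = _prepare_xy(x, y, species, cfg)

    sp_list = sorted(set(species))
    counts = {s: int(np.sum(species == s)) for s in sp_list}
    usable = [s for s in sp_list if counts[s] >= 2]
    excluded = [s for s in sp_list if counts[s] < 2]
    if excluded:
        log.info("within-species centring excludes %d singleton species",
                 len(excluded))
    if not usable:
        raise ValueError("no species with >= 2 individuals")
    keep = np.isin(species, usable)
    lx, ly, species = lx[keep], ly[keep], species[keep]

    cx = np.empty_like(lx)
    cy = np.empty_like(ly)
    for s in usable:
        m = species == s
        cx[m] = lx[m] - lx[m].mean()
        cy[m] = ly[m] - ly[m].mean()

    n = len(cx)
    X = np.column_stack([np.ones(n), cx])
    XtX = X.T @ X
    Xty = X.T @ cy
    am, ap = cfg.intercept_prior
    bm, bp = cfg.slope_prior
    prior_prec = np.array([ap, bp])
    prior_mean = np.array([am, bm])

    def run_chain(seed):
        rng = np.random.default_rng(seed)
        beta = np.linalg.solve(XtX, Xty) + 0.05 * rng.standard_normal(2)
        s2 = max(float(np.var(cy - X @ beta)), 1e-8)
        keep_n = cfg.n_iter - cfg.burn_in
        out_b = np.empty(keep_n)
        out_a = np.empty(keep_n)
        out_s = np.empty(keep_n)
        for it in range(cfg.n_iter):
            A = XtX / s2 + np.diag(prior_prec)
            h = Xty / s2 + prior_prec * prior_mean
            beta = _sample_mvn_prec(A, h, rng)
            r = cy - X @ beta
            s2 = _sample_variance(float(r @ r), n, cfg, rng)
            j = it - cfg.burn_in
            if j >= 0:
                out_a[j], out_b[j] = beta
                out_s[j] = np.sqrt(s2)
        return dict(b=out_b, a=out_a, lam=None, sigma_resid=out_s)

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains = []
    for s in seeds:
        c = run_chain(s)
        c.pop("lam")
        chains.append(c)
    return _pool_and_summarise(chains, cfg, "within", len(usable), n,
                               x_name, y_name, with_lambda=False)


def fit_clade(x, y, species, clade_labels,
              trees: Optional[TreeEnsemble] = None,
              config: Optional[AllometryConfig] = None,
              slope_prior_mean: float = 0.0,
              reference: Optional[float] = None,
              x_name: str = "x", y_name: str = "y",
              ) -> dict[str, AllometryFit]:
    """Independent interspecific fits per clade with informative priors.

    Uses the hierarchical measurement-error model on a single tree (the
    first of ``trees``) without tree-ensemble integration, slope prior
    N(``slope_prior_mean``, tau=1) and gamma(1e-3, 1e-3) priors on
    precisions. Clades with fewer than 3 species are skipped with a log
    entry. When ``reference`` is given, each fit's summary gains a flag for
    whether its slope CI excludes it.
    """
    cfg = config or AllometryConfig()
    base = AllometryConfig(
        n_chains=cfg.n_chains, n_iter=cfg.n_iter, burn_in=cfg.burn_in,
        slope_prior=(slope_prior_mean, 1.0), intercept_prior=(0.0, 1.0),
        variance_prior="gamma_precision", gamma_prior=(1e-3, 1e-3),
        characteristic_scale=cfg.characteristic_scale,
        tree_replicates=1, fix_lambda=cfg.fix_lambda,
        fix_within_cov=cfg.fix_within_cov, seed=cfg.seed)

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    species = np.asarray(species)
    clade_labels = np.asarray(clade_labels)
    fits: dict[str, AllometryFit] = {}
    for clade in sorted(set(clade_labels)):
        m = clade_labels == clade
        sp = sorted(set(species[m]))
        if len(sp) < 3:
            log.info("clade %s skipped: only %d species", clade, len(sp))
            continue
        sub_trees = None
        if trees is not None:
            sub_trees = TreeEnsemble([trees.trees[0]],
                                     source=trees.source).pruned_to(sp)
        fit = fit_interspecific(x[m], y[m], species[m], sub_trees, base,
                                x_name=x_name, y_name=y_name)
        if reference is not None:
            lo, hi = fit.slope_ci
            fit.diagnostics["excludes_reference"] = not (lo <= reference <= hi)
            fit.diagnostics["reference"] = reference
        fits[str(clade)] = fit
    return fits


def summarize_fit(fit: AllometryFit,
                  references: Sequence[float] = (0.0, 1.0)) -> pd.DataFrame:
    """Posterior mean, 95% equal-tailed CI and reference-overlap flags."""
    if len(fit.posterior_b) < 100:
        raise ValueError("need at least 100 posterior draws to summarise")
    out = fit.summary.copy()
    for ref in references:
        out[f"overlaps_{ref:g}"] = [
            bool(row.ci_low <= ref <= row.ci_high)
            for row in out.itertuples()]
    return out
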