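"""Single-common-factor model of cognitive test scores (latent g).

General cognitive functioning (g) is modelled per cohort as a one-factor
confirmatory factor model: each observed test ``x_j = mu_j + lambda_j * g
+ e_j`` with ``Var(g)`` fixed at 1 for identification, so the loadings
``lambda_j`` are on a common scale across cohorts.  Estimation is
full-information maximum likelihood (FIML): the Gaussian likelihood is
evaluated casewise on each subject's observed subvector, so subjects with
partially missing test scores contribute the information they have.  On
complete data this reduces exactly to the usual covariance-based ML fit.

Residual covariances between tests of the same cognitive domain (e.g.
processing-speed tests sharing method variance) can be freed via
``residual_cov_groups``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GModel", "residualize_tests", "fit_one_factor", "fit_indices",
    "factor_scores", "mvn_em",
]


def residualize_tests(table: pd.DataFrame, tests: list[str],
                      covariates: tuple[str, ...] = ("age", "sex")) -> pd.DataFrame:
    """Replace each test score with its residual from an OLS fit on covariates.

    Complete cases per test; missing scores stay missing.  Residuals are
    orthogonal to the covariates and mean zero by construction.
    """
    for c in covariates:
        if c not in table.columns:
            raise ValueError(f"covariate {c!r} not in table")
    out = table.copy()
    C = table[list(covariates)].to_numpy(dtype=float)
    design_full = np.column_stack([np.ones(len(table)), C])
    for t in tests:
        y = table[t].to_numpy(dtype=float)
        ok = ~np.isnan(y) & ~np.isnan(design_full).any(axis=1)
        if np.nanstd(y[ok]) == 0:
            raise ValueError(f"test {t!r} has zero variance")
        beta, *_ = np.linalg.lstsq(design_full[ok], y[ok], rcond=None)
        resid = np.full_like(y, np.nan)
        resid[ok] = y[ok] - design_full[ok] @ beta
        out[t] = resid
    return out


@dataclass
class GModel:
    tests: list[str]
    lam: pd.Series                 # loadings, factor variance fixed at 1
    psi: pd.DataFrame              # residual covariance matrix (diag + freed pairs)
    mu: pd.Series
    rescov_pairs: list             # (test_i, test_j) freed residual covariances
    loglik: float
    ll_saturated: float
    ll_baseline: float
    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    n: int
    converged: bool
    grad_norm: float
    heywood: bool
    sample_mean: pd.Series         # saturated-model mean (EM under missingness)
    sample_cov: pd.DataFrame       # saturated-model covariance
    n_restarts_used: int = 0
    loglik_trace: list = field(default_factory=list)

    @property
    def implied_cov(self) -> pd.DataFrame:
        lam = self.lam.to_numpy()
        sigma = np.outer(lam, lam) + self.psi.to_numpy()
        return pd.DataFrame(sigma, index=self.tests, columns=self.tests)


# ---------------------------------------------------------------------------
# likelihood machinery


def _pattern_groups(X: np.ndarray):
    """Group row indices of X by missingness pattern."""
    mask = ~np.isnan(X)
    keys = [tuple(row) for row in mask]
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    return [(np.array(k, dtype=bool), np.array(v)) for k, v in groups.items()]


def _gauss_loglik_pattern(Xobs: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    m = Xobs.shape[1]
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    dev = Xobs - mu
    sol = np.linalg.solve(chol, dev.T)
    quad = (sol ** 2).sum()
    n = Xobs.shape[0]
    return -0.5 * (n * (m * np.log(2 * np.pi) + logdet) + quad)


def fiml_loglik(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray, patterns=None) -> float:
    """Casewise Gaussian log-likelihood over observed subvectors."""
    if patterns is None:
        patterns = _pattern_groups(X)
    ll = 0.0
    for mask, rows in patterns:
        if not mask.any():
            continue
        sub = X[np.ix_(rows, np.where(mask)[0])]
        ll += _gauss_loglik_pattern(sub, mu[mask], sigma[np.ix_(mask, mask)])
    return ll


def mvn_em(X: np.ndarray, max_iter: int = 500, tol: float = 1e-10):
    """ML mean/covariance of a multivariate normal with ignorable missingness.

    Standard EM sweep over missingness patterns; on complete data this is
    the sample mean and the biased (1/n) covariance in one step.
    """
    n, p = X.shape
    mu = np.nanmean(X, axis=0)
    dev = np.where(np.isnan(X), 0.0, X - mu)
    sigma = dev.T @ dev / n + np.eye(p) * 1e-6
    patterns = _pattern_groups(X)
    if len(patterns) == 1 and patterns[0][0].all():
        mu = X.mean(axis=0)
        dev = X - mu
        return mu, dev.T @ dev / n
    ll_old = -np.inf
    for _ in range(max_iter):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for mask, rows in patterns:
            o = np.where(mask)[0]
            m = np.where(~mask)[0]
            Xo = X[np.ix_(rows, o)]
            if len(m) == 0:
                xhat = X[rows]
                s1 += xhat.sum(axis=0)
                s2 += xhat.T @ xhat
                continue
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(m, o)]
            Smm = sigma[np.ix_(m, m)]
            B = np.linalg.solve(Soo, Smo.T).T           # m x o
            cond_cov = Smm - B @ Smo.T
            xm = mu[m] + (Xo - mu[o]) @ B.T
            xhat = np.empty((len(rows), p))
            xhat[:, o] = Xo
            xhat[:, m] = xm
            s1 += xhat.sum(axis=0)
            s2 += xhat.T @ xhat
            s2[np.ix_(m, m)] += len(rows) * cond_cov
        mu = s1 / n
        sigma = s2 / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2
        ll = fiml_loglik(X, mu, sigma, patterns)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return mu, sigma


def _baseline_loglik(X: np.ndarray) -> float:
    """FIML log-likelihood of the independence (diagonal covariance) model.

    With a diagonal covariance the casewise likelihood factorizes, so the
    per-variable ML mean/variance over observed values is exact.
    """
    ll = 0.0
    for j in range(X.shape[1]):
        x = X[:, j]
        x = x[~np.isnan(x)]
        v = x.var()
        ll += -0.5 * len(x) * (np.log(2 * np.pi * v) + 1.0)
    return ll


def _build_sigma(lam: np.ndarray, psi_diag: np.ndarray, psi_off: np.ndarray,
                 pairs: list[tuple[int, int]]) -> np.ndarray:
    sigma = np.outer(lam, lam) + np.diag(psi_diag)
    for (i, j), v in zip(pairs, psi_off):
        sigma[i, j] += v
        sigma[j, i] += v
    return sigma


def fit_one_factor(table: pd.DataFrame, tests: list[str] | None = None,
                   residual_cov_groups: dict[str, list[str]] | None = None,
                   max_restarts: int = 3, gtol: float = 1e-6,
                   seed: int = 0, force_fiml: bool = False) -> GModel:
    """Fit the one-factor model by FIML.

    Parameters
    ----------
    table : DataFrame
        Subject-level table; ``tests`` columns are the indicators
        (default: all columns).
    residual_cov_groups : dict, optional
        Named groups of test columns; every within-group pair gets a free
        residual covariance (e.g. the four cognitive domains of a
        multi-domain battery).
    """
    if tests is None:
        tests = list(table.columns)
    if len(tests) < 3:
        raise ValueError("need at least 3 tests to identify a one-factor model")
    X = table[tests].to_numpy(dtype=float)
    X = X[~np.isnan(X).all(axis=1)]
    n, p = X.shape

    pairs: list[tuple[int, int]] = []
    if residual_cov_groups:
        tindex = {t: i for i, t in enumerate(tests)}
        for members in residual_cov_groups.values():
            idx = [tindex[m] for m in members]
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    pairs.append((min(idx[a], idx[b]), max(idx[a], idx[b])))
        pairs = sorted(set(pairs))
    m_off = len(pairs)
    df = p * (p + 1) // 2 - (2 * p + m_off)
    if df < 0:
        raise ValueError(f"model under-identified: df = {df} < 0")

    patterns = _pattern_groups(X)
    complete = len(patterns) == 1 and patterns[0][0].all() and not force_fiml
    if complete:
        xbar = X.mean(axis=0)
        S = (X - xbar).T @ (X - xbar) / n

        def negll(theta):
            mu, lam, psd, pso = _split(theta)
            sigma = _build_sigma(lam, psd, pso, pairs)
            try:
                chol = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                return 1e12
            logdet = 2 * np.log(np.diag(chol)).sum()
            inv = np.linalg.inv(sigma)
            d = xbar - mu
            val = n * (p * np.log(2 * np.pi) + logdet
                       + np.trace(S @ inv) + d @ inv @ d) / 2
            return val
    else:
        def negll(theta):
            mu, lam, psd, pso = _split(theta)
            sigma = _build_sigma(lam, psd, pso, pairs)
            ll = fiml_loglik(X, mu, sigma, patterns)
            return 1e12 if not np.isfinite(ll) else -ll

    def _split(theta):
        mu = theta[:p]
        lam = theta[p:2 * p]
        psd = theta[2 * p:3 * p]
        pso = theta[3 * p:]
        return mu, lam, psd, pso

    col_mean = np.nanmean(X, axis=0)
    col_var = np.nanvar(X, axis=0)
    corr = pd.DataFrame(X).corr().to_numpy()
    rbar = np.clip(np.nanmean(corr[np.triu_indices(p, 1)]), 0.05, 0.9)
    lam0 = np.sqrt(rbar * col_var)
    theta0 = np.concatenate([col_mean, lam0, (1 - rbar) * col_var, np.zeros(m_off)])

    rng = np.random.default_rng(seed)
    best = None
    restarts = 0
    trace: list[float] = []
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 * rng.uniform(0.5, 1.5, theta0.size)
        cb_trace: list[float] = []
        res = optimize.minimize(
            negll, start, method="L-BFGS-B",
            callback=lambda th: cb_trace.append(-negll(th)),
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": gtol / 10},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        ok = res.success or gnorm < gtol * max(1.0, abs(res.fun))
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm, ok, cb_trace)
        if ok:
            break
        restarts = attempt + 1
    res, gnorm, converged, trace = best
    mu_hat, lam_hat, psd_hat, pso_hat = _split(res.x)
    if lam_hat.mean() < 0:           # orientation: positive mean loading
        lam_hat = -lam_hat

    heywood = bool((psd_hat < 0).any())
    if heywood:
        warnings.warn("Heywood case: negative residual variance at solution "
                      "(reported as estimated, not truncated)")

    sat_mu, sat_sigma = mvn_em(X)
    ll_sat = fiml_loglik(X, sat_mu, sat_sigma, patterns)
    ll_model = -float(negll(np.concatenate([mu_hat, lam_hat, psd_hat, pso_hat])))
    ll_base = _baseline_loglik(X)

    psi = np.diag(psd_hat)
    for (i, j), v in zip(pairs, pso_hat):
        psi[i, j] = psi[j, i] = v

    return GModel(
        tests=list(tests),
        lam=pd.Series(lam_hat, index=tests, name="lambda"),
        psi=pd.DataFrame(psi, index=tests, columns=tests),
        mu=pd.Series(mu_hat, index=tests, name="mu"),
        rescov_pairs=[(tests[i], tests[j]) for i, j in pairs],
        loglik=ll_model,
        ll_saturated=float(ll_sat),
        ll_baseline=float(ll_base),
        chi2=max(0.0, 2 * (ll_sat - ll_model)),
        df=df,
        chi2_baseline=max(0.0, 2 * (ll_sat - ll_base)),
        df_baseline=p * (p - 1) // 2,
        n=n,
        converged=bool(converged),
        grad_norm=gnorm,
        heywood=heywood,
        sample_mean=pd.Series(sat_mu, index=tests),
        sample_cov=pd.DataFrame(sat_sigma, index=tests, columns=tests),
        n_restarts_used=restarts,
        loglik_trace=trace,
    )


def fit_indices(model: GModel, n: int | None = None) -> dict:
    """CFI, TLI, RMSEA and SRMR from the fitted and baseline models.

    Baseline = independence (diagonal covariance) model.  With df = 0 the
    model is saturated: RMSEA is 0 by definition and TLI is undefined
    (returned as NaN).
    """
    n = n or model.n
    t, df = model.chi2, model.df
    tb, dfb = model.chi2_baseline, model.df_baseline
    d = max(t - df, 0.0)
    db = max(tb - dfb, 0.0)
    cfi = 1.0 if (db == 0 and d == 0) else 1.0 - d / max(db, d)
    if df == 0:
        tli = np.nan
        rmsea = 0.0
    else:
        denom = tb / dfb - 1.0
        tli = np.nan if denom == 0 else (tb / dfb - t / df) / denom
        rmsea = float(np.sqrt(d / (df * n)))

    S = model.sample_cov.to_numpy()
    sig = model.implied_cov.to_numpy()
    sd = np.sqrt(np.diag(S))
    resid = (S - sig) / np.outer(sd, sd)
    iu = np.triu_indices(S.shape[0])
    srmr = float(np.sqrt((resid[iu] ** 2).mean()))
    return {"CFI": float(cfi), "TLI": float(tli) if np.isfinite(tli) else np.nan,
            "RMSEA": rmsea, "SRMR": srmr, "chi2": t, "df": df}


def factor_scores(model: GModel, table: pd.DataFrame) -> pd.Series:
    """Regression-method factor scores, one per subject.

    ``g_i = lambda' Sigma^-1 (x_i - mu)`` on each subject's observed
    subvector; orientation fixed so that g correlates positively with the
    mean of the standardized test scores.
    """
    X = table[model.tests].to_numpy(dtype=float)
    lam = model.lam.to_numpy()
    sigma = model.implied_cov.to_numpy()
    mu = model.mu.to_numpy()
    scores = np.full(X.shape[0], np.nan)
    for mask, rows in _pattern_groups(X):
        if not mask.any():
            continue
        o = np.where(mask)[0]
        so = sigma[np.ix_(o, o)]
        try:
            w = np.linalg.solve(so, lam[o])
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("singular implied covariance") from err
        scores[rows] = (X[np.ix_(rows, o)] - mu[o]) @ w
    z = (X - np.nanmean(X, axis=0)) / np.nanstd(X, axis=0)
    proxy = np.nanmean(z, axis=1)
    ok = ~np.isnan(scores) & ~np.isnan(proxy)
    if ok.sum() > 2 and np.corrcoef(scores[ok], proxy[ok])[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=table.index, name="g")
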