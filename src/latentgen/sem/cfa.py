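"""Confirmatory factor / structural models by full-information ML.

The casewise (FIML) log-likelihood

    l(theta) = sum_i -0.5 [ k_i log 2pi + log|Sigma_i(theta)|
                            + (y_i - mu_i)' Sigma_i(theta)^{-1} (y_i - mu_i) ]

is evaluated over each observation's observed variable subset, which makes
the estimates valid under MAR missingness.  Observations sharing a
missingness pattern share sufficient statistics (count, mean, within-
pattern covariance), so one likelihood evaluation costs O(#patterns), not
O(n).  The mean structure is saturated (free means); the covariance
structure is Sigma = Lambda Phi Lambda' + Theta with the patterns of
:class:`~latentgen.sem.model.ModelSpec` and, optionally, a second-order
layer Phi = B B' + D with unit first-order variances.

Optimization is quasi-Newton (L-BFGS-B) on the free parameters with
analytic gradients (which the test suite verifies against finite
differences).  The likelihood-ratio statistic is chi2 = 2(l_sat - l_model),
where the saturated mean/covariance MLE under missingness is obtained by
EM.  Standard errors come from the inverse observed information (numerical
differentiation of the analytic gradient).  If the implied covariance goes
indefinite during the search, a minimal ridge is applied and penalized so
the optimizer is steered back to the PD region; use at the optimum is
flagged, never silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import ModelSpec

__all__ = [
    "FitResult",
    "ConfirmatoryFactorModel",
    "fit_cfa_fiml",
    "compute_fit_indices",
    "saturated_mean_cov",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# missingness-pattern sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class _Pattern:
    idx: np.ndarray
    n: int
    ybar: np.ndarray
    S: np.ndarray  # within-pattern covariance, n divisor


def _build_patterns(Y: np.ndarray) -> tuple[list[_Pattern], int]:
    obs = ~np.isnan(Y)
    keep = obs.any(axis=1)
    Y, obs = Y[keep], obs[keep]
    pats: dict[bytes, list[int]] = {}
    for i, row in enumerate(obs):
        pats.setdefault(row.tobytes(), []).append(i)
    out = []
    for key, rows in pats.items():
        mask = np.frombuffer(key, dtype=bool)
        idx = np.where(mask)[0]
        block = Y[np.ix_(rows, idx)]
        ybar = block.mean(axis=0)
        centered = block - ybar
        S = centered.T @ centered / len(rows)
        out.append(_Pattern(idx=idx, n=len(rows), ybar=ybar, S=S))
    out.sort(key=lambda p: -p.n)
    return out, int(keep.sum())


def _loglik_mu_sigma(patterns: list[_Pattern], mu: np.ndarray, Sigma: np.ndarray) -> float:
    """FIML log-likelihood of an unstructured (mu, Sigma)."""
    ll = 0.0
    for p in patterns:
        sub = Sigma[np.ix_(p.idx, p.idx)]
        sign, logdet = np.linalg.slogdet(sub)
        if sign <= 0:
            return -np.inf
        iS = np.linalg.inv(sub)
        r = p.ybar - mu[p.idx]
        ll += -0.5 * p.n * (
            len(p.idx) * _LOG2PI + logdet + float(np.sum(iS * p.S)) + float(r @ iS @ r)
        )
    return ll


def saturated_mean_cov(
    patterns: list[_Pattern], p: int, tol: float = 1e-8, max_iter: int = 2000
) -> tuple[np.ndarray, np.ndarray, float]:
    """EM for the saturated (mu, Sigma) MLE under missing data.

    With complete data this reduces to the sample mean and the n-divisor
    covariance in a single step.  Returns (mu, Sigma, loglik).
    """
    n = sum(pt.n for pt in patterns)
    # initialize from available-case moments
    mu = np.zeros(p)
    var = np.ones(p)
    cnt = np.zeros(p)
    for pt in patterns:
        mu[pt.idx] += pt.n * pt.ybar
        cnt[pt.idx] += pt.n
        var[pt.idx] += pt.n * np.diag(pt.S)
    mu = mu / np.maximum(cnt, 1)
    Sigma = np.diag(np.maximum(var / np.maximum(cnt, 1), 1e-8))

    complete = len(patterns) == 1 and len(patterns[0].idx) == p
    if complete:
        pt = patterns[0]
        mu = pt.ybar.copy()
        Sigma = pt.S.copy()
        return mu, Sigma, _loglik_mu_sigma(patterns, mu, Sigma)

    ll = _loglik_mu_sigma(patterns, mu, Sigma)
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        for pt in patterns:
            o = pt.idx
            m = np.setdiff1d(np.arange(p), o, assume_unique=True)
            So = Sigma[np.ix_(o, o)]
            iSo = np.linalg.inv(So)
            d = pt.ybar - mu[o]
            Eyo = pt.n * pt.ybar
            Syy = pt.n * (pt.S + np.outer(pt.ybar, pt.ybar))
            T1[o] += Eyo
            T2[np.ix_(o, o)] += Syy
            if m.size:
                W = Sigma[np.ix_(m, o)] @ iSo
                mbar = mu[m] + W @ d  # mean of conditional means
                T1[m] += pt.n * mbar
                # sum_i E[y_m y_o'] = n*mu_m ybar' + W * sum_i (y_o - mu_o) y_o'
                Cyo = pt.n * (pt.S + np.outer(pt.ybar - mu[o], pt.ybar))
                Tmo = pt.n * np.outer(mu[m], pt.ybar) + W @ Cyo
                T2[np.ix_(m, o)] += Tmo
                T2[np.ix_(o, m)] += Tmo.T
                cond_cov = Sigma[np.ix_(m, m)] - W @ Sigma[np.ix_(o, m)]
                Smm = pt.n * (pt.S + np.outer(d, d))
                T2[np.ix_(m, m)] += pt.n * cond_cov + (
                    pt.n * np.outer(mu[m], mu[m])
                    + np.outer(mu[m], d) @ W.T * pt.n
                    + pt.n * W @ np.outer(d, mu[m])
                    + W @ Smm @ W.T
                )
        mu = T1 / n
        Sigma = T2 / n - np.outer(mu, mu)
        Sigma = (Sigma + Sigma.T) / 2.0
        new_ll = _loglik_mu_sigma(patterns, mu, Sigma)
        if abs(new_ll - ll) < tol:
            ll = new_ll
            break
        ll = new_ll
    return mu, Sigma, ll


def _baseline_loglik(patterns: list[_Pattern], p: int) -> tuple[float, int]:
    """Independence model: per-variable observed-case mean/variance MLE."""
    ll = 0.0
    for j in range(p):
        n_j = sum(pt.n for pt in patterns if j in pt.idx)
        if n_j == 0:
            continue
        mean = sum(
            pt.n * pt.ybar[list(pt.idx).index(j)] for pt in patterns if j in pt.idx
        ) / n_j
        ss = 0.0
        for pt in patterns:
            if j not in pt.idx:
                continue
            jj = list(pt.idx).index(j)
            ss += pt.n * (pt.S[jj, jj] + (pt.ybar[jj] - mean) ** 2)
        var = max(ss / n_j, 1e-12)
        ll += -0.5 * n_j * (_LOG2PI + np.log(var) + 1.0)
    df = p * (p + 3) // 2 - 2 * p
    return ll, df


# ---------------------------------------------------------------------------
# parameter mapping
# ---------------------------------------------------------------------------

class _ParamMap:
    """Maps the free-parameter vector onto (Lambda, Phi/B, Theta, mu)."""

    def __init__(self, spec: ModelSpec, col_var: np.ndarray, col_mean: np.ndarray):
        self.spec = spec
        p, k = spec.n_indicators, spec.n_latents
        self.entries: list[tuple[str, list[tuple]]] = []
        start: list[float] = []
        bounds: list[tuple] = []

        tied = {pos for g in spec.loading_ties for pos in g}
        lam_free = [
            (i, j)
            for i in range(p)
            for j in range(k)
            if np.isnan(spec.loadings[i, j]) and (i, j) not in tied
        ]
        n_row_free = np.isnan(spec.loadings).sum(axis=1)
        sd = np.sqrt(np.maximum(col_var, 1e-8))
        for (i, j) in lam_free:
            self.entries.append(("lam", [(i, j)]))
            start.append(0.55 * sd[i] / max(np.sqrt(n_row_free[i]), 1.0))
            bounds.append((None, None))
        for group in spec.loading_ties:
            self.entries.append(("lam", list(group)))
            i0 = group[0][0]
            start.append(0.55 * sd[i0] / max(np.sqrt(n_row_free[i0]), 1.0))
            bounds.append((None, None))
        if spec.second_order is None:
            for i in range(k):
                for j in range(i):
                    if np.isnan(spec.factor_cov[i, j]):
                        self.entries.append(("phi", [(i, j)]))
                        start.append(0.2)
                        bounds.append((-0.98, 0.98))
        else:
            so = spec.second_order
            positions = [
                (i, j)
                for i in range(so.loadings.shape[0])
                for j in range(so.loadings.shape[1])
                if np.isnan(so.loadings[i, j])
            ]
            if so.equal_loadings and positions:
                self.entries.append(("so", positions))
                start.append(0.6)
                bounds.append((-0.98, 0.98))
            else:
                for pos in positions:
                    self.entries.append(("so", [pos]))
                    start.append(0.6)
                    bounds.append((-0.98, 0.98))
        for i in range(p):
            if np.isnan(spec.residual_var[i]):
                self.entries.append(("theta", [(i,)]))
                start.append(0.5 * col_var[i])
                bounds.append((1e-8, None))
        for i in range(p):
            self.entries.append(("mu", [(i,)]))
            start.append(col_mean[i])
            bounds.append((None, None))
        self.start = np.array(start)
        self.bounds = bounds

    def unpack(self, theta: np.ndarray):
        spec = self.spec
        lam = np.nan_to_num(spec.loadings.copy())
        th = np.nan_to_num(spec.residual_var.copy())
        mu = np.zeros(spec.n_indicators)
        B = None
        if spec.second_order is not None:
            B = np.nan_to_num(spec.second_order.loadings.copy())
        phi = np.nan_to_num(spec.factor_cov.copy())
        for val, (kind, positions) in zip(theta, self.entries):
            if kind == "lam":
                for (i, j) in positions:
                    lam[i, j] = val
            elif kind == "phi":
                for (i, j) in positions:
                    phi[i, j] = phi[j, i] = val
            elif kind == "so":
                for pos in positions:
                    B[pos] = val
            elif kind == "theta":
                th[positions[0][0]] = val
            else:
                mu[positions[0][0]] = val
        if B is not None:
            D = np.clip(1.0 - (B**2).sum(axis=1), 1e-8, None)
            phi = B @ B.T + np.diag(D)
        return lam, phi, th, mu, B

    def pack_gradient(self, dLam, dPhi, dTheta, dMu, lam, phi, B) -> np.ndarray:
        spec = self.spec
        g = np.empty(len(self.entries))
        if B is not None:
            # chain through Phi = B B' + diag(1 - rowsum(B^2))
            H = dPhi  # dF/dPhi as a full symmetric matrix
            dB = 2.0 * (H @ B)
            dB -= 2.0 * np.diag(H)[:, None] * B
        for t, (kind, positions) in enumerate(self.entries):
            if kind == "lam":
                g[t] = sum(dLam[i, j] for (i, j) in positions)
            elif kind == "phi":
                i, j = positions[0]
                g[t] = 2.0 * dPhi[i, j]
            elif kind == "so":
                g[t] = sum(dB[pos] for pos in positions)
            elif kind == "theta":
                g[t] = dTheta[positions[0][0]]
            else:
                g[t] = dMu[positions[0][0]]
        return g


# ---------------------------------------------------------------------------
# FIML objective
# ---------------------------------------------------------------------------

def _objective(theta, pmap: _ParamMap, patterns, n_used, want_grad=True, penalty=1e3):
    lam, phi, th, mu, B = pmap.unpack(theta)
    Sigma = lam @ phi @ lam.T + np.diag(th)
    Sigma = (Sigma + Sigma.T) / 2.0
    ridge = 0.0
    evec = None
    w, V = np.linalg.eigh(Sigma)
    if w[0] < 1e-10:
        ridge = 1e-10 - w[0]
        evec = V[:, 0]
        Sigma = Sigma + ridge * np.eye(len(mu))

    ll = 0.0
    G = np.zeros_like(Sigma)
    gmu = np.zeros_like(mu)
    for pt in patterns:
        sub = Sigma[np.ix_(pt.idx, pt.idx)]
        sign, logdet = np.linalg.slogdet(sub)
        if sign <= 0:
            return (np.inf, np.zeros_like(theta)) if want_grad else np.inf
        iS = np.linalg.inv(sub)
        r = pt.ybar - mu[pt.idx]
        iSr = iS @ r
        ll += -0.5 * pt.n * (
            len(pt.idx) * _LOG2PI + logdet + float(np.sum(iS * pt.S)) + float(r @ iSr)
        )
        if want_grad:
            M = iS @ (pt.S + np.outer(r, r)) @ iS
            G[np.ix_(pt.idx, pt.idx)] += -0.5 * pt.n * (iS - M)
            gmu[pt.idx] += pt.n * iSr

    f = -ll / n_used + penalty * ridge
    if not want_grad:
        return f
    # dF/dSigma = -G/n + penalty * d(1e-10 - lambda_min)/dSigma = -G/n - penalty*vv'
    Gf = -G / n_used
    if ridge > 0:
        Gf -= penalty * np.outer(evec, evec)
    dLam = 2.0 * Gf @ lam @ phi
    dPhi = lam.T @ Gf @ lam
    dTheta = np.diag(Gf).copy()
    dMu = -gmu / n_used
    grad = pmap.pack_gradient(dLam, dPhi, dTheta, dMu, lam, phi, B)
    return f, grad


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted latent model: estimates, likelihood, fit statistics."""

    spec: ModelSpec
    estimates: dict[str, float]
    se: dict[str, float]
    loadings: np.ndarray
    factor_cov: np.ndarray
    residual_var: np.ndarray
    means: np.ndarray
    second_order_loadings: np.ndarray | None
    loglik: float
    loglik_sat: float
    chi2: float
    df: int
    n_used: int
    fit_indices: dict[str, float]
    converged: bool
    grad_norm: float
    implied_cov: np.ndarray
    implied_means: np.ndarray
    saturated_cov: np.ndarray
    saturated_mean: np.ndarray
    flags: list[str] = field(default_factory=list)


@dataclass
class _BaselineFit:
    chi2: float
    df: int
    n_used: int


def compute_fit_indices(fit, baseline) -> dict[str, float]:
    """RMSEA / CFI / TLI / SRMR from a fitted model and its independence
    baseline (same cases).

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1))); df = 0 gives RMSEA 0
    with an ``rmsea_undefined`` flag.  CFI and TLI compare noncentrality
    against the baseline; SRMR is the root mean square standardized
    residual between the saturated and model-implied covariances
    (diagonal included).
    """
    chi2_m, df_m, n = fit.chi2, fit.df, fit.n_used
    chi2_b, df_b = baseline.chi2, baseline.df
    out: dict[str, float] = {}
    flags = []
    if df_m > 0:
        out["rmsea"] = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * (n - 1))))
    else:
        out["rmsea"] = 0.0
        flags.append("rmsea_undefined")
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    out["cfi"] = 1.0 - (num / den if den > 0 else 0.0)
    if df_m > 0 and df_b > 0 and chi2_b / df_b > 1.0:
        out["tli"] = ((chi2_b / df_b) - (chi2_m / df_m)) / ((chi2_b / df_b) - 1.0)
    else:
        out["tli"] = 1.0
        flags.append("tli_undefined" if df_m == 0 else "tli_saturated_baseline")
    S = getattr(fit, "saturated_cov", None)
    Sig = getattr(fit, "implied_cov", None)
    if S is not None and Sig is not None:
        ds = np.sqrt(np.diag(S))
        dsig = np.sqrt(np.diag(Sig))
        Rs = S / np.outer(ds, ds)
        Rm = Sig / np.outer(dsig, dsig)
        # standardized residuals including the diagonal (variance residuals
        # enter through the scale difference of the two standardizations)
        resid = Rs - Rm
        iu = np.triu_indices_from(resid)
        out["srmr"] = float(np.sqrt(np.mean(resid[iu] ** 2)))
    if flags:
        out["flags"] = flags  # type: ignore[assignment]
    return out


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class ConfirmatoryFactorModel:
    """Confirmatory factor model fitted by FIML (or complete-data ML).

    Parameters
    ----------
    spec : ModelSpec
        Loading / factor-covariance / residual patterns.
    method : {"fiml", "ml"}
        ``fiml`` uses every observation's observed subset (MAR-valid);
        ``ml`` minimizes the covariance-ML discrepancy
        F = log|Sigma| + tr(S Sigma^-1) - log|S| - p on complete cases and
        exists mainly as an independent cross-check (with complete data the
        two coincide).
    compute_se : bool
        Standard errors from the inverse observed information (numerical
        differentiation of the analytic gradient); disable for speed in
        simulation loops.

    Fitted attributes: ``loadings_``, ``factor_corr_``, ``residual_vars_``,
    ``means_``, ``chi2_``, ``df_``, ``fit_indices_``, ``converged_``,
    ``result_`` (:class:`FitResult`), and :meth:`transform` returns factor
    scores.
    """

    def __init__(
        self,
        spec: ModelSpec,
        method: str = "fiml",
        max_iter: int = 2000,
        compute_se: bool = True,
    ):
        self.spec = spec
        self.method = method
        self.max_iter = max_iter
        self.compute_se = compute_se

    def get_params(self, deep: bool = True):
        return {
            "spec": self.spec,
            "method": self.method,
            "max_iter": self.max_iter,
            "compute_se": self.compute_se,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- fitting ----------------------------------------------------------
    def fit(self, X) -> "ConfirmatoryFactorModel":
        df = X.df if hasattr(X, "df") else X
        missing_cols = [c for c in self.spec.indicators if c not in df.columns]
        if missing_cols:
            raise KeyError(f"data lacks indicator columns: {missing_cols}")
        Y = df[self.spec.indicators].to_numpy(dtype=np.float64)
        if self.method == "ml":
            Y = Y[~np.isnan(Y).any(axis=1)]
        patterns, n_used = _build_patterns(Y)
        if n_used == 0:
            raise ValueError("no cases with at least one observed indicator")
        p = self.spec.n_indicators
        col_mean = np.nanmean(Y, axis=0)
        col_var = np.nanvar(Y, axis=0)
        pmap = _ParamMap(self.spec, col_var, col_mean)

        if self.method == "ml":
            theta, flags = self._optimize_ml(pmap, patterns, n_used)
        elif self.method == "fiml":
            theta, flags = self._optimize_fiml(pmap, patterns, n_used)
        else:
            raise ValueError(f"unknown method {self.method!r}")

        f, grad = _objective(theta, pmap, patterns, n_used)
        grad_norm = float(np.max(np.abs(grad)))
        lam, phi, th, mu, B = pmap.unpack(theta)
        Sigma = lam @ phi @ lam.T + np.diag(th)
        if np.linalg.eigvalsh(Sigma)[0] < 1e-10:
            flags.append("ridged_at_optimum")
        loglik = _loglik_mu_sigma(patterns, mu, Sigma)
        converged = bool(np.isfinite(loglik)) and grad_norm < 1e-5

        se_map: dict[str, float] = {}
        if self.compute_se:
            se_vec = self._observed_info_se(theta, pmap, patterns, n_used)
        else:
            se_vec = np.full(theta.size, np.nan)

        # resolve sign indeterminacy: each latent's loading sum positive
        signs = np.ones(self.spec.n_latents)
        for j in range(self.spec.n_latents):
            if lam[:, j].sum() < 0:
                signs[j] = -1.0
        lam = lam * signs
        phi = phi * np.outer(signs, signs)
        if B is not None:
            B = B * signs[:, None]

        mu_s, Sig_s, ll_sat = saturated_mean_cov(patterns, p)
        chi2 = 2.0 * (ll_sat - loglik)
        if chi2 < 0:
            if chi2 < -1e-4:
                flags.append("negative_chi2_clamped")
            chi2 = 0.0
        dof = self.spec.degrees_of_freedom()
        ll_b, df_b = _baseline_loglik(patterns, p)
        baseline = _BaselineFit(chi2=max(2.0 * (ll_sat - ll_b), 0.0), df=df_b, n_used=n_used)

        names = self._param_names(pmap)
        estimates = dict(zip(names, self._flip_values(theta, pmap, signs)))
        se_map = dict(zip(names, se_vec))

        result = FitResult(
            spec=self.spec,
            estimates=estimates,
            se=se_map,
            loadings=lam,
            factor_cov=phi,
            residual_var=th,
            means=mu,
            second_order_loadings=B,
            loglik=loglik,
            loglik_sat=ll_sat,
            chi2=float(chi2),
            df=dof,
            n_used=n_used,
            fit_indices={},
            converged=converged,
            grad_norm=grad_norm,
            implied_cov=lam @ phi @ lam.T + np.diag(th),
            implied_means=mu,
            saturated_cov=Sig_s,
            saturated_mean=mu_s,
            flags=flags,
        )
        result.fit_indices = compute_fit_indices(result, baseline)
        result.fit_indices["chi2_baseline"] = baseline.chi2
        result.fit_indices["df_baseline"] = baseline.df

        self.loadings_ = lam
        self.factor_corr_ = phi
        self.residual_vars_ = th
        self.means_ = mu
        self.second_order_loadings_ = B
        self.chi2_ = float(chi2)
        self.df_ = dof
        self.loglik_ = loglik
        self.n_used_ = n_used
        self.fit_indices_ = result.fit_indices
        self.converged_ = converged
        self.result_ = result
        return self

    def transform(self, X, method: str = "regression"):
        from .scores import extract_factor_scores

        return extract_factor_scores(self.result_, X, method=method).scores

    # -- internals --------------------------------------------------------
    def _optimize_fiml(self, pmap, patterns, n_used):
        res = optimize.minimize(
            _objective,
            pmap.start,
            args=(pmap, patterns, n_used),
            jac=True,
            method="L-BFGS-B",
            bounds=pmap.bounds,
            options={"maxiter": self.max_iter, "maxfun": 10 * self.max_iter,
                     "ftol": 1e-13, "gtol": 1e-9},
        )
        flags = [] if res.success else [f"optimizer: {res.message}"]
        return res.x, flags

    def _optimize_ml(self, pmap, patterns, n_used):
        """Independent complete-data route: minimize the ML discrepancy
        F = log|Sigma| + tr(S Sigma^-1) - log|S| - p (numeric gradient)."""
        pt = patterns[0]
        if len(patterns) != 1 or len(pt.idx) != self.spec.n_indicators:
            raise ValueError("method='ml' requires complete data")
        S = pt.S
        sign, logdetS = np.linalg.slogdet(S)
        p = S.shape[0]
        mu_idx = [t for t, (kind, _) in enumerate(pmap.entries) if kind == "mu"]
        cov_idx = [t for t, (kind, _) in enumerate(pmap.entries) if kind != "mu"]

        def fml(x):
            theta = pmap.start.copy()
            theta[cov_idx] = x
            theta[mu_idx] = pt.ybar
            lam, phi, th, _, _ = pmap.unpack(theta)
            Sigma = lam @ phi @ lam.T + np.diag(th)
            s2, ld = np.linalg.slogdet(Sigma)
            if s2 <= 0:
                return 1e10
            return ld + float(np.sum(np.linalg.inv(Sigma) * S)) - logdetS - p

        x0 = pmap.start[cov_idx] * 1.05 + 1e-3
        res = optimize.minimize(
            fml, x0, method="L-BFGS-B",
            bounds=[pmap.bounds[t] for t in cov_idx],
            options={"maxiter": self.max_iter, "ftol": 1e-15, "gtol": 1e-10},
        )
        theta = pmap.start.copy()
        theta[cov_idx] = res.x
        theta[mu_idx] = pt.ybar
        flags = [] if res.success else [f"optimizer: {res.message}"]
        return theta, flags

    def _observed_info_se(self, theta, pmap, patterns, n_used):
        q = theta.size
        H = np.empty((q, q))
        for i in range(q):
            h = 1e-5 * (1.0 + abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            _, gp = _objective(tp, pmap, patterns, n_used)
            _, gm = _objective(tm, pmap, patterns, n_used)
            H[i] = (gp - gm) / (2.0 * h)
        H = (H + H.T) / 2.0 * n_used  # total-likelihood information
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cov = np.linalg.pinv(H)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))

    def _param_names(self, pmap):
        spec = self.spec
        names = []
        for kind, positions in pmap.entries:
            if kind == "lam":
                i, j = positions[0]
                names.append(f"lambda[{spec.indicators[i]}~{spec.latents[j]}]")
            elif kind == "phi":
                i, j = positions[0]
                names.append(f"phi[{spec.latents[j]}~{spec.latents[i]}]")
            elif kind == "so":
                i, j = positions[0]
                names.append(f"gamma[{spec.latents[i]}~{spec.second_order.names[j]}]")
            elif kind == "theta":
                names.append(f"theta[{spec.indicators[positions[0][0]]}]")
            else:
                names.append(f"mu[{spec.indicators[positions[0][0]]}]")
        return names

    def _flip_values(self, theta, pmap, signs):
        out = theta.copy()
        for t, (kind, positions) in enumerate(pmap.entries):
            if kind == "lam":
                _, j = positions[0]
                out[t] *= signs[j]
            elif kind == "phi":
                i, j = positions[0]
                out[t] *= signs[i] * signs[j]
            elif kind == "so":
                i, _ = positions[0]
                out[t] *= signs[i]
        return out


def fit_cfa_fiml(table, spec: ModelSpec, **kwargs) -> FitResult:
    """Fit ``spec`` to a phenotype table (or DataFrame) by FIML."""
    return ConfirmatoryFactorModel(spec, method="fiml", **kwargs).fit(table).result_
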