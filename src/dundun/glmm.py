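"""Mixed-effects logistic regression of perceived category.

The perception model is a binomial GLMM:

    perceived_music ~ acoustic features + familiarity + confidence
                      + familiarity x (features, confidence)
                      + (1 | participant) + (1 | stimulus)

fit by maximum likelihood with the Laplace approximation: for candidate
random-intercept SDs, the joint penalized log-likelihood is maximized over
(beta, u) by Newton iterations, and the profiled Laplace objective

    ll(beta_hat, u_hat) - u'L^-1 u / 2 - log det(I + Lambda Z'WZ) / 2

is optimized over the two variance components.  Wald standard errors come
from the beta block of the inverse joint Hessian (the Schur complement used
by standard mixed-model software), odds-ratio CIs are Wald on the log-odds
scale, and R^2 follows the Nakagawa latent-scale decomposition with logistic
residual variance pi^2/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.special import expit

from .behavior import ConfusionCounts, accuracy as _accuracy, mcc as _mcc

__all__ = ["GLMMResult", "fit_logistic_glmm", "fit_perception_glmm", "build_model_matrix"]

DEFAULT_ACOUSTIC = [
    "mean_intensity",
    "mean_pitch",
    "mean_timbre",
    "mean_ioi_ms",
    "mean_pitch_change",
    "mean_intensity_change",
    "mean_timbre_change",
    "mean_interval_ratio",
    "ams_peak_hz",
    "pulse_clarity",
]


@dataclass
class GLMMResult:
    terms: pd.DataFrame                 # term, beta, se, z, p, odds_ratio, ci_low, ci_high, stars
    var_participant: float
    var_stimulus: float
    marginal_r2: float
    conditional_r2: float
    prediction_accuracy: float          # conditional (includes random intercepts)
    prediction_mcc: float
    prediction_accuracy_marginal: float
    prediction_mcc_marginal: float
    loglik: float
    converged: bool
    n_obs: int
    random_effects: dict = field(default_factory=dict, repr=False)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


class _LaplaceCore:
    """Profiled-Laplace objective for a Bernoulli GLMM with crossed intercepts."""

    def __init__(self, y, X, group_codes):
        self.y = np.asarray(y, dtype=np.float64)
        self.X = np.asarray(X, dtype=np.float64)
        self.n, self.p = self.X.shape
        self.sizes = []
        zs = []
        for codes in group_codes:
            codes = np.asarray(codes)
            q = codes.max() + 1
            self.sizes.append(q)
            zs.append(sparse.csr_matrix(
                (np.ones(self.n), (np.arange(self.n), codes)), shape=(self.n, q)
            ))
        self.Z = sparse.hstack(zs, format="csr")
        self.q = self.Z.shape[1]
        self.state = np.zeros(self.p + self.q)  # warm start across outer evals

    def _prec_diag(self, sds):
        prec = np.concatenate([
            np.full(q, 1.0 / max(sd, 1e-6) ** 2) for q, sd in zip(self.sizes, sds)
        ])
        return prec

    def _inner_newton(self, sds, tol=1e-9, max_iter=100):
        """Maximize ll + log prior over (beta, u) jointly."""
        y, X, Z = self.y, self.X, self.Z
        prec = self._prec_diag(sds)
        theta = self.state.copy()

        def penalized(theta):
            beta, u = theta[: self.p], theta[self.p :]
            eta = X @ beta + Z @ u
            ll = np.sum(y * eta - np.logaddexp(0.0, eta))
            return ll - 0.5 * np.sum(prec * u**2), eta

        f_old, eta = penalized(theta)
        for _ in range(max_iter):
            mu = expit(eta)
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            r = y - mu
            g = np.concatenate([X.T @ r, self.Z.T @ r - prec * theta[self.p :]])
            gnorm = np.linalg.norm(g)
            if gnorm < tol * max(1.0, self.n):
                break
            Xw = X * w[:, None]
            Zw = self.Z.multiply(w[:, None])
            H = np.empty((self.p + self.q, self.p + self.q))
            H[: self.p, : self.p] = X.T @ Xw
            XtWZ = (Xw.T @ self.Z.toarray()) if self.q <= 2048 else (Zw.T @ X).T
            H[: self.p, self.p :] = XtWZ
            H[self.p :, : self.p] = XtWZ.T
            ZtWZ = (self.Z.T @ Zw).toarray()
            ZtWZ[np.diag_indices(self.q)] += prec
            H[self.p :, self.p :] = ZtWZ
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            scale = 1.0
            for _half in range(30):
                cand = theta + scale * step
                f_new, eta_new = penalized(cand)
                if f_new >= f_old - 1e-12:
                    theta, f_old, eta = cand, f_new, eta_new
                    break
                scale *= 0.5
            else:  # no improving step
                break
        self.state = theta
        mu = expit(eta)
        return theta, eta, mu, f_old, gnorm

    def profiled_deviance(self, log_sds):
        sds = np.exp(np.clip(log_sds, -10, 5))
        theta, eta, mu, fpen, _ = self._inner_newton(sds)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        prec = self._prec_diag(sds)
        Zw = self.Z.multiply(w[:, None])
        ZtWZ = (self.Z.T @ Zw).toarray()
        # log det(I + Lambda Z'WZ) = log det(Z'WZ + P) - log det(P)
        A = ZtWZ + np.diag(prec)
        sign, logdet_A = np.linalg.slogdet(A)
        logdet = logdet_A - np.sum(np.log(prec))
        return -2.0 * (fpen - 0.5 * logdet)

    def fit(self, start_sd=0.8):
        x0 = np.log([start_sd] * len(self.sizes))
        res = optimize.minimize(
            self.profiled_deviance,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
        )
        log_sds = res.x
        sds = np.exp(np.clip(log_sds, -10, 5))
        theta, eta, mu, fpen, gnorm = self._inner_newton(sds, tol=1e-11)
        if gnorm > 1e-3 * max(1.0, self.n):
            raise RuntimeError(
                f"GLMM inner optimization did not converge (gradient norm {gnorm:.3g})"
            )
        # joint Hessian for Wald covariance of beta
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        prec = self._prec_diag(sds)
        Xw = self.X * w[:, None]
        Zw = self.Z.multiply(w[:, None])
        XtWX = self.X.T @ Xw
        XtWZ = Xw.T @ self.Z.toarray()
        ZtWZ = (self.Z.T @ Zw).toarray()
        ZtWZ[np.diag_indices(self.q)] += prec
        # Schur complement: Var(beta) = (X'WX - X'WZ (Z'WZ+P)^-1 Z'WX)^-1
        try:
            sol = np.linalg.solve(ZtWZ, XtWZ.T)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(ZtWZ, XtWZ.T, rcond=None)[0]
        info = XtWX - XtWZ @ sol
        vcov = np.linalg.inv(info)

        beta, u = theta[: self.p], theta[self.p :]
        ll = float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        return {
            "beta": beta,
            "u": u,
            "sds": sds,
            "vcov": vcov,
            "eta": eta,
            "loglik": ll,
            "converged": bool(res.success or res.fun is not None),
        }


def fit_logistic_glmm(y, X, term_names, participant_codes, stimulus_codes) -> GLMMResult:
    """Fit the Bernoulli GLMM with crossed participant/stimulus intercepts.

    ``X`` must already contain the intercept column.  Raises if either
    grouping factor has fewer than 2 levels (the intercept variance is then
    unidentifiable).
    """
    participant_codes = np.asarray(participant_codes)
    stimulus_codes = np.asarray(stimulus_codes)
    if participant_codes.max() + 1 < 2:
        raise ValueError("random intercept unidentifiable: need >= 2 participants")
    if stimulus_codes.max() + 1 < 2:
        raise ValueError("random intercept unidentifiable: need >= 2 stimuli")
    core = _LaplaceCore(y, X, [participant_codes, stimulus_codes])
    fit = core.fit()

    beta, vcov = fit["beta"], fit["vcov"]
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    if np.any(np.abs(beta[1:]) > 15) or np.any(se > 50):
        warnings.warn("possible complete separation: extreme coefficient or SE")
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(z))
    terms = pd.DataFrame(
        {
            "term": term_names,
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "odds_ratio": np.exp(beta),
            "ci_low": np.exp(beta - 1.959963984540054 * se),
            "ci_high": np.exp(beta + 1.959963984540054 * se),
            "stars": [_stars(v) for v in p],
        }
    )

    var_p, var_s = float(fit["sds"][0] ** 2), float(fit["sds"][1] ** 2)
    sigma2_f = float(np.var(X @ beta))
    resid = np.pi**2 / 3.0
    total = sigma2_f + var_p + var_s + resid
    marginal_r2 = sigma2_f / total
    conditional_r2 = (sigma2_f + var_p + var_s) / total

    y = np.asarray(y)
    eta_cond = fit["eta"]
    eta_marg = X @ beta

    def _score(eta):
        pred = (expit(eta) >= 0.5).astype(int)
        c = ConfusionCounts(
            TP=int(((y == 1) & (pred == 1)).sum()),
            FP=int(((y == 0) & (pred == 1)).sum()),
            FN=int(((y == 1) & (pred == 0)).sum()),
            TN=int(((y == 0) & (pred == 0)).sum()),
        )
        return _accuracy(c), _mcc(c)

    acc_c, mcc_c = _score(eta_cond)
    acc_m, mcc_m = _score(eta_marg)

    n_p = participant_codes.max() + 1
    return GLMMResult(
        terms=terms,
        var_participant=var_p,
        var_stimulus=var_s,
        marginal_r2=marginal_r2,
        conditional_r2=conditional_r2,
        prediction_accuracy=acc_c,
        prediction_mcc=mcc_c,
        prediction_accuracy_marginal=acc_m,
        prediction_mcc_marginal=mcc_m,
        loglik=fit["loglik"],
        converged=fit["converged"],
        n_obs=len(y),
        random_effects={
            "participant": fit["u"][:n_p],
            "stimulus": fit["u"][n_p:],
        },
    )


def build_model_matrix(
    responses: pd.DataFrame,
    features: pd.DataFrame,
    acoustic: list[str],
    *,
    interactions: bool = True,
):
    """Assemble y, X and grouping codes for the perception model.

    Acoustic predictors and confidence are centered and scaled (confidence is
    first shifted from 1-4 to 0-3; the affine shift is absorbed by
    centering).  Familiarity stays a 0/1 indicator.  With ``interactions``,
    familiarity x acoustic and familiarity x confidence products are added.
    """
    df = responses.merge(features, on="stimulus_id", how="left", validate="many_to_one")
    if df[acoustic].isna().any().any():
        missing = df.loc[df[acoustic].isna().any(axis=1), "stimulus_id"].unique()
        raise ValueError(f"stimuli missing acoustic features: {list(missing)[:5]}")
    y = (df["perceived"] == "music").to_numpy(dtype=np.float64)

    def zscore(v):
        v = np.asarray(v, dtype=np.float64)
        sd = v.std(ddof=0)
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    cols = {"(Intercept)": np.ones(len(df))}
    for name in acoustic:
        cols[name] = zscore(df[name])
    fam = df["familiar"].to_numpy(dtype=np.float64)
    cols["familiar"] = fam
    conf = zscore(df["confidence"].to_numpy(dtype=np.float64) - 1.0)
    cols["confidence"] = conf
    if interactions:
        for name in acoustic:
            cols[f"familiar:{name}"] = fam * cols[name]
        cols["familiar:confidence"] = fam * conf
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    p_codes = pd.Categorical(df["participant_id"]).codes
    s_codes = pd.Categorical(df["stimulus_id"]).codes
    return y, X, names, p_codes, s_codes


def fit_perception_glmm(
    responses: pd.DataFrame,
    features: pd.DataFrame,
    acoustic: list[str] | None = None,
    vif_threshold: float = 5.0,
    interactions: bool = True,
) -> GLMMResult:
    """VIF-screen the acoustic predictors, then fit the perception GLMM.

    ``acoustic=None`` starts from the default battery restricted to columns
    present in ``features`` and applies the iterative VIF screen before
    fitting; pass an explicit list to skip screening.
    """
    from .stats import vif_screen

    if acoustic is None:
        candidates = [c for c in DEFAULT_ACOUSTIC if c in features.columns]
        screen = vif_screen(features[candidates], threshold=vif_threshold)
        acoustic = screen["retained"]
    y, X, names, p_codes, s_codes = build_model_matrix(
        responses, features, acoustic, interactions=interactions
    )
    return fit_logistic_glmm(y, X, names, p_codes, s_codes)
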