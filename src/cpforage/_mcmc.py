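"""MCMC engine for random-intercept mixed models.

One sampler per family, both targeting the exact posterior of

    gaussian:   y_i = x_i' beta + u_{g(i)} + eps_i,  eps ~ N(0, sigma^2)
    bernoulli:  logit P(y_i = 1) = x_i' beta + u_{g(i)}

with beta_j ~ N(0, s_j^2), u ~ N(0, tau^2), sigma ~ Exponential(rate), and
tau half-normal.

The gaussian sampler is collapsed: the random intercepts are integrated out
analytically (per-group covariance sigma^2 I + tau^2 J, inverted by
Sherman-Morrison), beta is drawn from its conjugate GLS full conditional,
and (log sigma, log tau) move by adaptive random-walk Metropolis on the
marginal posterior; u is then drawn exactly from its conditional for
storage.  Collapsing matters because several of the models have one
observation per bird, where a centred Gibbs sampler barely mixes over the
variance split.

The Bernoulli sampler uses the non-centred parameterisation u = tau * z
(z ~ N(0,1)) for the same reason, with component-wise adaptive Metropolis
sweeps for beta, a vectorised per-group Metropolis step for z, and a scalar
step for log tau.  Proposal scales adapt only during warmup (Robbins-Monro),
keeping the post-warmup chains valid MCMC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

__all__ = ["MCMCSettings", "PriorSpec", "run_chains"]

_ACC_SCALAR = 0.44  # standard component-wise acceptance target


@dataclass(frozen=True)
class MCMCSettings:
    """Run-length configuration.

    Defaults are a 10x reduction of the headline five-chain
    60,000-iteration / 30,000-warmup protocol; they satisfy the same
    convergence gates (R-hat < 1.1, bulk ESS > 1000) at desk-scale runtimes.
    ``sweeps`` controls how many Metropolis scans of the slow components run
    per iteration (cheap, and it cuts autocorrelation roughly in proportion).
    """

    chains: int = 5
    iterations: int = 6000
    warmup: int = 3000
    seed: int = 0
    sweeps: int = 4
    store_group_effects: bool = True


@dataclass(frozen=True)
class PriorSpec:
    """Auto-scaled weakly-informative priors.

    ``beta_scale`` holds one normal sd per design column (2.5 sd(y)/sd(x) for
    gaussian responses, 2.5/sd(x) for logit; constant columns use the
    response-only scale).  ``sigma_rate`` is the exponential rate 1/sd(y) on
    the residual sd; ``tau_scale`` the half-normal scale on the
    random-intercept sd.
    """

    beta_scale: np.ndarray
    sigma_rate: float  # 0 for bernoulli (no residual sd)
    tau_scale: float

    @classmethod
    def auto(cls, X: np.ndarray, y: np.ndarray, family: str) -> "PriorSpec":
        sx = X.std(axis=0)
        safe = np.where(sx > 0, sx, 1.0)
        if family == "gaussian":
            sy = float(y.std())
            sy = sy if sy > 0 else 1.0
            scale = np.where(sx > 0, 2.5 * sy / safe, 2.5 * sy)
            return cls(beta_scale=scale, sigma_rate=1.0 / sy, tau_scale=2.5 * sy)
        scale = np.where(sx > 0, 2.5 / safe, 2.5)
        return cls(beta_scale=scale, sigma_rate=0.0, tau_scale=2.5)


def run_chains(family, X, y, gidx, n_groups, priors, settings) -> dict:
    """Sample all chains; returns arrays shaped (chains, kept_draws, ...)."""
    if settings.chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    if settings.warmup >= settings.iterations:
        raise ValueError("warmup must be smaller than iterations")
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"too few observations ({n}) for {p} fixed effects")
    kept = settings.iterations - settings.warmup
    out = {
        "beta": np.empty((settings.chains, kept, p)),
        "tau": np.empty((settings.chains, kept)),
    }
    if family == "gaussian":
        out["sigma"] = np.empty((settings.chains, kept))
    if settings.store_group_effects:
        out["u"] = np.empty((settings.chains, kept, n_groups))
    ss = np.random.SeedSequence(settings.seed)
    for c, child in enumerate(ss.spawn(settings.chains)):
        rng = np.random.default_rng(child)
        if family == "gaussian":
            _gaussian_chain(X, y, gidx, n_groups, priors, settings, rng, out, c)
        elif family == "bernoulli":
            _bernoulli_chain(X, y, gidx, n_groups, priors, settings, rng, out, c)
        else:
            raise ValueError(f"unknown family {family!r}")
    return out


def _rm_adapt(log_scale, accepted, it, target=_ACC_SCALAR):
    """Robbins-Monro step on a log proposal scale during warmup."""
    return log_scale + ((1.0 if accepted else 0.0) - target) / np.sqrt(it + 1.0)


def _gaussian_chain(X, y, gidx, q, priors, st, rng, out, c):
    n, p = X.shape
    counts = np.bincount(gidx, minlength=q).astype(float)
    XtX = X.T @ X
    Xty = X.T @ y
    # per-group column sums of X: S[g] = sum_i in g x_i  (q x p, fixed)
    S = np.zeros((q, p))
    np.add.at(S, gidx, X)
    gy = np.bincount(gidx, weights=y, minlength=q)
    # within/between decomposition of V^-1 = (I - P)/sigma^2 + P/(sigma^2 +
    # n_g tau^2) with P the group-mean projector: every term stays PSD, so
    # nothing cancels even when sigma -> 0 with one observation per group
    Sn = S / np.sqrt(counts)[:, None]
    W = XtX - Sn.T @ Sn  # within-group Gram matrix (fixed)
    cy = Xty - S.T @ (gy / counts)  # within-group cross-products (fixed)
    prior_prec = 1.0 / priors.beta_scale**2

    def marginal_loglik(sigma, tau, wss, gr):
        s2, t2 = sigma**2, tau**2
        denom = s2 + counts * t2
        quad = wss / s2 + np.sum(gr**2 / (counts * denom))
        logdet = np.sum((counts - 1.0) * np.log(s2) + np.log(denom))
        return -0.5 * (logdet + quad)

    def log_prior(sigma, tau):
        # exponential on sigma, half-normal on tau, Jacobians for log params
        return (
            -priors.sigma_rate * sigma
            + np.log(sigma)
            - tau**2 / (2 * priors.tau_scale**2)
            + np.log(tau)
        )

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma = max(float(resid.std()), 1e-4)
    tau = max(0.5 * sigma, 1e-4)
    ls_sig, ls_tau = np.log(0.2), np.log(0.4)

    kept = 0
    for it in range(st.iterations):
        s2, t2 = sigma**2, tau**2
        denom = counts * (s2 + counts * t2)
        # --- beta | sigma, tau (u collapsed): GLS conjugate normal
        A = W / s2 + S.T @ (S / denom[:, None]) + np.diag(prior_prec)
        b = cy / s2 + S.T @ (gy / denom)
        chol = cho_factor(A, lower=True)
        mean = cho_solve(chol, b)
        beta = mean + solve_triangular(chol[0].T, rng.standard_normal(p), lower=False)
        # --- (sigma, tau): component-wise MH on the marginal posterior
        r = y - X @ beta
        gr = np.bincount(gidx, weights=r, minlength=q)
        wss = max(float(r @ r - np.sum(gr**2 / counts)), 0.0)
        cur = marginal_loglik(sigma, tau, wss, gr) + log_prior(sigma, tau)
        for _ in range(4 * st.sweeps):
            prop = sigma * np.exp(np.exp(ls_sig) * rng.standard_normal())
            new = marginal_loglik(prop, tau, wss, gr) + log_prior(prop, tau)
            acc = np.log(rng.random()) < new - cur
            if acc:
                sigma, cur = prop, new
            if it < st.warmup:
                ls_sig = _rm_adapt(ls_sig, acc, it)
            prop = tau * np.exp(np.exp(ls_tau) * rng.standard_normal())
            new = marginal_loglik(sigma, prop, wss, gr) + log_prior(sigma, prop)
            acc = np.log(rng.random()) < new - cur
            if acc:
                tau, cur = prop, new
            if it < st.warmup:
                ls_tau = _rm_adapt(ls_tau, acc, it)
        if it >= st.warmup:
            out["beta"][c, kept] = beta
            out["tau"][c, kept] = tau
            out["sigma"][c, kept] = sigma
            if "u" in out:
                # exact conditional draw of the random intercepts
                pv = 1.0 / (counts / sigma**2 + 1.0 / tau**2)
                out["u"][c, kept] = pv * gr / sigma**2 + np.sqrt(pv) * rng.standard_normal(q)
            kept += 1


def _bern_loglik(y, eta):
    return y * eta - np.logaddexp(0.0, eta)


def _slice_scalar(x0, logf, rng, w=1.0, max_steps=50):
    """Univariate slice sampler (stepping out + shrinkage)."""
    y0 = logf(x0) - rng.exponential()
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logf(lo) <= y0:
            break
        lo -= w
    for _ in range(max_steps):
        if logf(hi) <= y0:
            break
        hi += w
    for _ in range(max_steps):
        new = lo + (hi - lo) * rng.random()
        if logf(new) > y0:
            return new
        if new < x0:
            lo = new
        else:
            hi = new
    return x0


def _slice_log_tau(lt, ssu, q, scale, rng):
    """Slice sample log tau from its centred conditional given u = tau z.

    Target (in log tau): -(q-1) lt - ssu e^{-2 lt} / 2 - e^{2 lt} /
    (2 scale^2), i.e. the half-normal prior times the N(u; 0, tau^2) terms
    with the log parameterisation's Jacobian; crossing the tau <->
    intercepts ridge in one draw.
    """

    def logf(v):
        return -(q - 1.0) * v - ssu * np.exp(-2 * v) / 2.0 - np.exp(2 * v) / (2 * scale**2)

    return _slice_scalar(lt, logf, rng)


def _bernoulli_chain(X, y, gidx, q, priors, st, rng, out, c):
    n, p = X.shape
    prior_prec = 1.0 / priors.beta_scale**2
    # per-group covariate values (trip covariates are constant within a bird's
    # rows: year, colony, condition, proportion), used by the translation move
    counts = np.bincount(gidx, minlength=q).astype(float)
    Xg = np.zeros((q, p))
    np.add.at(Xg, gidx, X)
    Xg /= counts[:, None]
    group_constant = np.array(
        [np.allclose(X[:, j], Xg[gidx, j]) for j in range(p)]
    )
    beta = np.zeros(p)
    z = 0.1 * rng.standard_normal(q)  # non-centred intercepts: u = tau * z
    tau = 1.0
    eta_fix = X @ beta
    ll_obs = _bern_loglik(y, eta_fix + tau * z[gidx])
    ls_beta = np.full(p, np.log(0.5))
    ls_z = np.full(q, np.log(1.0))
    ls_shift = np.full(p, np.log(0.5))

    kept = 0
    for it in range(st.iterations):
        u = tau * z
        # --- beta: component-wise adaptive Metropolis sweeps
        for _ in range(st.sweeps):
            deltas = np.exp(ls_beta) * rng.standard_normal(p)
            logu = np.log(rng.random(p))
            base = eta_fix + u[gidx]
            cur_sum = float(ll_obs.sum())
            for j in range(p):
                ll_new = _bern_loglik(y, base + X[:, j] * deltas[j])
                dlp = (
                    float(ll_new.sum()) - cur_sum
                    - 0.5 * prior_prec[j] * ((beta[j] + deltas[j]) ** 2 - beta[j] ** 2)
                )
                acc = logu[j] < dlp
                if acc:
                    beta[j] += deltas[j]
                    eta_fix = eta_fix + X[:, j] * deltas[j]
                    base = eta_fix + u[gidx]
                    ll_obs = ll_new
                    cur_sum = float(ll_new.sum())
                if it < st.warmup:
                    ls_beta[j] = _rm_adapt(ls_beta[j], acc, it)
        for _ in range(3):
            # --- z: vectorised per-group Metropolis (standard-normal prior)
            for _ in range(2):
                z_prop = z + np.exp(ls_z) * rng.standard_normal(q)
                ll_prop = _bern_loglik(y, eta_fix + tau * z_prop[gidx])
                d_group = np.bincount(gidx, weights=ll_prop - ll_obs, minlength=q)
                d_group += -(z_prop**2 - z**2) / 2.0
                acc_z = np.log(rng.random(q)) < d_group
                z = np.where(acc_z, z_prop, z)
                ll_obs = _bern_loglik(y, eta_fix + tau * z[gidx])
                if it < st.warmup:
                    ls_z += (acc_z.astype(float) - _ACC_SCALAR) / np.sqrt(it + 1.0)
            # --- tau, non-centred move (z fixed): slice sample the
            # conditional whose likelihood sees tau through u = tau z; when
            # the data say little about the intercepts this conditional is
            # wide and the slice crosses it in one draw
            zg = z[gidx]

            def logf_nc(lt):
                t = np.exp(lt)
                return (
                    float(_bern_loglik(y, eta_fix + t * zg).sum())
                    - t**2 / (2 * priors.tau_scale**2)
                    + lt
                )

            tau = np.exp(_slice_scalar(np.log(tau), logf_nc, rng))
            ll_obs = _bern_loglik(y, eta_fix + tau * zg)
            # --- interweaving: re-draw tau in the centred parameterisation
            # (u = tau z held fixed, so the likelihood is untouched) by
            # slice sampling its exact conditional, then z = u / tau
            ssu = tau**2 * float(z @ z)
            new_ltau = _slice_log_tau(np.log(tau), ssu, q, priors.tau_scale, rng)
            z = z * np.exp(np.log(tau) - new_ltau)
            tau = np.exp(new_ltau)
        # --- translation moves: slide mass along the beta_j <-> intercepts
        # ridge without changing the likelihood (eta is left exactly as is);
        # only valid for columns constant within groups
        for _ in range(2):
            for j in range(p):
                if not group_constant[j]:
                    continue
                delta = np.exp(ls_shift[j]) * rng.standard_normal()
                z_new = z - delta * Xg[:, j] / tau
                dlp = (
                    -0.5 * prior_prec[j] * ((beta[j] + delta) ** 2 - beta[j] ** 2)
                    - 0.5 * float(z_new @ z_new - z @ z)
                )
                acc = np.log(rng.random()) < dlp
                if acc:
                    beta[j] += delta
                    eta_fix = eta_fix + X[:, j] * delta
                    z = z_new
                if it < st.warmup:
                    ls_shift[j] = _rm_adapt(ls_shift[j], acc, it)
        if it >= st.warmup:
            out["beta"][c, kept] = beta
            out["tau"][c, kept] = tau
            if "u" in out:
                out["u"][c, kept] = tau * z
            kept += 1
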