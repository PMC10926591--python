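"""Downstream statistics: Bayesian enrichment and bootstrap QQ comparisons.

Two hierarchical Bayesian models summarize how the predicted PUF functions
differ from known PKF annotations. Both are this package's own model
reconstructions (isolated behind this interface so alternatives can be
swapped):

* **Odds-ratio model** — per term t with depth d(t):
  ``k_g,t ~ Binomial(n_g, p_g,t)`` for g in {PKF, PUF};
  ``logit(p_PKF,t) = alpha_t``, ``logit(p_PUF,t) = alpha_t + beta_t``;
  ``beta_t ~ Normal(mu_{d(t)}, sigma)``, ``mu_d ~ Normal(mu0, tau)`` —
  enrichment is partially pooled across terms of the same depth. The
  reported quantity is ``OR_t = exp(beta_t)``.

* **Expected-count model** — the PKF frequency of a term is the prior,
  ``p_t ~ Beta(k_pkf + 1, n_pkf - k_pkf + 1)``, updated by the PUF
  prediction counts ``k_puf ~ Binomial(n_puf, p_t)``; the expected number
  of PUFs carrying the term is ``total_pufs * p_t``. (The posterior is
  conjugate — a closed-form Beta — which serves as an independent check.)

Posteriors are sampled by blocked adaptive random-walk Metropolis on a
non-centered parameterization, with several fully independent chains
(vectorized across chains and terms); split-R-hat and effective sample
size come from arviz. Summaries report the posterior median and the
0.1/0.9 quantiles.

Distributional PUF-vs-PKF property comparisons use bootstrap resampling of
quantile-quantile curves: the null (y = x) is "excluded" only when it falls
outside the pointwise bootstrap band at every grid quantile.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from .ontology import AnnotationStore

logger = logging.getLogger(__name__)


@dataclass
class MCMCConfig:
    n_chains: int = 8
    n_steps: int = 3000
    n_burn: int = 1000
    rhat_warn: float = 1.05


@dataclass
class QQResult:
    grid: np.ndarray  # quantile levels
    q_a: np.ndarray  # observed quantiles, first group
    q_b: np.ndarray  # observed quantiles, second group
    band_lo: np.ndarray  # pointwise band on q_a - q_b
    band_hi: np.ndarray
    verdict: str  # excluded | not_excluded | indeterminate
    median_a: float
    median_b: float


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def build_term_counts(
    predicted_store: AnnotationStore,
    known_store: AnnotationStore,
    depths: Mapping[str, int],
    min_obs: int = 4,
) -> pd.DataFrame:
    """Per-term protein-level counts in PUF predictions vs PKF annotations.

    ``n_puf`` counts PUFs with at least one prediction; ``n_pkf`` counts
    annotated PKF proteins. Terms observed fewer than *min_obs* times in
    either group are excluded ("at least", i.e. >= min_obs survives). Both
    stores must be ancestor-closed.
    """
    puf_proteins = [
        p for p in predicted_store.proteins if predicted_store.terms_of(p)
    ]
    pkf_proteins = [p for p in known_store.proteins if known_store.terms_of(p)]
    if not puf_proteins or not pkf_proteins:
        raise ValueError("both stores must contain annotated proteins")
    k_puf: dict[str, int] = {}
    for p in puf_proteins:
        for t in predicted_store.terms_of(p):
            k_puf[t] = k_puf.get(t, 0) + 1
    k_pkf: dict[str, int] = {}
    for p in pkf_proteins:
        for t in known_store.terms_of(p):
            k_pkf[t] = k_pkf.get(t, 0) + 1
    rows = []
    for term in sorted(set(k_puf) | set(k_pkf)):
        kp, kk = k_puf.get(term, 0), k_pkf.get(term, 0)
        if kp >= min_obs and kk >= min_obs:
            rows.append(
                {
                    "term_id": term,
                    "k_puf": kp,
                    "n_puf": len(puf_proteins),
                    "k_pkf": kk,
                    "n_pkf": len(pkf_proteins),
                    "depth": depths[term],
                }
            )
    return pd.DataFrame(
        rows, columns=["term_id", "k_puf", "n_puf", "k_pkf", "n_pkf", "depth"]
    )


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def _binom_loglik(k, n, logit_p):
    return k * _log_sigmoid(logit_p) + (n - k) * _log_sigmoid(-logit_p)


def _diagnostics(draws: np.ndarray) -> tuple[float, float]:
    """(rhat, ess) of a (chains, draws) array via arviz."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(az.rhat(draws[None, ...].squeeze(0)))
        ess = float(az.ess(draws[None, ...].squeeze(0)))
    return rhat, ess


def _summarize(
    table: pd.DataFrame,
    per_term_draws: np.ndarray,  # (walkers, draws, T)
    config: MCMCConfig,
    value_name: str,
) -> pd.DataFrame:
    rows = []
    for t_idx, term in enumerate(table["term_id"]):
        draws = per_term_draws[:, :, t_idx]
        flat = draws.reshape(-1)
        rhat, ess = _diagnostics(draws)
        rows.append(
            {
                "term_id": term,
                "median": float(np.median(flat)),
                "q10": float(np.quantile(flat, 0.1)),
                "q90": float(np.quantile(flat, 0.9)),
                "ess": ess,
                "rhat": rhat,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["value"] = value_name
    bad = out["rhat"] > config.rhat_warn
    out["converged"] = ~bad
    if bad.any():
        logger.warning(
            "%d/%d %s posteriors show R-hat > %.2f; results flagged",
            int(bad.sum()),
            len(out),
            value_name,
            config.rhat_warn,
        )
    return out


def fit_enrichment_model(
    counts: pd.DataFrame,
    config: MCMCConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior PUF/PKF odds ratios per term, partially pooled by depth.

    Returns a frame with ``term_id, median, q10, q90, ess, rhat, converged``
    for OR_t = exp(beta_t). Non-convergence (R-hat above the configured
    bound) is reported via the ``converged`` flag, never hidden.
    """
    if len(counts) == 0:
        raise ValueError("empty count table")
    config = config or MCMCConfig()
    k_puf = counts["k_puf"].to_numpy(float)
    n_puf = counts["n_puf"].to_numpy(float)
    k_pkf = counts["k_pkf"].to_numpy(float)
    n_pkf = counts["n_pkf"].to_numpy(float)
    depth_levels = sorted(counts["depth"].unique())
    d_idx = counts["depth"].map({d: i for i, d in enumerate(depth_levels)}).to_numpy()
    T, D = len(counts), len(depth_levels)
    C = config.n_chains
    rng = np.random.default_rng(seed)

    # Non-centered parameterization (beta_t = mu0 + tau*u_{d(t)} + sigma*z_t)
    # avoids the hierarchical funnel. Blocked Metropolis-within-Gibbs:
    # given the globals, the per-term blocks (alpha_t, z_t) are independent
    # across terms, so all term blocks are updated in parallel with
    # per-term accept/reject; the global block (u, mu0, log sigma, log tau)
    # is then updated jointly per chain. Proposal scales adapt during
    # burn-in (frozen afterwards); chains are fully independent.

    def beta_of(z, u, mu0, ls, lt):
        mu_d = mu0[:, None] + np.exp(lt)[:, None] * u
        return mu_d[:, d_idx] + np.exp(ls)[:, None] * z

    def loglik_terms(alpha, beta):
        return _binom_loglik(k_pkf, n_pkf, alpha) + _binom_loglik(
            k_puf, n_puf, alpha + beta
        )

    def logprior_global(u, mu0, ls, lt):
        lp = (-0.5 * u**2).sum(axis=1) - 0.5 * mu0**2
        # half-normal(1) on sigma, tau with log-scale Jacobian
        lp += -0.5 * np.exp(2 * ls) + ls
        lp += -0.5 * np.exp(2 * lt) + lt
        return lp

    # initialization near the empirical logits
    p_pkf = (k_pkf + 0.5) / (n_pkf + 1.0)
    alpha = np.log(p_pkf / (1 - p_pkf))[None, :] + 0.2 * rng.standard_normal((C, T))
    z = rng.standard_normal((C, T))
    u = rng.standard_normal((C, D))
    mu0 = 0.2 * rng.standard_normal(C)
    ls = np.log(0.5) + 0.2 * rng.standard_normal(C)
    lt = np.log(0.5) + 0.2 * rng.standard_normal(C)

    # per-coordinate proposal scales, seeded from the curvature of the
    # binomial likelihood; adapted during burn-in
    alpha_scale = 2.4 * np.sqrt(
        1.0 / (k_pkf + k_puf + 1.0) + 1.0 / (n_pkf + n_puf - k_pkf - k_puf + 1.0)
    )[None, :]
    z_scale = np.full((1, T), 1.0)
    glob_scale = 0.25
    cent_scale = 0.25
    adapt_every = 50
    n_keep = config.n_steps - config.n_burn
    or_draws = np.empty((C, n_keep, T))
    acc_alpha = np.zeros(T)
    acc_z = np.zeros(T)
    acc_glob = 0.0
    acc_cent = 0.0

    ll_t = loglik_terms(alpha, beta_of(z, u, mu0, ls, lt))
    for step in range(config.n_steps):
        # --- alpha_t sub-block, parallel across terms --------------------
        beta = beta_of(z, u, mu0, ls, lt)
        alpha_p = alpha + alpha_scale * rng.standard_normal((C, T))
        ll_p = loglik_terms(alpha_p, beta)
        delta = ll_p - ll_t - 0.5 * ((alpha_p / 2.0) ** 2 - (alpha / 2.0) ** 2)
        accept = np.log(rng.random((C, T))) < delta
        alpha = np.where(accept, alpha_p, alpha)
        ll_t = np.where(accept, ll_p, ll_t)
        acc_alpha += accept.mean(axis=0)

        # --- z_t sub-block, parallel across terms ------------------------
        z_p = z + z_scale * rng.standard_normal((C, T))
        ll_p = loglik_terms(alpha, beta_of(z_p, u, mu0, ls, lt))
        delta = ll_p - ll_t - 0.5 * (z_p**2 - z**2)
        accept = np.log(rng.random((C, T))) < delta
        z = np.where(accept, z_p, z)
        ll_t = np.where(accept, ll_p, ll_t)
        acc_z += accept.mean(axis=0)

        # --- global block, joint per chain ------------------------------
        u_p = u + glob_scale * rng.standard_normal((C, D))
        mu0_p = mu0 + glob_scale * rng.standard_normal(C)
        ls_p = ls + glob_scale * rng.standard_normal(C)
        lt_p = lt + glob_scale * rng.standard_normal(C)
        ll_gp = loglik_terms(alpha, beta_of(z, u_p, mu0_p, ls_p, lt_p))
        delta_g = (
            ll_gp.sum(axis=1)
            - ll_t.sum(axis=1)
            + logprior_global(u_p, mu0_p, ls_p, lt_p)
            - logprior_global(u, mu0, ls, lt)
        )
        acc_g = np.log(rng.random(C)) < delta_g
        u[acc_g] = u_p[acc_g]
        mu0[acc_g] = mu0_p[acc_g]
        ls[acc_g] = ls_p[acc_g]
        lt[acc_g] = lt_p[acc_g]
        ll_t[acc_g] = ll_gp[acc_g]
        acc_glob += acc_g.mean()

        # --- interleaved centered global update (beta held fixed) -------
        # In the centered coordinates the likelihood does not involve the
        # globals, so this move costs no likelihood evaluation and mixes
        # the hierarchy scales well when the data dominate.
        beta = beta_of(z, u, mu0, ls, lt)
        u_p = u + cent_scale * rng.standard_normal((C, D))
        mu0_p = mu0 + cent_scale * rng.standard_normal(C)
        ls_p = ls + cent_scale * rng.standard_normal(C)
        lt_p = lt + cent_scale * rng.standard_normal(C)
        mu_term = (mu0[:, None] + np.exp(lt)[:, None] * u)[:, d_idx]
        mu_term_p = (mu0_p[:, None] + np.exp(lt_p)[:, None] * u_p)[:, d_idx]
        logn = lambda b, m, s: (-0.5 * ((b - m) / s[:, None]) ** 2).sum(
            axis=1
        ) - T * np.log(s)
        delta_c = (
            logn(beta, mu_term_p, np.exp(ls_p))
            - logn(beta, mu_term, np.exp(ls))
            + logprior_global(u_p, mu0_p, ls_p, lt_p)
            - logprior_global(u, mu0, ls, lt)
        )
        acc_c = np.log(rng.random(C)) < delta_c
        u[acc_c] = u_p[acc_c]
        mu0[acc_c] = mu0_p[acc_c]
        ls[acc_c] = ls_p[acc_c]
        lt[acc_c] = lt_p[acc_c]
        # keep beta fixed: recompute z under the accepted globals
        mu_new = (mu0[:, None] + np.exp(lt)[:, None] * u)[:, d_idx]
        z = np.where(
            acc_c[:, None], (beta - mu_new) / np.exp(ls)[:, None], z
        )
        acc_cent += acc_c.mean()

        # --- scale adaptation during burn-in only -----------------------
        if step < config.n_burn and (step + 1) % adapt_every == 0:
            alpha_scale *= np.exp(
                np.clip(acc_alpha / adapt_every - 0.44, -0.5, 0.5)
            )
            z_scale *= np.exp(np.clip(acc_z / adapt_every - 0.44, -0.5, 0.5))
            glob_scale *= float(
                np.exp(np.clip(acc_glob / adapt_every - 0.3, -0.5, 0.5))
            )
            cent_scale *= float(
                np.exp(np.clip(acc_cent / adapt_every - 0.3, -0.5, 0.5))
            )
            acc_alpha[:] = 0.0
            acc_z[:] = 0.0
            acc_glob = 0.0
            acc_cent = 0.0

        if step >= config.n_burn:
            or_draws[:, step - config.n_burn, :] = np.exp(
                beta_of(z, u, mu0, ls, lt)
            )
    return _summarize(counts, or_draws, config, "odds_ratio")


def fit_expected_count_model(
    counts: pd.DataFrame,
    total_pufs: int,
    config: MCMCConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior expected number of PUFs per term under PKF-frequency priors.

    Per term the frequency prior is Beta(k_pkf+1, n_pkf-k_pkf+1) and the PUF
    prediction count is Binomial(n_puf, p_t); the reported quantity is
    ``total_pufs * p_t``. Sampled on the logit scale; the conjugate Beta
    posterior exists in closed form and is used as a cross-check in tests,
    not as the implementation here.
    """
    if len(counts) == 0:
        raise ValueError("empty count table")
    if total_pufs < counts["n_puf"].max():
        raise ValueError("total_pufs must be >= n_puf")
    config = config or MCMCConfig()
    k_puf = counts["k_puf"].to_numpy(float)
    n_puf = counts["n_puf"].to_numpy(float)
    a = counts["k_pkf"].to_numpy(float) + 1.0
    b = (counts["n_pkf"] - counts["k_pkf"]).to_numpy(float) + 1.0
    T = len(counts)

    def log_prob_terms(theta: np.ndarray) -> np.ndarray:
        """Per-(chain, term) log density on the logit scale (the posterior
        factorizes over terms)."""
        log_p = _log_sigmoid(theta)
        log_q = _log_sigmoid(-theta)
        ll = k_puf * log_p + (n_puf - k_puf) * log_q
        # Beta prior + logit Jacobian p(1-p)
        lp = (a - 1.0) * log_p + (b - 1.0) * log_q + log_p + log_q
        return ll + lp

    rng = np.random.default_rng(seed)
    alpha_post = a + k_puf
    beta_post = b + n_puf - k_puf
    p_hat = alpha_post / (alpha_post + beta_post)
    center = np.log(p_hat / (1 - p_hat))
    # component-wise random-walk Metropolis, independent chains; proposal
    # scaled to the approximate posterior sd on the logit scale
    step_sd = 2.4 * np.sqrt(1.0 / alpha_post + 1.0 / beta_post)
    n_chains = config.n_chains
    theta = center[None, :] + 0.5 * step_sd * rng.standard_normal((n_chains, T))
    lp_cur = log_prob_terms(theta)
    draws = np.empty((n_chains, config.n_steps - config.n_burn, T))
    for step in range(config.n_steps):
        prop = theta + step_sd * rng.standard_normal(theta.shape)
        lp_prop = log_prob_terms(prop)
        accept = np.log(rng.random(theta.shape)) < lp_prop - lp_cur
        theta = np.where(accept, prop, theta)
        lp_cur = np.where(accept, lp_prop, lp_cur)
        if step >= config.n_burn:
            draws[:, step - config.n_burn, :] = theta
    count_draws = total_pufs / (1.0 + np.exp(-draws))
    return _summarize(counts, count_draws, config, "expected_count")


def conjugate_expected_count(
    counts: pd.DataFrame, total_pufs: int
) -> pd.DataFrame:
    """Closed-form Beta-posterior oracle for the expected-count model:
    p_t | data ~ Beta(k_pkf + k_puf + 1, n_pkf - k_pkf + n_puf - k_puf + 1)."""
    from scipy.stats import beta as beta_dist

    a = counts["k_pkf"] + counts["k_puf"] + 1.0
    b = counts["n_pkf"] - counts["k_pkf"] + counts["n_puf"] - counts["k_puf"] + 1.0
    dist = beta_dist(a, b)
    return pd.DataFrame(
        {
            "term_id": counts["term_id"],
            "median": total_pufs * dist.median(),
            "q10": total_pufs * dist.ppf(0.1),
            "q90": total_pufs * dist.ppf(0.9),
            "mean": total_pufs * dist.mean(),
            "sd": total_pufs * dist.std(),
        }
    )


# ---------------------------------------------------------------------------
# bootstrap QQ
# ---------------------------------------------------------------------------

def bootstrap_qq(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_boot: int = 500,
    band_level: float = 0.95,
    seed: int = 0,
    n_grid: int = 99,
) -> QQResult:
    """Bootstrap quantile-quantile comparison of two samples.

    Both groups are resampled with replacement *n_boot* times; at each of
    *n_grid* equally spaced quantile levels the pointwise band at
    *band_level* is computed on the quantile difference (group a minus
    group b). Verdict "excluded" means the identity line y = x lies outside
    the band at every grid point; constant degenerate samples give
    "indeterminate".
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    grid = np.linspace(0.01, 0.99, n_grid)
    q_a = np.quantile(a, grid)
    q_b = np.quantile(b, grid)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("degenerate constant sample; QQ verdict indeterminate")
        return QQResult(
            grid, q_a, q_b, q_a - q_b, q_a - q_b, "indeterminate",
            float(np.median(a)), float(np.median(b)),
        )
    rng = np.random.default_rng(seed)
    diffs = np.empty((n_boot, n_grid))
    for i in range(n_boot):
        qa = np.quantile(rng.choice(a, size=a.size, replace=True), grid)
        qb = np.quantile(rng.choice(b, size=b.size, replace=True), grid)
        diffs[i] = qa - qb
    alpha = (1.0 - band_level) / 2.0
    band_lo = np.quantile(diffs, alpha, axis=0)
    band_hi = np.quantile(diffs, 1.0 - alpha, axis=0)
    outside = (band_lo > 0) | (band_hi < 0)
    verdict = "excluded" if bool(outside.all()) else "not_excluded"
    return QQResult(
        grid, q_a, q_b, band_lo, band_hi, verdict,
        float(np.median(a)), float(np.median(b)),
    )
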