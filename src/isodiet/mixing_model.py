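"""Bayesian isotopic mixing model.

Per consumer observation (one nest-year), estimates the proportional
contribution of K food sources to the consumer's two-isotope feather
signature.  Proportions are a softmax transform of K latent standard
normals; the trophic enrichment factor enters additively in the source
means and its variance adds to the source variances; each isotope has a
residual SD with a half-Cauchy(0, 1) prior (optionally fixed).

The likelihood for isotope j is

    x_j ~ Normal( sum_k p_k (mu_kj + mu_TEF,j),
                  sum_k p_k^2 (sd_kj^2 + sd_TEF,j^2) + sigma_j^2 )

Sampling is adaptive random-walk Metropolis, vectorized across all
(consumer, chain) walkers; the per-walker proposal scale adapts toward
a 0.2-0.4 acceptance rate during burn-in and is frozen afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from isodiet.defaults import DEFAULT_N_BURNIN, DEFAULT_N_CHAINS, DEFAULT_N_ITER
from isodiet.types import ConsumerObservation, SourceSpec, TEFSpec, ValidationError

_TARGET_ACCEPT = 0.3
_LOG_HALF_CAUCHY_NORM = math.log(2.0 / math.pi)


@dataclass(frozen=True)
class MixingModelSpec:
    """Full specification of one mixing-model run."""

    sources: tuple[SourceSpec, ...]
    tef: TEFSpec
    consumers: tuple[ConsumerObservation, ...]
    n_chains: int = DEFAULT_N_CHAINS
    n_iter: int = DEFAULT_N_ITER
    n_burnin: int = DEFAULT_N_BURNIN
    seed: int = 0
    residual_sd: tuple[float, float] | None = None  # fixed per-isotope sigma; None = sampled
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if len(self.sources) < 2:
            raise ValidationError("at least 2 sources required")
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValidationError("need n_iter > n_burnin >= 0")
        if self.n_chains < 1:
            raise ValidationError("need n_chains >= 1")
        if self.residual_sd is not None and any(s <= 0 for s in self.residual_sd):
            raise ValidationError("fixed residual SDs must be > 0")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def source_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sources)


@dataclass(frozen=True)
class DietPosterior:
    """Retained posterior draws for every consumer observation.

    proportions: (n_consumers, n_chains, n_kept, K) array of diet
    proportions; residual_sd: (n_consumers, n_chains, n_kept, 2) array of
    residual SDs per isotope (constant when fixed in the spec).
    """

    consumers: tuple[ConsumerObservation, ...]
    source_names: tuple[str, ...]
    proportions: np.ndarray
    residual_sd: np.ndarray

    def flat(self, consumer_index: int) -> np.ndarray:
        """Pooled (chains*kept, K) proportion draws for one consumer."""
        draws = self.proportions[consumer_index]
        return draws.reshape(-1, draws.shape[-1])


@dataclass(frozen=True)
class FitSummary:
    """Posterior summaries and convergence diagnostics.

    ``table`` has one row per (consumer, source) with columns
    territory_id, year, source, mean, sd, median, q2_5, q25, q75, q97_5,
    rhat, ess.  ``residual_table`` summarizes residual SDs per isotope.
    """

    table: pd.DataFrame
    residual_table: pd.DataFrame
    rhat_threshold: float = 1.1
    converged: bool = True
    max_rhat: float = field(default=float("nan"))


def _model_arrays(spec: MixingModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """(K, 2) TEF-shifted source means and (K, 2) source+TEF variances."""
    mu = np.array([[s.mu13C + spec.tef.mu13C, s.mu15N + spec.tef.mu15N] for s in spec.sources])
    var = np.array(
        [
            [s.sd13C**2 + spec.tef.sd13C**2, s.sd15N**2 + spec.tef.sd15N**2]
            for s in spec.sources
        ]
    )
    return mu, var


def _softmax(f: np.ndarray) -> np.ndarray:
    z = f - f.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _log_post_batch(
    F: np.ndarray,
    LS: np.ndarray | None,
    x: np.ndarray,
    mu_adj: np.ndarray,
    var_src: np.ndarray,
    fixed_sigma2: np.ndarray | None,
) -> np.ndarray:
    """Unnormalized log posterior for a batch of walkers.

    F: (W, K) latent source scores; LS: (W, 2) log residual SDs or None
    when sigma is fixed; x: (W, 2) observed isotope values.
    """
    p = _softmax(F)
    mean = p @ mu_adj
    var = (p**2) @ var_src
    if fixed_sigma2 is not None:
        var = var + fixed_sigma2
        lp_sigma = 0.0
    else:
        sigma2 = np.exp(2.0 * LS)
        var = var + sigma2
        # half-Cauchy(0,1) prior on sigma plus the log|d sigma / d LS| Jacobian
        lp_sigma = (_LOG_HALF_CAUCHY_NORM - np.log1p(sigma2) + LS).sum(axis=-1)
    ll = -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var).sum(axis=-1)
    lp_f = -0.5 * (F**2).sum(axis=-1)
    return lp_f + lp_sigma + ll


def log_posterior(
    f: np.ndarray,
    log_sigma: np.ndarray | None,
    obs: ConsumerObservation,
    spec: MixingModelSpec,
) -> float:
    """Log prior + log likelihood at one point (reference scalar form)."""
    f = np.atleast_2d(np.asarray(f, dtype=float))
    if spec.residual_sd is not None:
        fixed_sigma2 = np.asarray(spec.residual_sd, dtype=float) ** 2
        LS = None
    else:
        if log_sigma is None:
            raise ValidationError("log_sigma required when residual SD is sampled")
        fixed_sigma2 = None
        LS = np.atleast_2d(np.asarray(log_sigma, dtype=float))
    x = np.array([[obs.mean_delta13C, obs.mean_delta15N]])
    mu_adj, var_src = _model_arrays(spec)
    return float(_log_post_batch(f, LS, x, mu_adj, var_src, fixed_sigma2)[0])


def sample_posterior(spec: MixingModelSpec) -> DietPosterior:
    """Run the MCMC for every consumer observation in the spec.

    All (consumer, chain) walkers advance in lock-step with vectorized
    proposals from a single seeded generator, so results are exactly
    reproducible for a given spec and seed.
    """
    if not spec.consumers:
        raise ValidationError("no consumer observations")
    n_obs = len(spec.consumers)
    K = spec.n_sources
    sample_sigma = spec.residual_sd is None
    D = K + (2 if sample_sigma else 0)
    W = n_obs * spec.n_chains
    n_kept = spec.n_iter - spec.n_burnin

    mu_adj, var_src = _model_arrays(spec)
    fixed_sigma2 = (
        None if sample_sigma else np.asarray(spec.residual_sd, dtype=float) ** 2
    )
    x = np.repeat(
        np.array([[c.mean_delta13C, c.mean_delta15N] for c in spec.consumers]),
        spec.n_chains,
        axis=0,
    )

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    # Overdispersed starts so multi-chain diagnostics are meaningful.
    state = np.empty((W, D))
    state[:, :K] = rng.normal(0.0, 1.0, size=(W, K))
    if sample_sigma:
        state[:, K:] = rng.normal(0.0, 0.5, size=(W, 2))

    def lp(s: np.ndarray) -> np.ndarray:
        F = s[:, :K]
        LS = s[:, K:] if sample_sigma else None
        return _log_post_batch(F, LS, x, mu_adj, var_src, fixed_sigma2)

    cur_lp = lp(state)
    scale = np.full(W, 2.38 / math.sqrt(D))

    kept_p = np.empty((W, n_kept, K))
    kept_sig = np.empty((W, n_kept, 2))

    for t in range(spec.n_iter):
        prop = state + scale[:, None] * rng.normal(size=(W, D))
        prop_lp = lp(prop)
        accept = np.log(rng.uniform(size=W)) < prop_lp - cur_lp
        state[accept] = prop[accept]
        cur_lp[accept] = prop_lp[accept]
        if t < spec.n_burnin:
            gamma = (t + 1) ** -0.6
            scale *= np.exp(gamma * (accept.astype(float) - _TARGET_ACCEPT))
        else:
            k = t - spec.n_burnin
            kept_p[:, k, :] = _softmax(state[:, :K])
            if sample_sigma:
                kept_sig[:, k, :] = np.exp(state[:, K:])
            else:
                kept_sig[:, k, :] = np.sqrt(fixed_sigma2)

    shape = (n_obs, spec.n_chains, n_kept)
    return DietPosterior(
        consumers=tuple(spec.consumers),
        source_names=spec.source_names,
        proportions=kept_p.reshape(*shape, K),
        residual_sd=kept_sig.reshape(*shape, 2),
    )


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor R-hat for one parameter.

    ``chains`` is (n_chains, n_draws).  Identical constant chains return
    1.0 by convention.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValidationError("gelman_rubin needs a (n_chains>=2, n_draws) array")
    if chains.shape[1] < 10:
        raise ValidationError("gelman_rubin needs >= 10 draws per chain")
    if np.all(chains == chains.flat[0]):  # degenerate 0/0 guarded by convention
        return 1.0
    half = chains.shape[1] // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = split.shape
    within = split.var(axis=1, ddof=1).mean()
    between = n * split.mean(axis=1).var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else float("inf")
    var_hat = (n - 1) / n * within + between / n
    return float(math.sqrt(var_hat / within))


def effective_sample_size(chains: np.ndarray) -> float:
    """Autocorrelation-based effective sample size for one parameter.

    Sums pairwise autocorrelations (chain-averaged), truncated at the
    first negative pair (Geyer initial positive sequence).
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    demeaned = chains - chains.mean(axis=1, keepdims=True)
    var = demeaned.var(axis=1, ddof=0).mean()
    if var == 0.0:
        return float(m * n)
    max_lag = min(n - 1, 1000)
    rho_sum = 0.0
    prev_pair = None
    for lag in range(1, max_lag, 2):
        rho1 = np.mean(demeaned[:, :-lag] * demeaned[:, lag:]) / var
        rho2 = (
            np.mean(demeaned[:, : -(lag + 1)] * demeaned[:, lag + 1 :]) / var
            if lag + 1 < n
            else 0.0
        )
        pair = rho1 + rho2
        if pair < 0:
            break
        if prev_pair is not None:
            pair = min(pair, prev_pair)  # enforce monotone decrease
        rho_sum += pair
        prev_pair = pair
    return float(m * n / (1.0 + 2.0 * rho_sum))


_QUANTS = {"q2_5": 0.025, "q25": 0.25, "median": 0.5, "q75": 0.75, "q97_5": 0.975}


def summarize_posterior(post: DietPosterior, rhat_threshold: float = 1.1) -> FitSummary:
    """Per-(consumer, source) posterior summaries with convergence diagnostics."""
    if post.proportions.size == 0:
        raise ValidationError("empty posterior")
    rows = []
    resid_rows = []
    multi_chain = post.proportions.shape[1] >= 2
    for i, c in enumerate(post.consumers):
        draws = post.proportions[i]  # (chains, kept, K)
        pooled = draws.reshape(-1, draws.shape[-1])
        for k, name in enumerate(post.source_names):
            chain_draws = draws[:, :, k]
            qs = np.quantile(pooled[:, k], list(_QUANTS.values()))
            rows.append(
                {
                    "territory_id": c.territory_id,
                    "year": c.year,
                    "source": name,
                    "mean": float(pooled[:, k].mean()),
                    "sd": float(pooled[:, k].std(ddof=1)),
                    **dict(zip(_QUANTS.keys(), map(float, qs))),
                    "rhat": gelman_rubin(chain_draws) if multi_chain else float("nan"),
                    "ess": effective_sample_size(chain_draws),
                }
            )
        for j, iso in enumerate(("delta13C", "delta15N")):
            sig = post.residual_sd[i, :, :, j]
            resid_rows.append(
                {
                    "territory_id": c.territory_id,
                    "year": c.year,
                    "isotope": iso,
                    "mean": float(sig.mean()),
                    "sd": float(sig.std(ddof=1)),
                    "rhat": (
                        gelman_rubin(sig)
                        if multi_chain and sig.std() > 0
                        else float("nan")
                    ),
                }
            )
    table = pd.DataFrame(rows)
    max_rhat = float(np.nanmax(table["rhat"].to_numpy())) if multi_chain else float("nan")
    converged = (not multi_chain) or bool(max_rhat <= rhat_threshold)
    return FitSummary(
        table=table,
        residual_table=pd.DataFrame(resid_rows),
        rhat_threshold=rhat_threshold,
        converged=converged,
        max_rhat=max_rhat,
    )


def population_diet_summary(summary: FitSummary) -> pd.DataFrame:
    """Across nest-years: mean and SD of per-consumer posterior means, in percent."""
    t = summary.table
    if t.empty:
        raise ValidationError("empty fit summary")
    grouped = t.groupby("source", sort=False)["mean"]
    out = pd.DataFrame(
        {
            "mean_pct": grouped.mean() * 100.0,
            "sd_pct": grouped.std(ddof=1).fillna(0.0) * 100.0,
            "n_nest_years": grouped.size(),
        }
    )
    return out.reset_index()


def with_consumers(
    spec: MixingModelSpec, consumers: tuple[ConsumerObservation, ...]
) -> MixingModelSpec:
    """Spec with the consumer list replaced (convenience for pipelines)."""
    return replace(spec, consumers=tuple(consumers))
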