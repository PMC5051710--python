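"""Bayesian estimation of the open N-mixture model.

Priors are diffuse and uniform: p ~ U(0,1) per stratum, lambda ~ U(0, B)
per stratum, and the site initial-abundance means Lambda_i ~ U(0, 2 K_i)
(with N_{i,first} ~ Poisson(Lambda_i); a discrete-uniform prior directly
on N_first is available as a variant).  The sampler alternates

  (a) exact latent-trajectory refresh per site by forward-filtering
      backward-sampling (FFBS) on the truncated state space;
  (b) exact draws from the full conditionals: p | N,y is Beta
      (1 + sum y, 1 + sum(N - y)) per stratum, and lambda | N and
      Lambda_i | N_first are truncated Gammas;
  (c) an interleaved random-walk Metropolis refresh of the detection
      block against the *marginal* likelihood (latent states integrated
      out by the forward algorithm): all p strata move jointly on the
      logit scale while every Lambda_i is rescaled to keep expected
      counts fixed.

Step (c) exists because, with a single count per site-year, detection and
abundance form a long ridge (p down, N and Lambda up leaves expected
counts fixed); conditional updates alone diffuse slowly along it, while
the joint rescaling move travels it directly.  Growth rates need no such
refresh: their exact Gamma conditionals are insensitive to the overall
abundance scale.  Chains start overdispersed, and convergence is checked
with the Gelman-Rubin potential scale reduction factor.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from ._forward import NEG_INF, backward_sample, forward_pass
from .count_data import CountDataset, PeriodScheme, stratum_key
from .nmixture_core import TruncationConfig, _lgamma_table, _PackedSite, pack_dataset

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "sample_posterior",
    "gelman_rubin",
    "posterior_summary",
]


@dataclass(frozen=True)
class McmcConfig:
    """Sampler protocol and prior bounds.

    Defaults follow the long-run protocol of the national analyses: three
    chains of 10000 iterations, 2000 discarded as burn-in, the remainder
    thinned one-in-ten.  ``lambda_bound`` is the upper end of the uniform
    prior on growth rates; ``init_mean_bound`` caps Lambda_i (default
    2 K_i per site).  ``prior_only`` ignores every observation (prior
    recovery checks).  ``marginal_every`` sets how often the marginal
    Metropolis refresh of the detection block runs after burn-in
    (``mh_reps`` proposals per refresh); ``burnin_marginal_every`` how
    often during burn-in, where the overdispersed chains must travel to
    the typical set and step sizes adapt (they are frozen afterwards).
    """

    n_chains: int = 3
    n_iter: int = 10000
    burn_in: int = 2000
    thin: int = 10
    seed: int = 0
    lambda_bound: float = 5.0
    init_mean_bound: float | None = None
    init_prior: str = "poisson_hierarchical"  # or "discrete_uniform"
    by_region: bool = False
    prior_only: bool = False
    marginal_every: int = 5
    burnin_marginal_every: int = 2
    mh_reps: int = 2
    rw_scale_p: float = 0.3
    store_latent: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.lambda_bound <= 0:
            raise ValueError("lambda_bound must be > 0")
        if self.init_mean_bound is not None and self.init_mean_bound <= 0:
            raise ValueError("init_mean_bound must be > 0")
        if self.init_prior not in ("poisson_hierarchical", "discrete_uniform"):
            raise ValueError(f"unknown init_prior {self.init_prior!r}")
        if self.marginal_every < 1 or self.burnin_marginal_every < 1:
            raise ValueError("marginal refresh intervals must be >= 1")

    @property
    def n_keep(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Retained posterior draws, shaped (n_chains, n_draws) per parameter.

    Parameter names follow ``lambda[stratum]``, ``p[stratum]``,
    ``Lambda[site]``; ``loglik`` holds the marginal log likelihood at the
    retained states.  ``latent`` optionally stores thinned trajectories
    per site as (n_chains, n_draws, span) arrays.
    """

    draws: dict[str, np.ndarray]
    config: McmcConfig
    meta: dict = field(default_factory=dict)
    latent: dict[str, np.ndarray] | None = None

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    def array(self, name: str) -> np.ndarray:
        return self.draws[name]

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def select(self, prefix: str) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.draws.items() if k.startswith(prefix)}

    def to_dataframe(self) -> pd.DataFrame:
        """Long table: chain, draw, one column per parameter."""
        n_chains, n_draws = self.n_chains, self.n_draws
        cols = {"chain": np.repeat(np.arange(n_chains), n_draws),
                "draw": np.tile(np.arange(n_draws), n_chains)}
        for k, v in self.draws.items():
            cols[k] = v.reshape(-1)
        return pd.DataFrame(cols)

    def to_arviz(self):
        import arviz as az
        return az.from_dict(posterior={k: v for k, v in self.draws.items()
                                       if k != "loglik"})

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path, config: McmcConfig | None = None) -> "PosteriorDraws":
        df = pd.read_csv(path)
        n_chains = int(df["chain"].max()) + 1
        n_draws = int(df["draw"].max()) + 1
        draws = {}
        for col in df.columns:
            if col in ("chain", "draw"):
                continue
            draws[col] = df[col].to_numpy().reshape(n_chains, n_draws)
        return cls(draws=draws, config=config or McmcConfig(n_iter=n_draws, burn_in=0,
                                                            thin=1), meta={})


# ---------------------------------------------------------------------------
# building blocks (exposed for conjugacy unit checks)
# ---------------------------------------------------------------------------


def beta_update_p(y_sum: float, deficit_sum: float, rng: np.random.Generator) -> float:
    """Draw p from its Beta(1 + sum y, 1 + sum(N - y)) full conditional."""
    return float(rng.beta(1.0 + y_sum, 1.0 + deficit_sum))


def truncated_gamma(shape: float, rate: float, bound: float,
                    rng: np.random.Generator) -> float:
    """Draw from Gamma(shape, rate) truncated to (0, bound] by inverse CDF."""
    if rate <= 0.0:
        return float(rng.uniform(0.0, bound))
    hi = float(special.gammainc(shape, rate * bound))
    if hi <= 0.0:
        return float(bound)
    x = float(special.gammaincinv(shape, rng.uniform(0.0, hi))) / rate
    return min(max(x, 1e-12), bound)


def _truncated_gamma_vec(shapes: np.ndarray, rate: float, bounds: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Vectorised truncated-Gamma draws (shared rate, per-element bounds)."""
    hi = special.gammainc(shapes, rate * bounds)
    u = rng.random(shapes.shape[0]) * hi
    x = special.gammaincinv(shapes, u) / rate
    return np.clip(x, 1e-12, bounds)


def gamma_update_lambda(n_to_sum: float, n_from_sum: float, bound: float,
                        rng: np.random.Generator) -> float:
    """Draw lambda from its truncated Gamma(1 + sum N_t, sum N_{t-1}) full
    conditional under a U(0, bound) prior."""
    return truncated_gamma(1.0 + n_to_sum, n_from_sum, bound, rng)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class _SiteState:
    """Mutable per-site buffers for one chain."""

    __slots__ = ("packed", "alpha", "lo", "hi", "N", "lam_init", "init_bound")

    def __init__(self, packed: _PackedSite, init_bound: float):
        self.packed = packed
        self.alpha = np.zeros((packed.S, packed.K + 1))
        self.lo = np.zeros(packed.S, dtype=np.int64)
        self.hi = np.zeros(packed.S, dtype=np.int64)
        self.N = np.zeros(packed.S, dtype=np.int64)
        self.lam_init = 1.0
        self.init_bound = init_bound


def _site_loglik_fast(st: _SiteState, lam_values: np.ndarray, p_values: np.ndarray,
                      init_uniform: bool, lgam: np.ndarray,
                      lam_init: float | None = None) -> float:
    pk = st.packed
    dummy = np.zeros((1, 1))
    idum = np.zeros(1, dtype=np.int64)
    return float(forward_pass(pk.obs, pk.y, lam_values[pk.lam_idx],
                              p_values[pk.p_idx], pk.K,
                              st.lam_init if lam_init is None else lam_init,
                              init_uniform, lgam, pk.fold, False,
                              dummy, idum, idum))


def _ffbs(st: _SiteState, lam_values: np.ndarray, p_values: np.ndarray,
          init_uniform: bool, lgam: np.ndarray, rng: np.random.Generator) -> int:
    """Refresh the site's latent trajectory; returns bound-hit count."""
    pk = st.packed
    ll = forward_pass(pk.obs, pk.y, lam_values[pk.lam_idx], p_values[pk.p_idx],
                      pk.K, st.lam_init, init_uniform, lgam, pk.fold, True,
                      st.alpha, st.lo, st.hi)
    if ll <= NEG_INF / 2:
        # numerically impossible state (e.g. far-off Lambda early in a chain):
        # keep the previous trajectory and let the parameter updates recover
        return -1
    u = rng.random(pk.S)
    return int(backward_sample(lam_values[pk.lam_idx], pk.K, lgam, pk.fold,
                               st.alpha, st.lo, st.hi, u, st.N))


def _run_chain(sites: list[_SiteState], lam_keys: list[str], p_keys: list[str],
               config: McmcConfig, chain_index: int,
               rng: np.random.Generator, lgam: np.ndarray):
    n_lam, n_p = len(lam_keys), len(p_keys)
    init_uniform = config.init_prior == "discrete_uniform"
    prior_only = config.prior_only

    # overdispersed starts
    lam0 = (0.5, 1.0, 1.5)[chain_index % 3]
    p0 = (0.2, 0.5, 0.8)[chain_index % 3]
    lam_values = np.full(n_lam, min(lam0, config.lambda_bound * 0.9))
    p_values = np.full(n_p, p0)
    for st in sites:
        st.lam_init = min(max(st.packed.max_count / p0, 1.0), st.init_bound)
        st.N[:] = np.maximum(st.packed.y, 1)

    step_p = np.full(n_p, config.rw_scale_p)

    # stratum of each site's first observed year: its Lambda_i is rescaled
    # jointly with that stratum's p proposal (detection/abundance ridge move)
    first_obs_stratum = np.array(
        [int(st.packed.p_idx[np.flatnonzero(st.packed.obs)[0]])
         if st.packed.obs.any() else -1 for st in sites], dtype=np.int64)

    site_ll = np.zeros(len(sites))
    ll_fresh = False

    n_keep = config.n_keep
    out_lam = np.zeros((n_keep, n_lam))
    out_p = np.zeros((n_keep, n_p))
    out_Lam = np.zeros((n_keep, len(sites)))
    out_ll = np.zeros(n_keep)
    out_latent = ([np.zeros((n_keep, st.packed.S), dtype=np.int64) for st in sites]
                  if config.store_latent else None)

    bound_hits = 0
    ffbs_failures = 0
    mh_accept = np.zeros(2)  # accepted, proposed

    shape_buf = np.zeros(max(n_lam, 1))
    rate_buf = np.zeros(max(n_lam, 1))
    ysum_buf = np.zeros(max(n_p, 1))
    nsum_buf = np.zeros(max(n_p, 1))

    keep_slot = 0
    for it in range(config.n_iter):
        # (a) latent trajectories by FFBS
        for st in sites:
            hits = _ffbs(st, lam_values, p_values, init_uniform, lgam, rng)
            if hits < 0:
                ffbs_failures += 1
            else:
                bound_hits += hits
        ll_fresh = False

        # (b) conjugate full conditionals given the latent states
        shape_buf[:] = 0.0
        rate_buf[:] = 0.0
        ysum_buf[:] = 0.0
        nsum_buf[:] = 0.0
        for st in sites:
            pk = st.packed
            N = st.N
            if pk.S > 1:
                np.add.at(shape_buf, pk.lam_idx[1:], N[1:])
                np.add.at(rate_buf, pk.lam_idx[1:], N[:-1])
            if not prior_only:
                om = pk.obs
                np.add.at(ysum_buf, pk.p_idx[om], pk.y[om])
                np.add.at(nsum_buf, pk.p_idx[om], N[om])
        for s in range(n_lam):
            lam_values[s] = gamma_update_lambda(shape_buf[s], rate_buf[s],
                                                config.lambda_bound, rng)
        for s in range(n_p):
            p_values[s] = beta_update_p(ysum_buf[s], nsum_buf[s] - ysum_buf[s], rng)
        if not init_uniform:
            shapes = np.array([1.0 + st.N[0] for st in sites], dtype=float)
            bounds = np.array([st.init_bound for st in sites])
            lam_inits = _truncated_gamma_vec(shapes, 1.0, bounds, rng)
            for st, v in zip(sites, lam_inits):
                st.lam_init = float(v)

        # (c) marginal Metropolis refresh of the detection block.
        # All p strata are proposed jointly on the logit scale with every
        # Lambda_i rescaled by its stratum's p ratio, so expected counts
        # stay fixed: the move travels along the detection/abundance ridge
        # that conditional updates cross only slowly.  The latent states
        # are integrated out by the forward pass; growth rates need no
        # marginal refresh because their exact Gamma conditionals already
        # mix across the ridge.
        adapting = it < config.burn_in
        every = config.burnin_marginal_every if adapting else config.marginal_every
        if it % every == 0 and not prior_only and n_p > 0:
            if not ll_fresh:
                for i, st in enumerate(sites):
                    site_ll[i] = _site_loglik_fast(st, lam_values, p_values,
                                                   init_uniform, lgam)
                ll_fresh = True
            for _rep in range(config.mh_reps):
                cur_logit = np.log(p_values / (1.0 - p_values))
                prop = 1.0 / (1.0 + np.exp(-(cur_logit
                                             + step_p * rng.standard_normal(n_p))))
                mh_accept[1] += 1
                ok = False
                if np.all((prop > 0.0) & (prop < 1.0)):
                    c = p_values / prop  # Lambda scale factor per stratum
                    scale = np.where(first_obs_stratum >= 0,
                                     c[np.maximum(first_obs_stratum, 0)], 1.0)
                    if init_uniform:
                        scale = np.ones(len(sites))
                    trial_init = np.array([st.lam_init for st in sites]) * scale
                    bounds_ok = all(trial_init[i] <= sites[i].init_bound
                                    for i in range(len(sites)))
                    if bounds_ok:
                        delta = 0.0
                        new_ll = np.empty(len(sites))
                        for i, st in enumerate(sites):
                            nl = _site_loglik_fast(
                                st, lam_values, prop, init_uniform, lgam,
                                lam_init=None if init_uniform else float(trial_init[i]))
                            new_ll[i] = nl
                            delta += nl - site_ll[i]
                        # logit-walk and deterministic log-scale Lambda shift:
                        # Jacobian terms for the uniform priors on p and Lambda
                        logr = (delta
                                + float(np.sum(np.log(prop * (1 - prop))
                                               - np.log(p_values * (1 - p_values))))
                                + (0.0 if init_uniform else
                                   float(np.sum(np.log(scale)))))
                        if math.log(rng.random()) < logr:
                            p_values = prop
                            if not init_uniform:
                                for i, st in enumerate(sites):
                                    st.lam_init = float(trial_init[i])
                            site_ll[:] = new_ll
                            ok = True
                            mh_accept[0] += 1
                if adapting:
                    step_p *= 1.12 if ok else 0.96
                    np.clip(step_p, 1e-3, 3.0, out=step_p)

        # (d) record
        if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
            out_lam[keep_slot] = lam_values
            out_p[keep_slot] = p_values
            out_Lam[keep_slot] = [st.lam_init for st in sites]
            if prior_only:
                out_ll[keep_slot] = 0.0
            else:
                if not ll_fresh:
                    for i, st in enumerate(sites):
                        site_ll[i] = _site_loglik_fast(st, lam_values, p_values,
                                                       init_uniform, lgam)
                    ll_fresh = True
                out_ll[keep_slot] = site_ll.sum()
            if out_latent is not None:
                for i, st in enumerate(sites):
                    out_latent[i][keep_slot] = st.N
            keep_slot += 1

    diag = {"bound_hits": bound_hits, "ffbs_failures": ffbs_failures,
            "mh_acceptance": (float(mh_accept[0] / mh_accept[1])
                              if mh_accept[1] else None),
            "final_steps_p": step_p.tolist()}
    return out_lam, out_p, out_Lam, out_ll, out_latent, diag


def _dataset_hash(ds: CountDataset) -> str:
    h = hashlib.sha256()
    for s in ds.series:
        h.update(repr((s.site_id, s.years, s.counts, s.region)).encode())
    return h.hexdigest()[:16]


def sample_posterior(ds: CountDataset, scheme: PeriodScheme,
                     trunc: TruncationConfig | None = None,
                     config: McmcConfig | None = None) -> PosteriorDraws:
    """Posterior sampling for a filtered, region/period-assigned dataset.

    Strata are the scheme's periods, crossed with site regions when
    ``config.by_region`` is set.  Deterministic for a fixed config and
    dataset: all randomness flows from ``config.seed``, with one
    substream per chain.
    """
    if config is None:
        config = McmcConfig()
    if trunc is None:
        trunc = TruncationConfig()
    if not ds.series:
        raise ValueError("cannot sample from an empty dataset")

    regions = sorted({s.region for s in ds.series if s.region is not None})
    if config.by_region and regions:
        lam_keys = [stratum_key(lbl, r) for r in regions for lbl in scheme.labels]
        p_keys = list(lam_keys)
    else:
        lam_keys = list(scheme.labels)
        p_keys = list(scheme.labels)

    packed = pack_dataset(ds, scheme, trunc, lam_keys, p_keys)
    if config.prior_only:
        for pk in packed:
            pk.obs = np.zeros_like(pk.obs)
    Kmax = max(pk.K for pk in packed)
    lgam = _lgamma_table(Kmax)
    # note: strata no site reaches simply sample their prior

    n_keep = config.n_keep
    if n_keep < 1:
        raise ValueError("protocol retains no draws; lower thin or burn_in")

    chain_results = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, c]))
        sites = [_SiteState(pk, config.init_mean_bound or 2.0 * pk.K)
                 for pk in packed]
        chain_results.append(_run_chain(sites, lam_keys, p_keys, config, c,
                                        rng, lgam))

    draws: dict[str, np.ndarray] = {}
    for s, key in enumerate(lam_keys):
        draws[f"lambda[{key}]"] = np.stack([r[0][:, s] for r in chain_results])
    for s, key in enumerate(p_keys):
        draws[f"p[{key}]"] = np.stack([r[1][:, s] for r in chain_results])
    if config.init_prior != "discrete_uniform":
        for i, pk in enumerate(packed):
            draws[f"Lambda[{pk.site_id}]"] = np.stack([r[2][:, i] for r in chain_results])
    draws["loglik"] = np.stack([r[3] for r in chain_results])

    latent = None
    if config.store_latent:
        latent = {pk.site_id: np.stack([r[4][i] for r in chain_results])
                  for i, pk in enumerate(packed)}

    meta = {
        "data_hash": _dataset_hash(ds),
        "lam_keys": lam_keys,
        "p_keys": p_keys,
        "site_ids": [pk.site_id for pk in packed],
        "site_K": {pk.site_id: pk.K for pk in packed},
        "chain_diagnostics": [r[5] for r in chain_results],
        "bound_hits": int(sum(r[5]["bound_hits"] for r in chain_results)),
    }
    if meta["bound_hits"]:
        meta["warning"] = (f"{meta['bound_hits']} sampled latent states hit the "
                           "truncation bound K; consider a larger safety_factor")
    return PosteriorDraws(draws=draws, config=config, meta=meta, latent=latent)


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------


def bgr_rhat(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction for one parameter.

    ``chains`` is (m, n): with W the mean within-chain variance and B/n
    the variance of the chain means, returns
    sqrt(((n-1)/n * W + B/n) / W).
    """
    x = np.asarray(chains, dtype=float)
    m, n = x.shape
    means = x.mean(axis=1)
    W = float(np.mean(x.var(axis=1, ddof=1)))
    B = n * float(np.var(means, ddof=1))
    if W <= 0.0:
        return 1.0 if B <= 0.0 else float("inf")
    var_plus = (n - 1) / n * W + B / n
    return math.sqrt(var_plus / W)


def _draws_dict(draws) -> dict[str, np.ndarray]:
    if isinstance(draws, PosteriorDraws):
        return {k: v for k, v in draws.draws.items() if k != "loglik"}
    return {k: np.asarray(v, dtype=float) for k, v in dict(draws).items()}


def gelman_rubin(draws, threshold: float = 1.1,
                 method: str = "bgr") -> pd.DataFrame:
    """Potential scale reduction factor R-hat per monitored parameter.

    ``method="bgr"`` is the classic between/within-chain variance form:
    with m chains of n draws, W the mean within-chain variance and B/n
    the variance of the chain means, R-hat = sqrt(((n-1)/n W + B/n) / W).
    ``method="rank"`` delegates to ArviZ's rank-normalised split R-hat.
    Parameters with R-hat above ``threshold`` (default 1.1) are flagged.
    """
    dd = _draws_dict(draws)
    if not dd:
        raise ValueError("no parameters to diagnose")
    first = next(iter(dd.values()))
    if first.ndim != 2 or first.shape[0] < 2:
        raise ValueError("R-hat needs >= 2 chains of draws (chains x draws)")
    if first.shape[1] < 10:
        raise ValueError("R-hat needs >= 10 retained draws per chain")

    rows = []
    if method == "rank":
        import arviz as az
        ds = az.convert_to_dataset(dd)
        result = az.rhat(ds)
        for name in dd:
            rows.append((name, float(result[name])))
    elif method == "bgr":
        for name, x in dd.items():
            rows.append((name, bgr_rhat(x)))
    else:
        raise ValueError(f"unknown method {method!r}")
    df = pd.DataFrame(rows, columns=["parameter", "rhat"]).set_index("parameter")
    df["converged"] = df["rhat"] <= threshold
    return df


def posterior_summary(draws, mass: float = 0.95, round_to: int | None = 3,
                      ess: bool = True) -> pd.DataFrame:
    """Pooled posterior mean and equal-tailed credible interval per parameter.

    The interval takes the (1-mass)/2 and (1+mass)/2 pooled percentiles
    (``mass=0`` collapses to the median).  Adds an effective-sample-size
    diagnostic and, when >= 2 chains are present, R-hat.
    """
    dd = _draws_dict(draws)
    if not dd:
        raise ValueError("no draws to summarise")
    if not 0 <= mass <= 1:
        raise ValueError("mass must be in [0, 1]")
    lo_q = 50.0 * (1.0 - mass)
    hi_q = 100.0 - lo_q

    multi_chain = next(iter(dd.values())).shape[0] >= 2
    rhat = gelman_rubin(dd)["rhat"] if (multi_chain and
                                        next(iter(dd.values())).shape[1] >= 10) else None

    ess_table = None
    if ess:
        try:
            import arviz as az
            ess_ds = az.ess(az.convert_to_dataset(dd))
            ess_table = {k: float(ess_ds[k]) for k in dd}
        except Exception:
            ess_table = None

    rows = []
    for name, x in dd.items():
        pooled = x.reshape(-1)
        if pooled.size == 0:
            raise ValueError(f"parameter {name!r} has no draws")
        mean = float(pooled.mean())
        lo, hi = np.percentile(pooled, [lo_q, hi_q])
        row = {"parameter": name, "mean": mean, "cri_lo": float(lo),
               "cri_hi": float(hi)}
        if ess_table is not None:
            row["ess"] = ess_table.get(name)
        if rhat is not None:
            row["rhat"] = float(rhat.loc[name])
        rows.append(row)
    df = pd.DataFrame(rows).set_index("parameter")
    if round_to is not None:
        for col in ("mean", "cri_lo", "cri_hi"):
            df[col] = df[col].round(round_to)
    return df
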