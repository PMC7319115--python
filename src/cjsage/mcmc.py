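"""Posterior sampling machinery and convergence diagnostics.

The models in this package have marginalized (latent-state-free) likelihoods
that are not conjugate, so sampling uses adaptive random-walk Metropolis:
a generic whole-vector sampler for arbitrary log-posteriors plus reusable
adaptive-scale helpers that the model classes combine into blocked
Metropolis-within-Gibbs scans (fixed effects | random effects | SDs).
Adaptation follows the standard diminishing-adaptation log-scale update
towards a target acceptance rate (0.44 for scalar moves, 0.234 for blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "AdaptiveScale",
    "sample_posterior",
    "gelman_rubin",
    "summarize_draws",
]


@dataclass(frozen=True)
class PriorSpec:
    """Vague-prior settings: Normal(0, coef_prior_sd^2) coefficients and
    Uniform(0, sd_upper) random-effect standard deviations (logit scale)."""

    coef_prior_sd: float = 10.0
    sd_upper: float = 5.0

    def __post_init__(self) -> None:
        if self.coef_prior_sd <= 0 or self.sd_upper <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class PosteriorDraws:
    """Labeled matrix of retained MCMC samples with chain structure."""

    draws: np.ndarray  # (n_samples, n_parameters), samples grouped by chain
    labels: list[str]
    chain_id: np.ndarray  # (n_samples,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.labels):
            raise ValueError("draws must be (n_samples, n_labels)")
        if len(self.chain_id) != self.draws.shape[0]:
            raise ValueError("chain_id length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("parameter labels must be unique")

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_id))

    def get(self, label: str) -> np.ndarray:
        return self.draws[:, self.labels.index(label)]

    def select(self, prefix: str) -> np.ndarray:
        """All columns whose label starts with ``prefix`` (in label order)."""
        idx = [i for i, l in enumerate(self.labels) if l.startswith(prefix)]
        return self.draws[:, idx]

    def by_chain(self) -> list[np.ndarray]:
        return [self.draws[self.chain_id == c] for c in np.unique(self.chain_id)]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        frames = []
        for c in np.unique(self.chain_id):
            block = self.draws[self.chain_id == c]
            it = np.arange(block.shape[0])
            for j, lab in enumerate(self.labels):
                frames.append(pd.DataFrame(
                    {"chain": c, "iteration": it, "parameter": lab, "value": block[:, j]}
                ))
        return pd.concat(frames, ignore_index=True)

    def thin_to(self, n: int, rng: np.random.Generator | None = None) -> "PosteriorDraws":
        """Uniformly thin the retained draws down to about ``n`` samples."""
        total = self.draws.shape[0]
        if n >= total:
            return self
        idx = np.linspace(0, total - 1, n).round().astype(int)
        return PosteriorDraws(self.draws[idx], list(self.labels), self.chain_id[idx],
                              dict(self.meta, thinned_to=n))


class AdaptiveScale:
    """Robbins-Monro log-scale adaptation towards a target acceptance rate."""

    def __init__(self, n: int = 1, scale: float = 0.1, target: float = 0.44):
        self.log_scale = np.full(n, np.log(scale))
        self.target = target
        self.t = 0

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accepted) -> None:
        self.t += 1
        gamma = min(0.25, 2.0 / np.sqrt(self.t))
        self.log_scale += gamma * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_scale, -12.0, 6.0, out=self.log_scale)


def sample_posterior(
    logposterior: Callable[[np.ndarray], float],
    init: np.ndarray | Callable[[np.random.Generator], np.ndarray],
    chains: int = 3,
    iterations: int = 4000,
    burnin: int = 1000,
    thinning: int = 2,
    seed: int = 0,
    labels: Sequence[str] | None = None,
    blocks: Sequence[np.ndarray] | None = None,
) -> PosteriorDraws:
    """Adaptive random-walk Metropolis sampling of an arbitrary log-posterior.

    ``init`` is either a start vector (jittered per chain) or a callable
    drawing one from a chain-specific Generator.  ``blocks`` optionally
    partitions the coordinates into groups updated one at a time (each with
    its own adapted scale); by default the whole vector moves jointly.
    Identical seeds give identical draws.
    """
    if iterations <= burnin:
        raise ValueError("iterations must exceed burnin")
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)
    all_draws, all_chain = [], []
    accept_rates = []
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        if callable(init):
            x = np.asarray(init(rng), dtype=float).copy()
        else:
            x = np.asarray(init, dtype=float) + 0.05 * rng.standard_normal(len(init))
        lp = logposterior(x)
        tries = 0
        while not np.isfinite(lp):
            tries += 1
            if tries > 100:
                raise RuntimeError("log-posterior not finite at any initialization attempt")
            if callable(init):
                x = np.asarray(init(rng), dtype=float).copy()
            else:
                x = np.asarray(init, dtype=float) + 0.05 * rng.standard_normal(len(init))
            lp = logposterior(x)
        d = len(x)
        blks = [np.arange(d)] if blocks is None else [np.asarray(b) for b in blocks]
        adapt = [AdaptiveScale(1, scale=0.5 / np.sqrt(len(b)),
                               target=0.234 if len(b) > 1 else 0.44) for b in blks]
        kept = []
        n_acc = n_prop = 0
        for it in range(iterations):
            for b, ad in zip(blks, adapt):
                prop = x.copy()
                prop[b] = x[b] + ad.scale[0] * rng.standard_normal(len(b))
                lp_prop = logposterior(prop)
                accept = np.log(rng.uniform()) < lp_prop - lp
                if accept:
                    x, lp = prop, lp_prop
                ad.update(accept)
                n_prop += 1
                n_acc += accept
            if it >= burnin and (it - burnin) % thinning == 0:
                kept.append(x.copy())
        all_draws.append(np.asarray(kept))
        all_chain.append(np.full(len(kept), c))
        accept_rates.append(n_acc / n_prop)
    draws = np.concatenate(all_draws)
    if labels is None:
        labels = [f"x{j}" for j in range(draws.shape[1])]
    return PosteriorDraws(
        draws=draws,
        labels=list(labels),
        chain_id=np.concatenate(all_chain),
        meta={"iterations": iterations, "burnin": burnin, "thinning": thinning,
              "chains": chains, "seed": seed, "acceptance_rates": accept_rates},
    )


def gelman_rubin(draws: PosteriorDraws) -> pd.Series:
    """Potential scale reduction factor R-hat per parameter.

    Classic between/within formulation: with m chains of length n, chain means
    x̄_j and variances s_j², B = n·Var(x̄_j), W = mean(s_j²), and
    R-hat = sqrt(((n-1)/n·W + B/n) / W).  A parameter with zero variance in
    every chain is degenerate and reported as 1 by convention.
    """
    chains = draws.by_chain()
    if len(chains) < 2:
        raise ValueError("gelman_rubin requires at least 2 chains")
    n = min(len(c) for c in chains)
    if n < 10:
        raise ValueError("gelman_rubin requires at least 10 samples per chain")
    x = np.stack([c[:n] for c in chains])  # (m, n, p)
    m = x.shape[0]
    chain_mean = x.mean(axis=1)  # (m, p)
    chain_var = x.var(axis=1, ddof=1)  # (m, p)
    W = chain_var.mean(axis=0)
    B = n * chain_mean.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    rhat = np.where(W == 0, 1.0, rhat)
    return pd.Series(rhat, index=draws.labels, name="rhat")


def summarize_draws(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, SD, central 95% interval and R-hat per parameter."""
    d = draws.draws
    out = pd.DataFrame(
        {
            "mean": d.mean(axis=0),
            "sd": d.std(axis=0, ddof=1),
            "q2.5": np.percentile(d, 2.5, axis=0),
            "q97.5": np.percentile(d, 97.5, axis=0),
        },
        index=draws.labels,
    )
    if draws.n_chains >= 2 and min(len(c) for c in draws.by_chain()) >= 10:
        out["rhat"] = gelman_rubin(draws)
    return out
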