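"""Trial-level Bayesian association model and its MCMC fit.

The model, for historical trials ``i = 1..N`` with biomarker totals
``B_i`` (of which ``B_Ti`` in the treatment arm) and endpoint totals
``X_i`` (of which ``X_Ti``):

    B_Ti | phi_Bi            ~ Binomial(B_i, phi_Bi)
    X_Ti | phi_Xi            ~ Binomial(X_i, phi_Xi)
    g(phi_Xi) = beta0 + beta * g(phi_Bi)

with a diffuse normal prior on the intercept, a uniform prior on the
slope, and independent Beta priors on each ``phi_Bi``.  Arm sizes do not
enter the likelihood; they are used only for validation.  Posterior draws
come from an adaptive Metropolis-within-Gibbs sampler (see ``_mcmc``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logit

from . import _mcmc
from .links import LinkSpec, inverse_link, link
from .trials import TrialSummary

__all__ = [
    "ModelSpec",
    "SamplerSettings",
    "PosteriorDraws",
    "FitError",
    "log_likelihood",
    "fit",
    "usable_trials",
]

logger = logging.getLogger(__name__)


class FitError(ValueError):
    """The trial set cannot support a model fit."""


@dataclass(frozen=True)
class ModelSpec:
    """Link choice plus prior hyperparameters.

    Defaults: ``beta0 ~ Normal(0, 1)``, ``beta ~ Uniform(-100, 100)`` and
    ``phi_Bi ~ Beta(1, 1)``; all are overridable.  The standard-normal
    intercept prior is deliberate: the intercept and slope share a long
    weakly-identified ridge when endpoint counts are sparse, and a truly
    flat intercept prior lets the posterior drift to extreme slopes that
    destroy out-of-range prediction (verified against the packaged worked
    example).  A degenerate ``beta_prior_bounds=(c, c)`` pins the slope at
    ``c``.
    """

    link: LinkSpec = field(default_factory=LinkSpec)
    beta0_prior_sd: float = 1.0
    beta_prior_bounds: tuple[float, float] = (-100.0, 100.0)
    phi_b_prior: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if isinstance(self.link, str):
            object.__setattr__(self, "link", LinkSpec(self.link))
        if self.beta0_prior_sd <= 0:
            raise ValueError("beta0_prior_sd must be positive")
        lo, hi = self.beta_prior_bounds
        if hi < lo:
            raise ValueError("beta_prior_bounds must be an interval (lo <= hi)")
        a, b = self.phi_b_prior
        if a <= 0 or b <= 0:
            raise ValueError("phi_b_prior shape parameters must be positive")


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run lengths.  Defaults give 4 x 5,000 = 20,000 kept draws."""

    n_chains: int = 4
    n_burnin: int = 10_000
    n_iter: int = 20_000
    thin: int = 4

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_burnin, self.n_iter, self.thin) < 1:
            raise ValueError("sampler settings must all be >= 1")
        if self.n_iter < self.thin:
            raise ValueError("n_iter must be at least thin")

    @property
    def n_kept_per_chain(self) -> int:
        return self.n_iter // self.thin


@dataclass
class PosteriorDraws:
    """Flattened posterior draws plus sampler metadata.

    ``phi_b`` has one column per trial, in the order of ``trial_ids``.
    """

    beta0: np.ndarray
    beta: np.ndarray
    phi_b: np.ndarray
    trial_ids: tuple[str, ...]
    n_chains: int
    n_burnin: int
    n_kept: int
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = self.n_kept * self.n_chains
        if not (len(self.beta0) == len(self.beta) == self.phi_b.shape[0] == total):
            raise ValueError("draw vectors must all have n_kept * n_chains rows")
        if self.phi_b.size and not (
            (self.phi_b > 0.0).all() and (self.phi_b < 1.0).all()
        ):
            raise ValueError("phi_b draws must lie strictly inside (0, 1)")

    @property
    def n_draws(self) -> int:
        return len(self.beta0)

    def to_frame(self) -> pd.DataFrame:
        data = {"beta0": self.beta0, "beta": self.beta}
        for j, tid in enumerate(self.trial_ids):
            data[f"phi_b[{tid}]"] = self.phi_b[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def usable_trials(trials: Sequence[TrialSummary]) -> list[TrialSummary]:
    """Return trials that can inform the association model.

    A trial needs at least one biomarker responder and one endpoint
    responder overall; zero-responder trials carry no information about
    either share parameter and are rejected at fit time.
    """
    out = []
    for t in trials:
        if not t.has_endpoint:
            raise FitError(f"trial {t.trial_id!r} has no endpoint counts")
        if t.b == 0 or t.x == 0:
            raise FitError(
                f"trial {t.trial_id!r} has zero biomarker or endpoint "
                "responders and cannot inform the association model"
            )
        out.append(t)
    return out


def _trial_arrays(trials: Sequence[TrialSummary]):
    b_t = np.array([t.b_t for t in trials], dtype=np.int64)
    b_n = np.array([t.b for t in trials], dtype=np.int64)
    x_t = np.array([t.x_t for t in trials], dtype=np.int64)
    x_n = np.array([t.x for t in trials], dtype=np.int64)
    return b_t, b_n, x_t, x_n


def log_likelihood(
    trials: Sequence[TrialSummary],
    beta: float,
    beta0: float,
    phi_b: Sequence[float],
    spec: ModelSpec | None = None,
) -> float:
    """Joint log-likelihood of the biomarker and endpoint counts.

    Includes the binomial normalising constants, so values are directly
    comparable with ``scipy.stats.binom.logpmf`` sums.  States for which
    any implied endpoint share leaves (0, 1) — possible under the odds
    link — get ``-inf``.
    """
    spec = spec or ModelSpec()
    trials = usable_trials(trials)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_b.shape != (len(trials),):
        raise ValueError("need exactly one phi_b entry per trial")
    if np.any((phi_b <= 0.0) | (phi_b >= 1.0)):
        raise ValueError("phi_b entries must lie strictly inside (0, 1)")
    b_t, b_n, x_t, x_n = _trial_arrays(trials)

    eta = beta0 + beta * link(phi_b, spec.link)
    if spec.link.name == "odds" and np.any(eta <= 0.0):
        return float("-inf")
    phi_x = inverse_link(eta, spec.link)
    phi_x = np.atleast_1d(phi_x)
    if np.any((phi_x <= 0.0) | (phi_x >= 1.0)):
        return float("-inf")

    def _binom(k, n, p):
        return (
            gammaln(n + 1)
            - gammaln(k + 1)
            - gammaln(n - k + 1)
            + k * np.log(p)
            + (n - k) * np.log1p(-p)
        )

    return float(np.sum(_binom(b_t, b_n, phi_b)) + np.sum(_binom(x_t, x_n, phi_x)))


def _initial_state(trials, spec: ModelSpec):
    """Link-scale least-squares start values from empirical shares."""
    b_t, b_n, x_t, x_n = _trial_arrays(trials)
    # continuity-corrected shares keep the transforms finite
    pb = (b_t + 0.5) / (b_n + 1.0)
    px = (x_t + 0.5) / (x_n + 1.0)
    gb = link(pb, spec.link)
    gx = link(px, spec.link)
    gb = np.atleast_1d(gb)
    gx = np.atleast_1d(gx)
    lo, hi = spec.beta_prior_bounds
    if hi <= lo or len(trials) < 2 or np.ptp(gb) < 1e-9:
        beta = 0.5 * (lo + hi)
    else:
        slope = np.polyfit(gb, gx, 1)[0]
        beta = float(np.clip(slope, lo, hi))
    intercept = float(np.mean(gx) - beta * np.mean(gb))
    z0 = logit(pb)
    return intercept, beta, z0


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction, chains shaped (m, n)."""
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    split = chains[:, : 2 * half].reshape(2 * m, half)
    means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_hat = (half - 1) / half * w + b / half
    return float(np.sqrt(var_hat / w))


def _ess(chains: np.ndarray) -> float:
    """Crude effective sample size from lag-summed autocorrelation."""
    m, n = chains.shape
    if n < 4:
        return float(m * n)
    acsum = 0.0
    for row in chains:
        x = row - row.mean()
        var = x @ x / n
        if var <= 0:
            continue
        rho_sum = 0.0
        for lag in range(1, min(n // 2, 200)):
            rho = x[:-lag] @ x[lag:] / ((n - lag) * var)
            if rho < 0.05:
                break
            rho_sum += rho
        acsum += 1.0 + 2.0 * rho_sum
    if acsum <= 0:
        return float(m * n)
    return float(m * n / (acsum / m))


def fit(
    trials: Sequence[TrialSummary],
    spec: ModelSpec | None = None,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    compute_diagnostics: bool = True,
) -> PosteriorDraws:
    """Draw from the joint posterior of ``(beta, beta0, phi_B1..phi_BN)``.

    Deterministic given ``seed`` and ``settings``.  Non-convergence
    (split-chain scale reduction above 1.1) triggers a warning, never a
    failure.
    """
    spec = spec or ModelSpec()
    settings = settings or SamplerSettings()
    trials = usable_trials(trials)
    if len(trials) < 2:
        raise FitError(
            "need at least 2 usable trials to identify intercept and slope"
        )
    b_t, b_n, x_t, x_n = _trial_arrays(trials)
    beta0_init, beta_init, z_init = _initial_state(trials, spec)
    lo, hi = spec.beta_prior_bounds
    a_b, b_b = spec.phi_b_prior

    per_chain = []
    for c in range(settings.n_chains):
        chain_seed = (seed + 0x9E3779B1 * (c + 1)) % (2**31 - 1)
        out = _mcmc.run_chain(
            b_t,
            b_n,
            x_t,
            x_n,
            spec.link.code,
            spec.beta0_prior_sd,
            lo,
            hi,
            a_b,
            b_b,
            settings.n_burnin,
            settings.n_iter,
            settings.thin,
            chain_seed,
            beta0_init,
            beta_init,
            z_init,
        )
        per_chain.append(out)

    beta0 = np.concatenate([o[0] for o in per_chain])
    beta = np.concatenate([o[1] for o in per_chain])
    phi_b = np.vstack([o[2] for o in per_chain])

    diagnostics: dict = {}
    if compute_diagnostics:
        names = ["beta0", "beta"] + [f"phi_b[{t.trial_id}]" for t in trials]
        stacks = [
            np.stack([o[0] for o in per_chain]),
            np.stack([o[1] for o in per_chain]),
        ] + [
            np.stack([o[2][:, j] for o in per_chain]) for j in range(len(trials))
        ]
        rhat = {}
        ess = {}
        for name, chains in zip(names, stacks):
            if np.ptp(chains) < 1e-14:  # pinned parameter
                rhat[name] = 1.0
                ess[name] = float(chains.size)
            else:
                rhat[name] = _split_rhat(chains)
                ess[name] = _ess(chains)
        diagnostics = {"rhat": rhat, "ess": ess}
        worst = np.nanmax(list(rhat.values()))
        logger.info("fit: worst split-Rhat %.4f", worst)
        if worst > 1.1:
            warnings.warn(
                f"possible non-convergence: max split-Rhat {worst:.3f} > 1.1",
                RuntimeWarning,
                stacklevel=2,
            )

    return PosteriorDraws(
        beta0=beta0,
        beta=beta,
        phi_b=phi_b,
        trial_ids=tuple(t.trial_id for t in trials),
        n_chains=settings.n_chains,
        n_burnin=settings.n_burnin,
        n_kept=settings.n_kept_per_chain,
        seed=seed,
        diagnostics=diagnostics,
    )
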