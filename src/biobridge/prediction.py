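"""Posterior-predictive rate ratio and vaccine efficacy for a new trial.

Given posterior draws of the association parameters and the new trial's
biomarker counts, each draw maps the new trial's biomarker share onto the
endpoint-share scale and then to the between-arm rate ratio; the median of
the predictive draws is the point estimate and the 2.5/97.5 percentiles
give the 95% credible interval (percentiles use linear interpolation, the
numpy/type-7 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .links import inverse_link, link
from .model import ModelSpec, PosteriorDraws
from .trials import TrialSummary, phi_hat

__all__ = ["PredictionResult", "predict", "rr_from_phi"]


@dataclass(frozen=True)
class PredictionResult:
    """Predictive draws and summaries for one new trial."""

    phi_x_draws: np.ndarray
    rr_draws: np.ndarray
    rr_point: float
    rr_ci: tuple[float, float]
    ve_point: float
    ve_ci: tuple[float, float]
    propagate_biomarker_uncertainty: bool
    n_dropped: int = 0

    def summary(self) -> dict:
        return {
            "rr_point": self.rr_point,
            "rr_ci_lower": self.rr_ci[0],
            "rr_ci_upper": self.rr_ci[1],
            "ve_point": self.ve_point,
            "ve_ci_lower": self.ve_ci[0],
            "ve_ci_upper": self.ve_ci[1],
            "n_draws": int(len(self.rr_draws)),
            "n_dropped": int(self.n_dropped),
            "propagate_biomarker_uncertainty": self.propagate_biomarker_uncertainty,
        }


def rr_from_phi(phi_x: float, ratio: float = 1.0):
    """Between-arm rate ratio implied by the treatment share ``phi_x``.

    ``phi_x / (ratio * (1 - phi_x))`` for a treatment:control sample-size
    ratio ``ratio``; strictly increasing in ``phi_x``.
    """
    phi_x = np.asarray(phi_x, dtype=float)
    if np.any((phi_x <= 0.0) | (phi_x >= 1.0)):
        raise ValueError("phi_x must lie strictly inside (0, 1)")
    if ratio <= 0:
        raise ValueError("sample-size ratio must be positive")
    out = phi_x / (ratio * (1.0 - phi_x))
    return out if out.ndim else float(out)


def predict(
    post: PosteriorDraws,
    new_trial: TrialSummary | None = None,
    spec: ModelSpec | None = None,
    propagate: bool = False,
    ratio: float = 1.0,
    seed: int = 0,
    phi_bj: float | None = None,
) -> PredictionResult:
    """Predictive distribution of the new trial's endpoint rate ratio.

    The new trial's biomarker share enters the linear predictor as a given
    quantity: by default the plug-in estimate
    ``B_T / (B_T + ratio * B_C)`` from ``new_trial``, or an explicit
    ``phi_bj`` value.  With ``propagate=True`` the share is instead redrawn
    per posterior draw from its Beta posterior
    ``Beta(a + B_T, b + B - B_T)``, carrying the biomarker sampling
    uncertainty of the new trial into the prediction (sensitivity
    analysis; widens the interval).

    Odds-link draws whose inverse is undefined are dropped and counted; a
    warning is emitted when more than 1% are lost.
    """
    spec = spec or ModelSpec()
    if phi_bj is None and new_trial is None:
        raise ValueError("provide either new_trial counts or an explicit phi_bj")
    if new_trial is not None and new_trial.b_t + new_trial.b_c == 0:
        raise ValueError(
            f"new trial {new_trial.trial_id!r} has no biomarker responders"
        )
    if post.n_draws == 0:
        raise ValueError("posterior is empty")

    n = post.n_draws
    if propagate:
        if new_trial is None:
            raise ValueError("propagate=True requires new_trial counts")
        a_b, b_b = spec.phi_b_prior
        rng = np.random.default_rng(seed)
        phi_bj = rng.beta(a_b + new_trial.b_t, b_b + new_trial.b_c, size=n)
        # guard against degenerate floating-point endpoints
        phi_bj = np.clip(phi_bj, 1e-12, 1.0 - 1e-12)
    elif phi_bj is not None:
        if not 0.0 < phi_bj < 1.0:
            raise ValueError("phi_bj must lie strictly inside (0, 1)")
        phi_bj = np.full(n, float(phi_bj))
    else:
        phi_bj = np.full(n, phi_hat(new_trial.b_t, new_trial.b_c, ratio))

    eta = post.beta0 + post.beta * link(phi_bj, spec.link)
    if spec.link.name == "odds":
        valid = eta > 0.0
    else:
        valid = np.isfinite(eta)
    n_dropped = int(n - valid.sum())
    if valid.sum() == 0:
        raise ValueError("every predictive draw fell outside the link domain")
    if n_dropped > 0.01 * n:
        warnings.warn(
            f"{n_dropped}/{n} predictive draws dropped (link domain)",
            RuntimeWarning,
            stacklevel=2,
        )
    phi_x = np.asarray(inverse_link(eta[valid], spec.link))
    phi_x = np.clip(phi_x, 1e-12, 1.0 - 1e-12)
    rr = phi_x / (ratio * (1.0 - phi_x))

    rr_point = float(np.median(rr))
    lo, hi = np.percentile(rr, [2.5, 97.5])
    return PredictionResult(
        phi_x_draws=phi_x,
        rr_draws=rr,
        rr_point=rr_point,
        rr_ci=(float(lo), float(hi)),
        ve_point=1.0 - rr_point,
        ve_ci=(1.0 - float(hi), 1.0 - float(lo)),
        propagate_biomarker_uncertainty=propagate,
        n_dropped=n_dropped,
    )
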