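"""Semi-parametric decomposition of the combined PSM score distribution.

The score density of all target PSMs is modelled as the two-component
mixture f(x) = pi0*f0(x) + pi1*f1(x): f0 is the null (incorrect-match)
density, estimated directly from decoy scores by kernel density estimation;
f1 (correct matches) and pi0 are recovered by an EM-like iteration in which
each target PSM carries a correctness probability theta_i that serves as its
kernel weight when refitting f1.  The posterior error probability of a
target PSM with score x is then PEP(x) = pi0*f0(x) / f(x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .density import DensityEstimate, fit_weighted_kde, loo_pdf_at_samples
from .exceptions import InsufficientDataError

__all__ = ["CombinedMixture", "estimate_null_density", "decompose",
           "combined_pep", "pilot_theta"]

#: below this many target PSMs the combined/separate decomposition is
#: refused; small groups are exactly the regime for the transfer estimator.
MIN_TARGETS = 50

_PI1_FLOOR = 1e-12


@dataclass
class CombinedMixture:
    """A fitted two-component score mixture."""

    pi0: float
    f0: DensityEstimate
    f1: DensityEstimate | None          # None when the alternative is empty
    theta: np.ndarray                    # per-target correctness probability
    target_scores: np.ndarray = field(repr=False, default=None)
    iterations: int = 0
    converged: bool = False
    degenerate: bool = False

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0


def estimate_null_density(decoy_scores) -> DensityEstimate:
    """Kernel estimate of the null score density from decoy PSMs."""
    x = np.asarray(decoy_scores, dtype=float).ravel()
    if x.size < 2 or np.unique(x).size < 2:
        raise InsufficientDataError(
            f"need >=2 distinct decoy scores to estimate the null density "
            f"(got {x.size})", count=int(x.size), required=2)
    return fit_weighted_kde(x, weights=None)


def pilot_theta(target_scores: np.ndarray, f0: DensityEstimate) -> np.ndarray:
    """Pilot correctness probabilities from a crude density ratio.

    theta0_i = clip(1 - f0(x_i) / f_t(x_i), 0, 1) with f_t the unweighted
    KDE of all target scores: the conservative posterior under pi0 = 1.
    Starting the EM near this ratio avoids the long quasi-flat crawl that a
    flat or rank-based initialization suffers when the alternative
    component is a small fraction of the sample.
    """
    x = np.asarray(target_scores, dtype=float).ravel()
    ft = fit_weighted_kde(x)
    ratio = f0.pdf(x) / np.maximum(ft.pdf(x), 1e-300)
    return np.clip(1.0 - ratio, 0.0, 1.0)


def decompose(target_scores, f0: DensityEstimate,
              init=None, max_iter: int = 100, tol: float = 1e-4,
              min_targets: int = MIN_TARGETS) -> CombinedMixture:
    """Fit pi0 and f1 given the (decoy-derived) null density f0.

    Iterates  pi1 <- mean(theta);  f1 <- weighted KDE(targets, theta);
    theta_i <- pi1*f1(x_i) / (pi0*f0(x_i) + pi1*f1(x_i))
    until max|delta theta| < tol or ``max_iter`` sweeps.  f1 is evaluated
    leave-one-out at the sample points (see
    :func:`~transferpep.density.loo_pdf_at_samples`).

    Non-convergence returns ``converged=False`` with a warning rather than
    raising.  theta collapsing to all ~0 (or all ~1) is flagged as
    degenerate.
    """
    x = np.asarray(target_scores, dtype=float).ravel()
    if x.size < min_targets:
        raise InsufficientDataError(
            f"decompose needs >= {min_targets} target scores (got {x.size}); "
            f"use the transfer estimator for small groups",
            count=int(x.size), required=min_targets)

    if init is None:
        theta = pilot_theta(x, f0)
    else:
        theta = np.clip(np.asarray(init, dtype=float).ravel(), 0.0, 1.0)
        if theta.shape != x.shape:
            raise ValueError("init must match target_scores in length")

    f0_at = f0.pdf(x)
    f1 = None
    converged = False
    degenerate = False
    it = 0
    for it in range(1, max_iter + 1):
        pi1 = float(theta.mean())
        if pi1 < _PI1_FLOOR or pi1 > 1.0 - _PI1_FLOOR:
            degenerate = True
            converged = True
            theta = np.zeros_like(theta) if pi1 < 0.5 else np.ones_like(theta)
            f1 = None
            break
        f1 = fit_weighted_kde(x, weights=theta)
        num = pi1 * loo_pdf_at_samples(f1, x, theta)
        den = (1.0 - pi1) * f0_at + num
        theta_new = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        delta = float(np.max(np.abs(theta_new - theta)))
        theta = theta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"combined mixture EM did not converge in {max_iter} iterations",
            RuntimeWarning, stacklevel=2)

    pi1 = float(theta.mean())
    if not degenerate and (pi1 < 1e-6 or pi1 > 1 - 1e-6):
        degenerate = True
    return CombinedMixture(pi0=1.0 - pi1, f0=f0, f1=f1, theta=theta,
                           target_scores=x, iterations=it,
                           converged=converged, degenerate=degenerate)


def combined_pep(model: CombinedMixture, scores) -> np.ndarray:
    """PEP(x) = pi0*f0(x) / (pi0*f0(x) + pi1*f1(x)), clipped to [0,1].

    Where both mixture components evaluate to zero (e.g. far outside the
    observed score range) the PEP is set to 1, the conservative convention.
    """
    x = np.asarray(scores, dtype=float)
    null_mass = model.pi0 * model.f0.pdf(x)
    alt_mass = (model.pi1 * model.f1.pdf(x)) if model.f1 is not None \
        else np.zeros_like(null_mass)
    den = null_mass + alt_mass
    pep = np.where(den > 0, null_mass / np.where(den > 0, den, 1.0), 1.0)
    return np.clip(pep, 0.0, 1.0)
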