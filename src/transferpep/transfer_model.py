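"""The transfer machinery: gamma/lambda fitting and the derived group null.

gamma_G(x) = Prob(G | H0, s >= x) is the probability that an incorrect PSM
scoring at least x belongs to the group of interest.  It is observable from
decoys (the given incorrect PSMs) as the proportion of group decoys among
decoys above each threshold, and is fitted as a line a*x + b.  Because the
observed proportions at high scores fluctuate wildly (few decoys survive),
the fit excludes the extreme tail and the line is *extrapolated* there --
this extrapolation is what makes small-group estimation possible.

From the identity  pi_G0 * (1 - F_G0(x)) = pi0 * (1 - F0(x)) * gamma_G(x) / pi_G
differentiation gives the weighted group null density

    pi_G0 * f_G0(x) = [ -gamma'(x) * (1 - F0(x)) + gamma(x) * f0(x) ] * pi0 / pi_G

lambda_G(x) = Prob(G | H1, s >= x) plays the symmetric role for correct
PSMs and is estimated from target/decoy count differences.  gamma constant
iff f_G0 = f0; lambda constant iff f_G1 = f1 -- these verdicts drive the
mode dispatch of the transfer estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .density import DensityEstimate
from .exceptions import EstimationError, ModelInconsistencyError
from .psm_io import PSMTable

__all__ = ["GammaFit", "LambdaEstimate", "TransferNull",
           "fit_gamma", "estimate_lambda", "judge_equality",
           "build_transfer_null"]

DEFAULT_N_THRESHOLDS = 100
DEFAULT_MIN_TAIL = 20
DEFAULT_REL_TOL = 0.1

#: relative excess of the transfer-null integral over 1 tolerated as
#: sampling noise before declaring the gamma fit inconsistent (the integral
#: fluctuates with sd ~0.026 around its truth under the default theoretical
#: model, so only a gross excess is diagnostic of real misuse)
_MASS_EXCESS_TOL = 0.25


@dataclass
class GammaFit:
    """Linear fit gamma(x) = slope*x + intercept to the observed proportion
    of group decoys among decoys with score >= threshold."""

    slope: float
    intercept: float
    thresholds: np.ndarray
    observed_props: np.ndarray
    r_squared: float
    score_range: tuple[float, float]     # observed decoy score range
    is_constant: bool | None = None
    degenerate: bool = False             # all decoys in group -> gamma == 1

    def gamma(self, x) -> np.ndarray:
        """gamma(x), clipped to [0,1]."""
        x = np.asarray(x, dtype=float)
        return np.clip(self.slope * x + self.intercept, 0.0, 1.0)

    def gamma_derivative(self, x) -> np.ndarray:
        """d gamma/dx; zero wherever the [0,1] clip is active."""
        x = np.asarray(x, dtype=float)
        raw = self.slope * x + self.intercept
        inside = (raw > 0.0) & (raw < 1.0)
        return np.where(inside, self.slope, 0.0)

    @property
    def support_upper(self) -> float:
        """Score at which gamma reaches 0 (group null support ends)."""
        if self.slope < 0:
            return -self.intercept / self.slope
        return np.inf


@dataclass
class LambdaEstimate:
    """Threshold-wise estimate of lambda_G(x) from tail count differences.

    lambda_hat(x) = (N_Gt(x) - N_Gd(x)) / (N_t(x) - N_d(x)) with strict
    "score > x" counting; thresholds where N_t - N_d <= 0 are dropped, and
    those with a negative numerator are dropped and flagged.
    """

    thresholds: np.ndarray
    lambda_hat: np.ndarray
    counts: dict = field(repr=False, default_factory=dict)
    n_flagged: int = 0
    is_constant: bool | None = None


@dataclass
class TransferNull:
    """The weighted group null pi_G0 * f_G0(x) derived from the combined
    null and the fitted gamma line."""

    gamma_fit: GammaFit
    f0: DensityEstimate = field(repr=False)
    pi0: float = 0.0
    pi_g: float = 1.0
    pi_g0: float = 0.0                    # numeric integral of weighted_pdf
    support_upper: float = np.inf
    grid: np.ndarray = field(repr=False, default=None)
    grid_values: np.ndarray = field(repr=False, default=None)

    def weighted_pdf(self, x) -> np.ndarray:
        """pi_G0 * f_G0(x), floored at 0."""
        x = np.asarray(x, dtype=float)
        g = self.gamma_fit.gamma(x)
        dg = self.gamma_fit.gamma_derivative(x)
        val = (-dg * self.f0.sf(x) + g * self.f0.pdf(x)) * self.pi0 / self.pi_g
        return np.maximum(val, 0.0)

    def tail_from_gamma(self, x) -> np.ndarray:
        """pi_G0 * (1 - F_G0(x)) via the gamma identity (diagnostic)."""
        x = np.asarray(x, dtype=float)
        return self.pi0 * self.f0.sf(x) * self.gamma_fit.gamma(x) / self.pi_g


def _tail_counts_ge(sorted_scores: np.ndarray, x: np.ndarray) -> np.ndarray:
    """#scores >= x for each threshold (scores pre-sorted ascending)."""
    return sorted_scores.size - np.searchsorted(sorted_scores, x, side="left")


def _tail_counts_gt(sorted_scores: np.ndarray, x: np.ndarray) -> np.ndarray:
    """#scores > x for each threshold."""
    return sorted_scores.size - np.searchsorted(sorted_scores, x, side="right")


def fit_gamma(decoy_scores, decoy_in_group,
              n_thresholds: int = DEFAULT_N_THRESHOLDS,
              min_tail: int = DEFAULT_MIN_TAIL,
              rel_tol: float = DEFAULT_REL_TOL) -> GammaFit:
    """Fit the gamma line from decoy PSMs.

    Thresholds are ``n_thresholds`` equally spaced quantiles of the decoy
    scores between the minimum and the quantile above which exactly
    ``min_tail`` decoys remain; the noisy extreme tail never enters the
    ordinary-least-squares fit.
    """
    scores = np.asarray(decoy_scores, dtype=float).ravel()
    flags = np.asarray(decoy_in_group, dtype=bool).ravel()
    if scores.shape != flags.shape:
        raise ValueError("decoy scores and group flags must align")
    n_d = scores.size
    n_g = int(flags.sum())
    if n_g == 0:
        raise EstimationError(
            "no decoy PSMs in the group: gamma (and the transfer null) "
            "cannot be estimated")
    rng_lo, rng_hi = float(scores.min()), float(scores.max())
    if n_g == n_d:
        warnings.warn("all decoys belong to the group; gamma == 1 "
                      "(degenerate fit)", RuntimeWarning, stacklevel=2)
        thr = np.array([rng_lo, rng_hi])
        fit = GammaFit(slope=0.0, intercept=1.0, thresholds=thr,
                       observed_props=np.ones_like(thr), r_squared=1.0,
                       score_range=(rng_lo, rng_hi), degenerate=True)
        judge_equality(fit, rel_tol)
        return fit

    q_hi = max(1.0 - min_tail / n_d, 0.0)
    thr = np.quantile(scores, np.linspace(0.0, q_hi, n_thresholds))
    thr = np.unique(thr)   # heavy ties can duplicate quantiles

    s_sorted = np.sort(scores)
    g_sorted = np.sort(scores[flags])
    n_ge = _tail_counts_ge(s_sorted, thr)
    n_g_ge = _tail_counts_ge(g_sorted, thr)
    keep = n_ge > 0
    thr, props = thr[keep], n_g_ge[keep] / n_ge[keep]
    if thr.size < 2:
        raise EstimationError("fewer than 2 usable gamma thresholds")

    slope, intercept = np.polyfit(thr, props, 1)
    resid = props - (slope * thr + intercept)
    ss_tot = float(np.sum((props - props.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    fit = GammaFit(slope=float(slope), intercept=float(intercept),
                   thresholds=thr, observed_props=props, r_squared=r2,
                   score_range=(rng_lo, rng_hi))
    judge_equality(fit, rel_tol)
    return fit


def estimate_lambda(table: PSMTable, thresholds=None,
                    rel_tol: float = DEFAULT_REL_TOL) -> LambdaEstimate:
    """Estimate lambda_G at a grid of score thresholds (default: deciles of
    the target scores)."""
    t = np.sort(table.target_scores)
    d = np.sort(table.decoy_scores)
    gt = np.sort(table.group_target_scores)
    gd = np.sort(table.group_decoy_scores)
    if thresholds is None:
        thresholds = np.quantile(table.target_scores,
                                 np.linspace(0.1, 0.9, 9))
    thresholds = np.unique(np.asarray(thresholds, dtype=float))

    n_t = _tail_counts_gt(t, thresholds)
    n_d = _tail_counts_gt(d, thresholds)
    n_gt = _tail_counts_gt(gt, thresholds)
    n_gd = _tail_counts_gt(gd, thresholds)

    denom_ok = (n_t - n_d) > 0
    numer = n_gt - n_gd
    flagged = denom_ok & (numer < 0)
    keep = denom_ok & (numer >= 0)
    if not np.any(keep):
        raise EstimationError(
            "N_t - N_d <= 0 (or negative group excess) at every threshold: "
            "no signal to estimate lambda")
    lam = numer[keep] / (n_t[keep] - n_d[keep])
    est = LambdaEstimate(
        thresholds=thresholds[keep], lambda_hat=lam,
        counts={"n_gt": n_gt[keep], "n_gd": n_gd[keep],
                "n_t": n_t[keep], "n_d": n_d[keep]},
        n_flagged=int(flagged.sum()))
    judge_equality(est, rel_tol)
    return est


def judge_equality(fit, rel_tol: float = DEFAULT_REL_TOL) -> bool:
    """Decide whether a fitted gamma line / lambda profile is 'a constant'.

    GammaFit: constant iff |slope| * (observed score range) <= rel_tol *
    intercept (a zero slope is constant for any positive tolerance).
    LambdaEstimate: constant iff (max - min) <= rel_tol * median over the
    retained thresholds.  The verdict is stored on the object.
    """
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    if isinstance(fit, GammaFit):
        if fit.slope == 0.0:
            verdict = True
        else:
            spread = abs(fit.slope) * (fit.score_range[1] - fit.score_range[0])
            verdict = spread <= rel_tol * fit.intercept
    elif isinstance(fit, LambdaEstimate):
        lam = fit.lambda_hat
        spread = float(lam.max() - lam.min())
        med = float(np.median(lam))
        verdict = spread <= rel_tol * med if med > 0 else spread == 0.0
    else:
        raise TypeError(f"cannot judge equality for {type(fit).__name__}")
    fit.is_constant = bool(verdict)
    return fit.is_constant


def build_transfer_null(f0: DensityEstimate, pi0: float, gamma: GammaFit,
                        pi_g: float) -> TransferNull:
    """Construct the weighted group null pi_G0 * f_G0 from the combined
    null and the fitted gamma line.

    pi_G0 is recovered as the numeric integral of the weighted density.  An
    integral above 1 means the gamma fit implies more group-null mass than
    possible; excesses of a few percent are ordinary sampling noise in the
    fitted gamma line and are tolerated, while a gross excess (beyond 25%)
    raises a model-inconsistency error.
    """
    if not 0.0 < pi_g <= 1.0:
        raise EstimationError(f"pi_g must lie in (0,1], got {pi_g}")
    if not 0.0 <= pi0 <= 1.0:
        raise EstimationError(f"pi0 must lie in [0,1], got {pi0}")
    tn = TransferNull(gamma_fit=gamma, f0=f0, pi0=float(pi0),
                      pi_g=float(pi_g), support_upper=gamma.support_upper)
    grid = np.asarray(f0.grid, dtype=float)
    vals = tn.weighted_pdf(grid)
    tn.grid = grid
    tn.grid_values = vals
    # the weighted pdf is the exact derivative of -pi0*(1-F0)*gamma/pi_G
    # (also inside the gamma clip regions, where gamma' = 0), so its
    # integral telescopes; this stays exact even when f0 diverges at the
    # support boundary, where trapezoid quadrature overshoots
    tn.pi_g0 = float(max(tn.tail_from_gamma(grid[0])
                         - tn.tail_from_gamma(grid[-1]), 0.0))
    if tn.pi_g0 > 1.0 + _MASS_EXCESS_TOL:
        raise ModelInconsistencyError(
            f"transfer null integrates to {tn.pi_g0:.4f} > 1: the gamma fit "
            f"is incompatible with pi0={pi0:.3f}, pi_G={pi_g:.3f}")
    return tn
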