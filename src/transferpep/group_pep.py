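"""The three group-PEP estimators and the PEP -> integrated-FDR relation.

combined  -- fit the mixture on all PSMs and read the group PEPs off the
             combined model (fast, but wrong when the group's null or
             alternative differs from the combined one);
separate  -- fit the mixture on the group's PSMs alone (needs a group large
             enough for kernel density estimation);
transfer  -- the small-group method: derive the group null from the fitted
             gamma line (or reuse the combined null when gamma is judged
             constant), then estimate the group alternative and the null
             proportion with the weighted-kernel EM, warm-started from the
             combined PEPs.

The integrated FDR at a score threshold is the running mean of the PEPs of
all PSMs at or above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combined_mixture import (CombinedMixture, combined_pep, decompose,
                               estimate_null_density, MIN_TARGETS)
from .density import DensityEstimate, fit_weighted_kde, loo_pdf_at_samples
from .exceptions import EstimationError, InsufficientDataError
from .psm_io import PEPResult, PSMTable
from .transfer_model import (GammaFit, LambdaEstimate, TransferNull,
                             build_transfer_null, estimate_lambda, fit_gamma,
                             DEFAULT_MIN_TAIL, DEFAULT_N_THRESHOLDS,
                             DEFAULT_REL_TOL)
from scipy.stats import norm

__all__ = ["GroupModel", "estimate_group_pep_combined",
           "estimate_group_pep_separate", "estimate_group_pep_transfer",
           "fit_group_alternative", "pep_to_fdr"]

MIN_SEPARATE_TARGETS = MIN_TARGETS
MIN_SEPARATE_DECOYS = 2

#: fixed kernel bandwidth used when the group alternative must be smoothed
#: around fewer than two distinct scores (a point-mass group)
_SINGLETON_BANDWIDTH = 1.0


@dataclass
class GroupModel:
    """The fitted group mixture produced by the transfer estimator."""

    null_equal: bool                   # f_G0 == f0 verdict used
    alt_equal: bool                    # f_G1 == f1 verdict used
    transfer_null: TransferNull | None
    f_g1: DensityEstimate | None       # None when alt reused from combined
    pi_g1: float
    theta_g: np.ndarray
    iterations: int = 0
    converged: bool = False
    degenerate: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def pi_g0(self) -> float:
        """Null proportion: 1 - pi_G1 when estimated by EM, else the
        transfer-null integral (reported in diagnostics)."""
        return 1.0 - self.pi_g1


def pep_to_fdr(peps, scores) -> np.ndarray:
    """Integrated FDR: at each threshold, the mean PEP of all PSMs scoring
    at or above it.  Returned aligned with the input order; ties in score
    are broken stably by input order."""
    p = np.asarray(peps, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if p.shape != s.shape:
        raise ValueError("peps and scores must have equal length")
    if p.size == 0:
        return np.empty(0)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("peps must lie in [0,1]")
    order = np.argsort(-s, kind="stable")
    running = np.cumsum(p[order]) / np.arange(1, p.size + 1)
    out = np.empty_like(running)
    out[order] = running
    return out


def _make_result(psm_ids, scores, peps, method, diagnostics) -> PEPResult:
    ids = np.asarray(psm_ids)
    s = np.asarray(scores, dtype=float)
    p = np.clip(np.asarray(peps, dtype=float), 0.0, 1.0)
    order = np.argsort(-s, kind="stable")
    ids, s, p = ids[order], s[order], p[order]
    ifdr = np.cumsum(p) / np.arange(1, p.size + 1) if p.size else p
    df = pd.DataFrame({"psm_id": ids, "score": s, "pep": p, "ifdr": ifdr})
    return PEPResult(df=df, method=method, model_diagnostics=diagnostics)


def _fit_combined(table: PSMTable, max_iter=100, tol=1e-4) -> CombinedMixture:
    f0 = estimate_null_density(table.decoy_scores)
    return decompose(table.target_scores, f0, max_iter=max_iter, tol=tol)


def estimate_group_pep_combined(table: PSMTable, max_iter: int = 100,
                                tol: float = 1e-4) -> PEPResult:
    """Group PEPs read off the mixture fitted on *all* PSMs."""
    table.validate()
    model = _fit_combined(table, max_iter, tol)
    g_scores = table.group_target_scores
    if g_scores.size == 0:
        warnings.warn("no group target PSMs; returning an empty result",
                      RuntimeWarning, stacklevel=2)
        return PEPResult(df=pd.DataFrame(
            columns=["psm_id", "score", "pep", "ifdr"]),
            method="combined", model_diagnostics=model)
    peps = combined_pep(model, g_scores)
    return _make_result(table.group_target_ids, g_scores, peps,
                        "combined", model)


def estimate_group_pep_separate(table: PSMTable,
                                min_targets: int = MIN_SEPARATE_TARGETS,
                                min_decoys: int = MIN_SEPARATE_DECOYS,
                                max_iter: int = 100,
                                tol: float = 1e-4) -> PEPResult:
    """Group PEPs from the mixture fitted on the group's PSMs alone."""
    table.validate()
    n_gt = table.group_target_scores.size
    n_gd = table.group_decoy_scores.size
    if n_gt < min_targets or n_gd < min_decoys:
        raise InsufficientDataError(
            f"separate estimation needs >= {min_targets} group targets and "
            f">= {min_decoys} group decoys (got {n_gt} targets, {n_gd} "
            f"decoys); use the transfer estimator",
            count=n_gt, required=min_targets)
    sub = table.subset_group()
    f_g0 = estimate_null_density(sub.decoy_scores)
    model = decompose(sub.target_scores, f_g0, max_iter=max_iter, tol=tol,
                      min_targets=min_targets)
    peps = combined_pep(model, sub.target_scores)
    return _make_result(sub.df.loc[sub.is_target, "psm_id"].to_numpy(),
                        sub.target_scores, peps, "separate", model)


def _alt_pdf_values(scores: np.ndarray, theta: np.ndarray):
    """Weighted-kernel alternative density evaluated leave-one-out at the
    group scores, with a fixed-bandwidth fallback for point-mass groups."""
    mask = theta > 0
    if np.unique(scores[mask]).size >= 2:
        f_g1 = fit_weighted_kde(scores, weights=theta)
        return f_g1, loo_pdf_at_samples(f_g1, scores, theta)
    # all alternative mass sits on (numerically) one score: smooth it with
    # a fixed-width Gaussian so the EM update stays defined
    center = float(np.average(scores, weights=theta)) if mask.any() \
        else float(scores[0])
    vals = norm.pdf(scores, loc=center, scale=_SINGLETON_BANDWIDTH)
    return None, vals


def fit_group_alternative(group_target_scores, weighted_null,
                          init=None, max_iter: int = 100, tol: float = 1e-4,
                          fixed_alt=None,
                          null_is_weighted: bool = True) -> GroupModel:
    """EM-like estimation of the group alternative and null proportion.

    Parameters
    ----------
    group_target_scores
        Scores of the group's target PSMs (>= 1).
    weighted_null
        Callable ``x -> pi_G0*f_G0(x)`` (``null_is_weighted=True``, the
        transfer-null mode: the weighted null stays *fixed* while pi_G1 is
        re-estimated as mean(theta)), or ``x -> f_G0(x)`` with
        ``null_is_weighted=False`` (the equal-null mode: the null weight is
        the EM's own 1 - pi_G1).
    fixed_alt
        Callable giving a fixed alternative density (the combined f1 when
        the lambda verdict says f_G1 = f1); when set, only the mixing
        proportion is iterated -- a standard EM in its simplest form.
    init
        Initial theta (defaults to the pilot density-ratio start
        clip(1 - null/f_t, 0, 1); the transfer estimator passes
        1 - combined PEP).
    """
    x = np.asarray(group_target_scores, dtype=float).ravel()
    if x.size < 1:
        raise InsufficientDataError("need >= 1 group target PSM",
                                    count=0, required=1)
    null_at = np.maximum(np.asarray(weighted_null(x), dtype=float), 0.0)
    alt_fixed_at = None
    if fixed_alt is not None:
        alt_fixed_at = np.maximum(np.asarray(fixed_alt(x), dtype=float), 0.0)

    if init is None:
        if np.unique(x).size >= 2:
            ft = fit_weighted_kde(x)
            theta = np.clip(1.0 - null_at / np.maximum(ft.pdf(x), 1e-300),
                            0.0, 1.0)
        else:
            theta = np.full_like(x, 0.5)
    else:
        theta = np.clip(np.asarray(init, dtype=float).ravel(), 0.0, 1.0)
        if theta.shape != x.shape:
            raise ValueError("init must match group_target_scores in length")

    f_g1 = None
    converged = False
    degenerate = False
    it = 0
    for it in range(1, max_iter + 1):
        pi_g1 = float(theta.mean())
        if theta.sum() < 0.5:
            # fewer than half an effective point of alternative mass:
            # all-null group
            degenerate = True
            converged = True
            theta = np.zeros_like(theta)
            f_g1 = None
            break
        if alt_fixed_at is not None:
            alt_at = alt_fixed_at
        else:
            f_g1, alt_at = _alt_pdf_values(x, theta)
        num = pi_g1 * alt_at
        if null_is_weighted:
            den = null_at + num
        else:
            den = (1.0 - pi_g1) * null_at + num
        theta_new = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        delta = float(np.max(np.abs(theta_new - theta)))
        theta = theta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"group EM did not converge in {max_iter} iterations",
                      RuntimeWarning, stacklevel=2)

    return GroupModel(null_equal=not null_is_weighted,
                      alt_equal=alt_fixed_at is not None,
                      transfer_null=None, f_g1=f_g1,
                      pi_g1=float(theta.mean()), theta_g=theta,
                      iterations=it, converged=converged,
                      degenerate=degenerate)


def estimate_group_pep_transfer(table: PSMTable,
                                force_null: str = "auto",
                                force_alt: str = "auto",
                                n_thresholds: int = DEFAULT_N_THRESHOLDS,
                                min_tail: int = DEFAULT_MIN_TAIL,
                                rel_tol: float = DEFAULT_REL_TOL,
                                max_iter: int = 100, tol: float = 1e-4,
                                monotonize: bool = False) -> PEPResult:
    """The transfer estimator.

    Steps: fit the combined mixture; fit gamma on decoys and lambda on the
    table; judge the two equalities (or obey ``force_null`` /
    ``force_alt``); build the group null (transfer null when gamma is not
    constant, else the combined f0 with pi_G0 estimated by EM); estimate
    the group alternative (the combined f1 when lambda is constant, else a
    weighted-kernel fit); evaluate the group PEP and append the integrated
    FDR.

    ``force_null`` in {"auto", "equal", "transfer"}; ``force_alt`` in
    {"auto", "equal", "separate"} ("separate" = fit the group's own
    alternative density).
    """
    if force_null not in ("auto", "equal", "transfer"):
        raise ValueError(f"invalid force_null: {force_null!r}")
    if force_alt not in ("auto", "equal", "separate"):
        raise ValueError(f"invalid force_alt: {force_alt!r}")
    table.validate()
    g_scores = table.group_target_scores
    if g_scores.size < 1:
        raise InsufficientDataError("transfer estimation needs >= 1 group "
                                    "target PSM", count=0, required=1)

    cm = _fit_combined(table, max_iter, tol)

    gfit: GammaFit | None = None
    lam: LambdaEstimate | None = None
    n_group_decoys = int(table.group_decoy_scores.size)
    if force_null == "transfer" and n_group_decoys == 0:
        raise EstimationError(
            "force_null='transfer' requires >= 1 group decoy PSM to fit "
            "gamma, but the table has none")
    if force_null == "auto" or force_null == "transfer":
        gfit = fit_gamma(table.decoy_scores, table.decoy_in_group,
                         n_thresholds=n_thresholds, min_tail=min_tail,
                         rel_tol=rel_tol)
    if force_alt == "auto":
        lam = estimate_lambda(table, rel_tol=rel_tol)

    null_equal = (force_null == "equal") if force_null != "auto" \
        else bool(gfit.is_constant)
    alt_equal = (force_alt == "equal") if force_alt != "auto" \
        else bool(lam.is_constant)

    pi_g = float(g_scores.size) / float(table.target_scores.size)

    tn: TransferNull | None = None
    if null_equal:
        f0_at = cm.f0.pdf
        weighted_null = f0_at
        null_is_weighted = False
    else:
        tn = build_transfer_null(cm.f0, cm.pi0, gfit, pi_g)
        weighted_null = tn.weighted_pdf
        null_is_weighted = True

    if alt_equal:
        if cm.f1 is None:
            fixed_alt = lambda x: np.zeros_like(np.asarray(x, dtype=float))
        else:
            fixed_alt = cm.f1.pdf
    else:
        fixed_alt = None

    init = 1.0 - combined_pep(cm, g_scores)
    gm = fit_group_alternative(g_scores, weighted_null, init=init,
                               max_iter=max_iter, tol=tol,
                               fixed_alt=fixed_alt,
                               null_is_weighted=null_is_weighted)
    gm.transfer_null = tn

    null_at = np.maximum(np.asarray(weighted_null(g_scores), float), 0.0)
    if not null_is_weighted:
        null_at = (1.0 - gm.pi_g1) * null_at
    if gm.alt_equal:
        alt_at = np.maximum(np.asarray(fixed_alt(g_scores), float), 0.0)
    elif gm.f_g1 is not None:
        alt_at = gm.f_g1.pdf(g_scores)
    else:
        alt_at = np.zeros_like(g_scores)
    alt_at = gm.pi_g1 * alt_at
    den = null_at + alt_at
    peps = np.where(den > 0, null_at / np.where(den > 0, den, 1.0), 1.0)
    peps = np.clip(peps, 0.0, 1.0)

    gm.diagnostics = {
        "gamma_slope": gfit.slope if gfit is not None else None,
        "gamma_intercept": gfit.intercept if gfit is not None else None,
        "gamma_constant": gfit.is_constant if gfit is not None else None,
        "lambda_constant": lam.is_constant if lam is not None else None,
        "pi0": cm.pi0, "pi_g": pi_g,
        "pi_g0_transfer_integral": tn.pi_g0 if tn is not None else None,
        "pi_g1": gm.pi_g1,
        # residual tension between the fixed weighted null and the
        # EM-estimated pi_G1 (the two are deliberately not constrained)
        "mass_residual": (gm.pi_g1 + tn.pi_g0 - 1.0) if tn is not None
        else None,
        "mode": ("equal" if null_equal else "transfer",
                 "equal" if alt_equal else "separate"),
        "combined": cm,
    }

    if monotonize and peps.size:
        order = np.argsort(-g_scores, kind="stable")
        ranked = peps[order]
        ranked = np.maximum.accumulate(ranked)  # running max down the ranking
        peps = np.empty_like(ranked)
        peps[order] = ranked

    return _make_result(table.group_target_ids, g_scores, peps,
                        "transfer", gm)
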