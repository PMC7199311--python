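"""Theoretical score simulator with closed-form oracle densities.

The generative model: combined null f0 = Gamma(shape 0.96, scale 1.5) (all
scores >= 0), group membership of an incorrect PSM governed by the linear
gamma_G(x) = a*x + b (defaults a = -0.01, b = 0.4), from which the group
and complement null densities follow in closed form:

    f_G0(x) = [ -a*(1 - F0(x)) + (a*x + b)*f0(x) ] / b        on [0, -b/a]
    f_Q0(x) = [ f0(x) - b*f_G0(x) ] / (1 - b)

Correct scores come from f_G1 = Normal(9, 6) for the n group-correct PSMs
and f_Q1 = Normal(10, 6) for the rest.  The 6 is read as a *variance*
(sigma ~ 2.449) by default: with sigma = 6 roughly 7% of group-correct
scores would be negative, contradicting the nonnegative-score support of
the model; a config switch restores the sigma = 6 reading for sensitivity
checks.

Of N = 15000 scores, round(pi0*N) are null (pi0 = 0.65); among those,
N_G0 ~ Binomial(N0, b) come from f_G0 and the rest from f_Q0.  To mimic
the target-decoy strategy, N0 decoy scores are drawn the same way (the
same N_G0 from f_G0).  The theoretical group PEP

    PEP_G(x) = pi_G0*f_G0(x) / (pi_G0*f_G0(x) + pi_G1*f_G1(x)),
    pi_G0 = b*pi0/pi_G,  pi_G = b*pi0 + n/N

is the ground truth every estimator is scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Callable

import numpy as np
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from .exceptions import ValidationError
from .psm_io import PSMTable

import pandas as pd

__all__ = ["SimulationConfig", "OracleFunctions", "SimulatedDataset",
           "build_oracle", "sample_derived_null", "simulate_dataset"]

_PROBE_POINTS = 2048
_INVERSE_GRID_POINTS = 8192


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the theoretical generative model (defaults above)."""

    n_total: int = 15000
    pi0: float = 0.65
    gamma_a: float = -0.01
    gamma_b: float = 0.4
    null_shape: float = 0.96
    null_scale: float = 1.5
    group_alt_mean: float = 9.0
    group_alt_spread: float = 6.0
    other_alt_mean: float = 10.0
    other_alt_spread: float = 6.0
    n_group_correct: int = 10
    spread_is_variance: bool = True
    truncate_negative: bool = False
    seed: int = 0

    @property
    def group_alt_sigma(self) -> float:
        return np.sqrt(self.group_alt_spread) if self.spread_is_variance \
            else self.group_alt_spread

    @property
    def other_alt_sigma(self) -> float:
        return np.sqrt(self.other_alt_spread) if self.spread_is_variance \
            else self.other_alt_spread

    @property
    def n_null(self) -> int:
        return int(round(self.pi0 * self.n_total))

    @property
    def n_correct(self) -> int:
        return self.n_total - self.n_null

    def validate(self) -> None:
        if not 0.0 < self.gamma_b <= 1.0:
            raise ValidationError("gamma_b must lie in (0, 1]")
        if not 0.0 < self.pi0 < 1.0:
            raise ValidationError("pi0 must lie in (0, 1)")
        if self.null_shape <= 0 or self.null_scale <= 0:
            raise ValidationError("gamma null parameters must be positive")
        if self.n_group_correct > self.n_correct:
            raise ValidationError(
                f"n_group_correct={self.n_group_correct} exceeds the number "
                f"of correct scores N1={self.n_correct}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class OracleFunctions:
    """Closed-form densities, cdfs and the theoretical group PEP."""

    config: SimulationConfig
    f0: Callable
    F0: Callable
    f_g0: Callable
    F_g0: Callable
    f_q0: Callable
    F_q0: Callable
    f_g1: Callable
    f_q1: Callable
    pep_g: Callable
    pi_g: float
    pi_g0_true: float
    pi_g1_true: float
    support_upper: float
    _inv_cache: dict = field(default_factory=dict, repr=False)

    def weighted_null(self, x) -> np.ndarray:
        """pi_G0 * f_G0(x) -- the true transfer null."""
        return self.pi_g0_true * self.f_g0(x)


def build_oracle(config: SimulationConfig) -> OracleFunctions:
    """Wire up the closed-form oracle functions for a configuration.

    The derived densities are probed on a 2048-point grid; a configuration
    whose Eq-derived f_G0 or f_Q0 goes negative is rejected.
    """
    config.validate()
    a, b = config.gamma_a, config.gamma_b
    dist0 = gamma_dist(config.null_shape, scale=config.null_scale)
    x_star = -b / a if a < 0 else np.inf

    def f0(x):
        return dist0.pdf(np.asarray(x, dtype=float))

    def F0(x):
        return dist0.cdf(np.asarray(x, dtype=float))

    def gamma_line(x):
        return np.clip(a * np.asarray(x, dtype=float) + b, 0.0, 1.0)

    def f_g0(x):
        x = np.asarray(x, dtype=float)
        inside = (x >= 0) & (x <= x_star)
        val = (-a * dist0.sf(x) + (a * x + b) * dist0.pdf(x)) / b
        return np.where(inside, np.maximum(val, 0.0), 0.0)

    def F_g0(x):
        x = np.asarray(x, dtype=float)
        val = 1.0 - dist0.sf(x) * (a * x + b) / b
        out = np.where(x < 0, 0.0, np.where(x > x_star, 1.0, val))
        return np.clip(out, 0.0, 1.0)

    if b < 1.0:
        def f_q0(x):
            x = np.asarray(x, dtype=float)
            return np.maximum((dist0.pdf(x) - b * f_g0(x)) / (1.0 - b), 0.0)

        def F_q0(x):
            x = np.asarray(x, dtype=float)
            return np.clip((dist0.cdf(x) - b * F_g0(x)) / (1.0 - b), 0.0, 1.0)
    else:
        def f_q0(x):
            return np.zeros_like(np.asarray(x, dtype=float))

        def F_q0(x):
            return np.zeros_like(np.asarray(x, dtype=float))

    sig_g = config.group_alt_sigma
    sig_q = config.other_alt_sigma

    def f_g1(x):
        return norm.pdf(np.asarray(x, dtype=float),
                        loc=config.group_alt_mean, scale=sig_g)

    def f_q1(x):
        return norm.pdf(np.asarray(x, dtype=float),
                        loc=config.other_alt_mean, scale=sig_q)

    pi_g = b * config.pi0 + config.n_group_correct / config.n_total
    pi_g0 = b * config.pi0 / pi_g
    pi_g1 = 1.0 - pi_g0

    def pep_g(x):
        x = np.asarray(x, dtype=float)
        null_mass = pi_g0 * f_g0(x)
        den = null_mass + pi_g1 * f_g1(x)
        return np.clip(np.where(den > 0,
                                null_mass / np.where(den > 0, den, 1.0),
                                1.0), 0.0, 1.0)

    # reject configurations whose derived densities go negative before the
    # floor (the floor only absorbs float noise, not model violations)
    probe_hi = max(x_star if np.isfinite(x_star) else 0.0,
                   float(dist0.ppf(0.9999)))
    # start just above 0: the gamma pdf diverges at 0 for shape < 1
    probe = np.linspace(probe_hi / _PROBE_POINTS, probe_hi, _PROBE_POINTS)
    raw_g0 = (-a * dist0.sf(probe) + (a * probe + b) * dist0.pdf(probe)) / b
    raw_g0 = np.where((probe >= 0) & (probe <= x_star), raw_g0, 0.0)
    if np.any(raw_g0 < -1e-9):
        raise ValidationError("derived f_G0 is negative on the probe grid; "
                              "configuration rejected")
    if b < 1.0:
        raw_q0 = (dist0.pdf(probe) - b * np.maximum(raw_g0, 0.0)) / (1.0 - b)
        if np.any(raw_q0 < -1e-9):
            raise ValidationError("derived f_Q0 is negative on the probe "
                                  "grid; configuration rejected")

    return OracleFunctions(config=config, f0=f0, F0=F0, f_g0=f_g0, F_g0=F_g0,
                           f_q0=f_q0, F_q0=F_q0, f_g1=f_g1, f_q1=f_q1,
                           pep_g=pep_g, pi_g=pi_g, pi_g0_true=pi_g0,
                           pi_g1_true=pi_g1, support_upper=x_star)


def _inverse_table(oracle: OracleFunctions, which: str):
    """Cached (cdf, x) grid for inverse-transform sampling of a derived
    null; built once per oracle."""
    if which in oracle._inv_cache:
        return oracle._inv_cache[which]
    dist0 = gamma_dist(oracle.config.null_shape, scale=oracle.config.null_scale)
    if which == "G":
        hi = oracle.support_upper
        if not np.isfinite(hi):
            hi = float(dist0.isf(1e-12))
        cdf = oracle.F_g0
    elif which == "Q":
        hi = float(dist0.isf(1e-12))
        cdf = oracle.F_q0
    else:
        raise ValueError("which must be 'G' or 'Q'")
    xg = np.linspace(0.0, hi, _INVERSE_GRID_POINTS)
    cg = np.asarray(cdf(xg), dtype=float)
    # enforce strict monotonicity for interpolation on the cdf axis
    cg = np.maximum.accumulate(cg)
    oracle._inv_cache[which] = (cg, xg)
    return cg, xg


def sample_derived_null(n: int, which: str, oracle: OracleFunctions,
                        seed=None) -> np.ndarray:
    """Draw ``n`` scores from f_G0 (``which='G'``) or f_Q0 (``'Q'``) by
    inverse-transform sampling on the cached cdf grid.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    cg, xg = _inverse_table(oracle, which)
    u = rng.random(n)
    return np.interp(u, cg, xg)


@dataclass
class SimulatedDataset:
    """A simulated PSM table plus its ground truth and oracle."""

    table: PSMTable
    truth: pd.DataFrame    # psm_id, hypothesis ("H0"/"H1"), component
    oracle: OracleFunctions
    n_g0: int = 0          # realized binomial group-null count
    seed: int = 0

    @property
    def group_target_truth_null(self) -> np.ndarray:
        """Boolean H0 indicator aligned with the group target records."""
        m = self.table.is_target & self.table.in_group
        ids = self.table.df.loc[m, "psm_id"]
        t = self.truth.set_index("psm_id").loc[ids, "hypothesis"]
        return (t == "H0").to_numpy()


def simulate_dataset(config: SimulationConfig,
                     seed: int | None = None) -> SimulatedDataset:
    """Generate one target-decoy dataset from the theoretical model.

    Deterministic given (config, seed); ``seed=None`` uses ``config.seed``.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    oracle = build_oracle(config)
    rng = np.random.default_rng(seed)

    n0, n1 = config.n_null, config.n_correct
    n_gc = config.n_group_correct
    n_g0 = int(rng.binomial(n0, config.gamma_b))
    n_q0 = n0 - n_g0

    def _alt_draw(n, mean, sigma):
        x = rng.normal(mean, sigma, n)
        if config.truncate_negative:
            while np.any(x < 0):
                neg = x < 0
                x[neg] = rng.normal(mean, sigma, int(neg.sum()))
        return x

    t_g0 = sample_derived_null(n_g0, "G", oracle, rng)
    t_q0 = sample_derived_null(n_q0, "Q", oracle, rng)
    t_g1 = _alt_draw(n_gc, config.group_alt_mean, config.group_alt_sigma)
    t_q1 = _alt_draw(n1 - n_gc, config.other_alt_mean, config.other_alt_sigma)
    d_g0 = sample_derived_null(n_g0, "G", oracle, rng)
    d_q0 = sample_derived_null(n_q0, "Q", oracle, rng)

    scores = np.concatenate([t_g0, t_q0, t_g1, t_q1, d_g0, d_q0])
    labels = np.array(["target"] * (n0 + n1) + ["decoy"] * n0)
    in_group = np.concatenate([
        np.ones(n_g0, bool), np.zeros(n_q0, bool),
        np.ones(n_gc, bool), np.zeros(n1 - n_gc, bool),
        np.ones(n_g0, bool), np.zeros(n_q0, bool)])
    component = np.array(["G0"] * n_g0 + ["Q0"] * n_q0 + ["G1"] * n_gc
                         + ["Q1"] * (n1 - n_gc)
                         + ["G0"] * n_g0 + ["Q0"] * n_q0)
    hypothesis = np.array(["H0"] * n0 + ["H1"] * n1 + ["decoy"] * n0)
    ids = np.array([f"T{i + 1:06d}" for i in range(n0 + n1)]
                   + [f"D{i + 1:06d}" for i in range(n0)])

    table = PSMTable.from_arrays(
        ids, scores, labels, in_group,
        provenance=(f"simulate_dataset(seed={seed}, n={n_gc}, "
                    f"N={config.n_total}, pi0={config.pi0})"))
    truth = pd.DataFrame({"psm_id": ids, "hypothesis": hypothesis,
                          "component": component})
    return SimulatedDataset(table=table, truth=truth, oracle=oracle,
                            n_g0=n_g0, seed=int(seed))
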