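"""Model-based estimators for continuous-report error distributions.

The workhorse is the maximum-likelihood circular mixture familiar from the
visual-working-memory literature, adapted to this design in two ways: the
orientation space is the full 360-degree circle (a Landolt-C gap position is
unique on the circle, unlike a grating), and the distractor offset delta_i
varies trial by trial, entering the likelihood per trial rather than as a
single fixed offset.

Standard mixture (shared concentration kappa across components):

    L = prod_i [ (1 - beta - gamma) f_k(e_i) + beta f_k(e_i - d_i) + gamma/360 ]

with f_k the von Mises density parameterised in degrees, e_i the wrapped
report error and d_i the flanker-gap offset. The averaging extension adds a
component p_avg * f_k(e_i - w d_i) with mixing weight p_avg and averaging
weight w in [0, 1]; with few trials its likelihood surface has a known ridge
(w -> 0 mimics target reports, w -> 1 mimics substitution), so fits carry an
instability diagnostic.

Also here: a Monte Carlo proportion estimator (simplex grid + simulated
error distributions scored by a two-sample Kuiper distance), kappa <-> SD
conversion, and the linear-slope fit whose interpretation (0 = target,
0.5 = average, 1 = substitution) is convenient but can be spurious.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .circular import wrap_deg

__all__ = [
    "KAPPA_MIN",
    "KAPPA_MAX",
    "KAPPA_FIT_MIN",
    "kappa_to_circ_sd",
    "circ_sd_to_kappa",
    "MixtureFit",
    "AveragingMixtureFit",
    "MonteCarloFit",
    "SlopeFit",
    "fit_standard_mixture",
    "fit_averaging_mixture",
    "monte_carlo_proportions",
    "kuiper_two_sample",
    "linear_slope",
]

# kappa bounds keep the likelihood finite on degenerate data; hits are logged.
# Conversions admit the full [KAPPA_MIN, KAPPA_MAX] range; the *fits* bound
# kappa below at KAPPA_FIT_MIN (circular SD ~44 deg, far broader than any
# plausible perceptual report noise): a von Mises with near-zero kappa is
# indistinguishable from the uniform guess component, so without that floor
# the guess rate is not identified.
KAPPA_MIN = 0.01
KAPPA_MAX = 500.0
KAPPA_FIT_MIN = 2.0

_DEG2RAD = np.pi / 180.0


# ---------------------------------------------------------------------------
# kappa <-> circular SD
# ---------------------------------------------------------------------------

def _mean_resultant_length(kappa):
    """R(kappa) = I1(kappa)/I0(kappa), computed with exponentially scaled
    Bessel functions for stability at large kappa."""
    k = np.asarray(kappa, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = special.i1e(k) / special.i0e(k)
    return np.where(k == 0.0, 0.0, r)


def kappa_to_circ_sd(kappa) -> float:
    """Circular SD (degrees) of a von Mises with concentration ``kappa``.

    SD = sqrt(-2 ln R(kappa)); strictly decreasing in kappa, -> 0 as
    kappa -> inf and -> inf as kappa -> 0 (returned as ``inf``).
    """
    k = np.asarray(kappa, dtype=float)
    if np.any(k < 0):
        raise ValueError("kappa must be non-negative")
    r = _mean_resultant_length(k)
    with np.errstate(divide="ignore"):
        sd = np.degrees(np.sqrt(-2.0 * np.log(r)))
    sd = np.where(r == 0.0, np.inf, sd)
    return float(sd) if np.ndim(kappa) == 0 else sd


def circ_sd_to_kappa(sd_deg: float) -> float:
    """Inverse of :func:`kappa_to_circ_sd` by monotone root-finding.

    SDs below the kappa_max-representable floor (~2.6 deg at kappa=500) or
    above the kappa_min ceiling are clamped to the bounds with a warning.
    """
    if not np.isfinite(sd_deg) or sd_deg <= 0:
        raise ValueError("sd_deg must be positive and finite")
    sd_at_max = kappa_to_circ_sd(KAPPA_MAX)
    sd_at_min = kappa_to_circ_sd(KAPPA_MIN)
    if sd_deg <= sd_at_max:
        warnings.warn(f"circular SD {sd_deg:.3g} deg below representable floor; clamping kappa to {KAPPA_MAX}")
        return KAPPA_MAX
    if sd_deg >= sd_at_min:
        warnings.warn(f"circular SD {sd_deg:.3g} deg above representable ceiling; clamping kappa to {KAPPA_MIN}")
        return KAPPA_MIN
    return float(optimize.brentq(lambda k: kappa_to_circ_sd(k) - sd_deg, KAPPA_MIN, KAPPA_MAX, xtol=1e-10))


def _vm_pdf_deg(err_deg: np.ndarray, kappa: float) -> np.ndarray:
    """von Mises density on the 360-degree circle, per degree.

    exp(kappa (cos x - 1)) <= 1, so the value is overflow-safe for any kappa.
    """
    x = err_deg * _DEG2RAD
    # 1/(2 pi I0(k)) * exp(k cos x), converted to per-degree
    return np.exp(kappa * (np.cos(x) - 1.0)) / (2.0 * np.pi * special.i0e(kappa)) * _DEG2RAD


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """MLE of the target/substitution/guess mixture with shared kappa."""

    p_target: float
    p_substitution: float
    p_guess: float
    kappa: float
    circ_sd_deg: float
    log_likelihood: float
    n_restarts: int
    converged: bool
    n_trials: int = 0
    warnings_: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "p_target": self.p_target, "p_substitution": self.p_substitution,
            "p_guess": self.p_guess, "kappa": self.kappa,
            "circ_sd_deg": self.circ_sd_deg, "log_likelihood": self.log_likelihood,
            "n_restarts": self.n_restarts, "converged": self.converged,
            "n_trials": self.n_trials, "warnings": list(self.warnings_),
        }


@dataclass
class AveragingMixtureFit(MixtureFit):
    """Averaging-extended mixture fit; flagged unreliable when the
    likelihood surface is degenerate (see ``unstable``)."""

    p_average: float = 0.0
    average_weight: float = 0.5
    unstable: bool = False
    instability: float = 0.0  # spread of p_average across near-optimal restarts
    hessian_cond: float = np.nan

    def to_dict(self) -> dict:
        d = super().to_dict()
        d.update(p_average=self.p_average, average_weight=self.average_weight,
                 unstable=self.unstable, instability=self.instability,
                 hessian_cond=self.hessian_cond)
        return d


@dataclass
class MonteCarloFit:
    """Result of the simulation-grid proportion estimator."""

    p_target: float
    p_substitution: float
    fit_score: float  # Kuiper distance at the argmin cell
    grid: np.ndarray  # candidate p_target values
    scores: np.ndarray  # Kuiper distance per cell


@dataclass
class SlopeFit:
    """OLS fit of report error on flanker-gap offset.

    Slope 0 is consistent with target reports, 1 with substitution, 0.5 with
    averaging — but a 50/50 mix of noisy target and substitution reports also
    yields a slope near 0.5, so the slope alone may give a spurious
    interpretation favouring the averaging model.
    """

    slope: float
    intercept: float
    r_squared: float
    n: int


# ---------------------------------------------------------------------------
# standard mixture MLE
# ---------------------------------------------------------------------------

def _validate_errors_deltas(errors, deltas):
    e = wrap_deg(np.asarray(errors, dtype=float))
    d = wrap_deg(np.asarray(deltas, dtype=float))
    e = np.atleast_1d(e)
    d = np.atleast_1d(d)
    if e.size == 0 or e.shape != d.shape:
        raise ValueError("errors and deltas must be non-empty and aligned")
    return e, d


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - np.max(z)
    ez = np.exp(z)
    return ez / ez.sum()


def fit_standard_mixture(errors, deltas, n_restarts: int = 20, seed=None) -> MixtureFit:
    """Fit the target + substitution + uniform-guess mixture by MLE.

    Parameters are optimised on an unconstrained scale (softmax over the
    three mixing proportions, log kappa) with L-BFGS-B from ``n_restarts``
    random starting points; the best restart is returned. Deterministic
    given ``seed``.
    """
    e, d = _validate_errors_deltas(errors, deltas)
    rng = np.random.default_rng(seed)
    log_k_lo, log_k_hi = np.log(KAPPA_FIT_MIN), np.log(KAPPA_MAX)

    def nll(theta):
        p = _softmax(np.array([0.0, theta[0], theta[1]]))
        kappa = np.exp(np.clip(theta[2], log_k_lo, log_k_hi))
        lik = (p[0] * _vm_pdf_deg(e, kappa)
               + p[1] * _vm_pdf_deg(wrap_deg(e - d), kappa)
               + p[2] / 360.0)
        return -np.sum(np.log(np.maximum(lik, 1e-300)))

    best = None
    n_ok = 0
    for _ in range(n_restarts):
        p0 = rng.dirichlet(np.ones(3))
        th0 = np.array([
            np.log(max(p0[1], 1e-6)) - np.log(max(p0[0], 1e-6)),
            np.log(max(p0[2], 1e-6)) - np.log(max(p0[0], 1e-6)),
            np.log(circ_sd_to_kappa(rng.uniform(5.0, 45.0))),
        ])
        res = optimize.minimize(nll, th0, method="L-BFGS-B")
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(f"mixture optimisation failed on all {n_restarts} restarts")

    p = _softmax(np.array([0.0, best.x[0], best.x[1]]))
    kappa = float(np.exp(np.clip(best.x[2], log_k_lo, log_k_hi)))
    warns = []
    if kappa in (KAPPA_FIT_MIN, KAPPA_MAX):
        warns.append(f"kappa clamped to bound {kappa}")
    return MixtureFit(
        p_target=float(p[0]), p_substitution=float(p[1]), p_guess=float(p[2]),
        kappa=kappa, circ_sd_deg=kappa_to_circ_sd(kappa),
        log_likelihood=float(-best.fun), n_restarts=n_restarts,
        converged=bool(best.success) and n_ok > 0, n_trials=e.size, warnings_=warns,
    )


# ---------------------------------------------------------------------------
# averaging-extended mixture
# ---------------------------------------------------------------------------

_LL_NEIGHBOURHOOD = 2.0  # restarts within this many log-lik units count as ties
_SPREAD_LIMIT = 0.25     # p_average disagreement among tied restarts
_COND_LIMIT = 1e8        # Hessian condition number marking a flat surface


def fit_averaging_mixture(errors, deltas, n_restarts: int = 50, seed=None) -> AveragingMixtureFit:
    """Fit the four-component mixture with an averaged-report component.

    Adds ``p_average * f_k(e - w d)`` with averaging weight ``w`` in [0, 1]
    (logit-transformed). The fit is flagged ``unstable`` when near-optimal
    restarts disagree on ``p_average`` by more than 0.25 or the numerical
    Hessian at the optimum is ill-conditioned — the regime in which the
    extra parameters are not identified from the data.
    """
    e, d = _validate_errors_deltas(errors, deltas)
    rng = np.random.default_rng(seed)
    log_k_lo, log_k_hi = np.log(KAPPA_FIT_MIN), np.log(KAPPA_MAX)

    def unpack(theta):
        p = _softmax(np.array([0.0, theta[0], theta[1], theta[2]]))
        kappa = np.exp(np.clip(theta[3], log_k_lo, log_k_hi))
        w = special.expit(theta[4])
        return p, kappa, w

    def nll(theta):
        p, kappa, w = unpack(theta)
        lik = (p[0] * _vm_pdf_deg(e, kappa)
               + p[1] * _vm_pdf_deg(wrap_deg(e - d), kappa)
               + p[2] * _vm_pdf_deg(wrap_deg(e - w * d), kappa)
               + p[3] / 360.0)
        return -np.sum(np.log(np.maximum(lik, 1e-300)))

    results = []
    for _ in range(n_restarts):
        p0 = rng.dirichlet(np.ones(4))
        th0 = np.array([
            np.log(max(p0[1], 1e-6)) - np.log(max(p0[0], 1e-6)),
            np.log(max(p0[2], 1e-6)) - np.log(max(p0[0], 1e-6)),
            np.log(max(p0[3], 1e-6)) - np.log(max(p0[0], 1e-6)),
            np.log(circ_sd_to_kappa(rng.uniform(5.0, 45.0))),
            rng.normal(0.0, 1.5),
        ])
        res = optimize.minimize(nll, th0, method="L-BFGS-B")
        if np.isfinite(res.fun):
            results.append(res)
    if not results:
        raise RuntimeError(f"averaging-mixture optimisation failed on all {n_restarts} restarts")

    best = min(results, key=lambda r: r.fun)
    p, kappa, w = unpack(best.x)

    tied = [r for r in results if r.fun <= best.fun + _LL_NEIGHBOURHOOD]
    p_avg_tied = np.array([unpack(r.x)[0][2] for r in tied])
    spread = float(p_avg_tied.max() - p_avg_tied.min()) if len(tied) > 1 else 0.0

    cond = _hessian_condition(nll, best.x)
    unstable = (spread > _SPREAD_LIMIT) or (not np.isfinite(cond)) or (cond > _COND_LIMIT)

    warns = []
    if unstable:
        warns.append("averaging-extended fit unreliable: flat/ridged likelihood surface")
    return AveragingMixtureFit(
        p_target=float(p[0]), p_substitution=float(p[1]), p_guess=float(p[3]),
        p_average=float(p[2]), average_weight=float(w),
        kappa=float(kappa), circ_sd_deg=kappa_to_circ_sd(float(kappa)),
        log_likelihood=float(-best.fun), n_restarts=n_restarts,
        converged=bool(best.success), n_trials=e.size,
        unstable=bool(unstable), instability=spread, hessian_cond=float(cond),
        warnings_=warns,
    )


def _hessian_condition(f, x, h: float = 1e-4) -> float:
    """Condition number of a central-difference Hessian of ``f`` at ``x``."""
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h * h)
    try:
        sv = np.linalg.svd(H, compute_uv=False)
    except np.linalg.LinAlgError:
        return np.inf
    if sv[-1] <= 0 or not np.all(np.isfinite(sv)):
        return np.inf
    return float(sv[0] / sv[-1])


# ---------------------------------------------------------------------------
# Monte Carlo proportion estimator
# ---------------------------------------------------------------------------

def kuiper_two_sample(x_deg, y_deg) -> float:
    """Two-sample Kuiper statistic V = D+ + D- on circular data in degrees.

    Kuiper's V is invariant to a common rotation of both samples, which
    makes it the natural Kolmogorov-Smirnov variant for angles.
    """
    x = np.sort(np.mod(np.asarray(x_deg, dtype=float), 360.0))
    y = np.sort(np.mod(np.asarray(y_deg, dtype=float), 360.0))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    fx = np.searchsorted(x, grid, side="right") / x.size
    fy = np.searchsorted(y, grid, side="right") / y.size
    return float(np.max(fx - fy) + np.max(fy - fx))


def monte_carlo_proportions(
    errors,
    deltas,
    noise_sd_deg: float,
    grid_step: float = 0.05,
    n_sims_per_cell: int = 200,
    seed=None,
) -> MonteCarloFit:
    """Estimate (p_target, p_substitution) by simulation-grid search.

    Assumes reports are a two-component mix of target reports (error 0) and
    substitution reports (error delta), each plus Gaussian orientation noise
    of ``noise_sd_deg`` (estimated from unflanked data or supplied). For
    each candidate p_target on a simplex grid, ``n_sims_per_cell`` synthetic
    datasets of the observed size are pooled (deltas resampled from the
    observed deltas) and the pooled error distribution is scored against the
    observed one with the two-sample Kuiper statistic; the argmin cell wins.
    """
    e, d = _validate_errors_deltas(errors, deltas)
    if noise_sd_deg <= 0:
        raise ValueError("noise_sd_deg must be positive")
    if not 0 < grid_step <= 1:
        raise ValueError("grid_step must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    grid = np.arange(0.0, 1.0 + grid_step / 2.0, grid_step)
    n_sim = n_sims_per_cell * e.size
    scores = np.empty(grid.size)
    for i, p_t in enumerate(grid):
        sim_d = rng.choice(d, size=n_sim, replace=True)
        is_target = rng.random(n_sim) < p_t
        centre = np.where(is_target, 0.0, sim_d)
        sim_e = wrap_deg(centre + rng.normal(0.0, noise_sd_deg, size=n_sim))
        scores[i] = kuiper_two_sample(e, sim_e)
    i_best = int(np.argmin(scores))
    return MonteCarloFit(
        p_target=float(grid[i_best]), p_substitution=float(1.0 - grid[i_best]),
        fit_score=float(scores[i_best]), grid=grid, scores=scores,
    )


# ---------------------------------------------------------------------------
# linear slope
# ---------------------------------------------------------------------------

def linear_slope(errors, deltas) -> SlopeFit:
    """OLS regression of wrapped report error on flanker-gap offset.

    Offsets beyond +/-90 deg trigger a warning: wrapping makes the linear
    model questionable there (offsets are naturally concentrated, SD 22.5
    deg, so this is rare in practice).
    """
    e, d = _validate_errors_deltas(errors, deltas)
    if e.size < 3:
        raise ValueError("linear_slope requires at least 3 trials")
    if np.ptp(d) == 0:
        raise ValueError("deltas have no variance: slope undefined")
    if np.any(np.abs(d) > 90.0):
        warnings.warn("deltas beyond +/-90 deg present: linear fit may be wrap-corrupted")
    res = stats.linregress(d, e)
    return SlopeFit(slope=float(res.slope), intercept=float(res.intercept),
                    r_squared=float(res.rvalue ** 2), n=e.size)
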