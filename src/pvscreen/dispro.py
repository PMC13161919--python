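"""Disproportionality statistics for drug-event 2x2 tables.

Four families of signal statistics are computed per drug-event pair, each in
its standard published form:

* **ROR** — reporting odds ratio ``ad/bc`` with a Woolf (log-scale Wald)
  95% interval, ``exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  Pearson chi-squared statistic on the table, Yates-continuity-corrected by
  default.
* **BCPNN IC** — the information component of the Bayesian confidence
  propagation neural network, ``log2`` of the ratio of the posterior joint
  reporting probability to the product of the posterior margins under the
  conjugate Beta priors of the original closed-form recipe
  (gamma11 = 1, alpha = beta = 2, alpha1 = beta1 = 1); the lower bound is
  ``IC025 = E(IC) - 2 * sqrt(V(IC))``.
* **MGPS EBGM** — the empirical-Bayes geometric mean of the relative
  reporting rate ``lambda`` under DuMouchel's two-component gamma mixture
  prior fitted by maximum marginal likelihood across all pairs (the
  gamma-Poisson marginal is negative binomial); ``EB05`` is the posterior
  5th percentile.

A pair is a **positive signal** when all screening thresholds hold jointly:
at least ``min_reports`` co-reports, ROR 95% CI lower bound > 1, PRR >= 2,
chi-squared >= 4, IC025 > 0 and EB05 > 2.

Zero-cell policy: a = 0 makes every association statistic degenerate and the
pair can never reach the report-count threshold, so such pairs are skipped
with an explicit reason; a zero in b, c or d triggers the Haldane-Anscombe
+0.5 on all four cells for the ratio statistics (ROR, PRR) only.
Not-computable statistics propagate as NaN, never silently as 0 or 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .contingency import ContingencyTable

logger = logging.getLogger("pvscreen.dispro")

__all__ = [
    "NotComputable",
    "SignalCriteria",
    "DisproportionalityResult",
    "GammaMixturePrior",
    "PriorFit",
    "ror_with_ci",
    "prr_with_chi2",
    "bcpnn_ic",
    "fit_gamma_mixture_prior",
    "marginal_loglik",
    "ebgm_posterior",
    "evaluate_signal_criteria",
    "compute_signals",
    "read_results",
    "write_results",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "drug", "n", "ror", "ror_lo", "ror_hi", "prr", "chi2",
    "ic", "ic025", "ebgm", "eb05", "is_signal",
]

_LN2 = math.log(2.0)


class NotComputable(ValueError):
    """A statistic is undefined for this table; carries the reason."""


@dataclass(frozen=True)
class SignalCriteria:
    """Conjunctive positive-signal thresholds (all must hold)."""

    min_reports: int = 3
    ror_lo_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    eb05_gt: float = 2.0


@dataclass
class DisproportionalityResult:
    """All signal statistics for one drug-event pair; NaN = not computable."""

    n_reports: int
    ror: float = math.nan
    ror_lo: float = math.nan
    ror_hi: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    eb05: float = math.nan
    is_signal: bool = False


# --------------------------------------------------------------------------
# Frequentist statistics


def _cells(t: ContingencyTable, correction: bool) -> Tuple[float, float, float, float]:
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if correction and min(b, c, d) == 0.0:
        logger.info("zero cell in (b,c,d)=(%g,%g,%g); Haldane-Anscombe +0.5 applied", b, c, d)
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d


def ror_with_ci(
    t: ContingencyTable, z: float = 1.96, correction: bool = True
) -> Tuple[float, float, float]:
    """Reporting odds ratio with Woolf log-scale 95% CI bounds."""
    if t.a == 0:
        raise NotComputable("a = 0: no co-reports, ROR undefined")
    a, b, c, d = _cells(t, correction)
    if min(b, c, d) == 0.0:
        raise NotComputable("zero cell with continuity correction disabled")
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def prr_with_chi2(
    t: ContingencyTable, chi2_mode: str = "yates", correction: bool = True
) -> Tuple[float, float]:
    """Proportional reporting ratio and the (Yates or plain) Pearson chi2.

    The chi-squared statistic is computed on the raw cells; the Haldane
    correction applies only to the ratio.
    """
    if t.a == 0:
        raise NotComputable("a = 0: no co-reports, PRR undefined")
    a, b, c, d = _cells(t, correction)
    if c == 0.0 or a + b == 0.0 or c + d == 0.0:
        raise NotComputable("empty margin: PRR undefined")
    prr = (a / (a + b)) / (c / (c + d))

    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0.0:
        return prr, math.nan
    diff = abs(a * d - b * c)
    if chi2_mode == "yates":
        diff = max(diff - n / 2.0, 0.0)
    elif chi2_mode != "pearson":
        raise ValueError(f"unknown chi2 mode: {chi2_mode!r}")
    chi2 = n * diff * diff / denom
    return prr, chi2


# --------------------------------------------------------------------------
# BCPNN information component

# Hyperparameters of the closed-form recipe: joint prior Beta(gamma11, gamma - gamma11)
# with gamma tuned so the prior satisfies independence at the posterior margins,
# margin priors Beta(alpha1, alpha - alpha1) = Beta(1, 1).
_G11 = 1.0
_ALPHA = 2.0
_ALPHA1 = 1.0


def bcpnn_ic(t: ContingencyTable, variance: str = "moments") -> Tuple[float, float]:
    """Expected information component (bits) and its IC025 lower bound.

    ``ic`` is the conventional plug-in posterior estimate
    ``log2[(a+1)(N+2)^2 / ((N+gamma)(a+b+1)(a+c+1))]``; it is exactly 0 on a
    symmetric independence table.  ``ic025 = E(IC) - 2*sqrt(V(IC))`` with the
    three-term variance in one of two dialects:

    * ``"moments"`` (default) — exact posterior moments of ``log p`` under
      the model's Beta posteriors (digamma mean, trigamma variance); this
      tracks the Monte-Carlo posterior 2.5th percentile to < 0.1 bits down
      to small a-cells.
    * ``"bate1998"`` — the original delta-method variance around the
      plug-in estimate; noticeably anti-conservative below a ~ 10.
    """
    a, n = float(t.a), float(t.N)
    r1 = float(t.a + t.b)  # drug margin
    c1 = float(t.a + t.c)  # event margin
    if n < 1:
        raise NotComputable("empty table")
    gamma = _G11 * (n + _ALPHA) * (n + _ALPHA) / ((r1 + _ALPHA1) * (c1 + _ALPHA1))
    ic = math.log2(
        (a + _G11) * (n + _ALPHA) * (n + _ALPHA)
        / ((n + gamma) * (r1 + _ALPHA1) * (c1 + _ALPHA1))
    )
    if variance == "moments":
        psi, psi1 = special.digamma, lambda x: special.polygamma(1, x)
        e_ln = (
            (psi(a + _G11) - psi(n + gamma))
            - (psi(r1 + _ALPHA1) - psi(n + _ALPHA))
            - (psi(c1 + _ALPHA1) - psi(n + _ALPHA))
        )
        v_ln = (
            (psi1(a + _G11) - psi1(n + gamma))
            + (psi1(r1 + _ALPHA1) - psi1(n + _ALPHA))
            + (psi1(c1 + _ALPHA1) - psi1(n + _ALPHA))
        )
        ic025 = (e_ln - 2.0 * math.sqrt(v_ln)) / _LN2
    elif variance == "bate1998":
        var = (
            (n - a + gamma - _G11) / ((a + _G11) * (1.0 + n + gamma))
            + (n - r1 + _ALPHA - _ALPHA1) / ((r1 + _ALPHA1) * (1.0 + n + _ALPHA))
            + (n - c1 + _ALPHA - _ALPHA1) / ((c1 + _ALPHA1) * (1.0 + n + _ALPHA))
        ) / (_LN2 * _LN2)
        ic025 = ic - 2.0 * math.sqrt(var)
    else:
        raise ValueError(f"unknown IC variance dialect: {variance!r}")
    return ic, ic025


# --------------------------------------------------------------------------
# MGPS: gamma-mixture prior fit and EBGM posterior


@dataclass(frozen=True)
class GammaMixturePrior:
    """Two-component gamma prior on the relative reporting rate lambda.

    Component j is Gamma(shape=alpha_j, rate=beta_j); component 1 carries
    mixture weight w.  The marginal of the observed count a given the
    expected count E is the matching two-component negative binomial.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes and rates must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("mixture weight must lie strictly in (0, 1)")

    def as_tuple(self) -> Tuple[float, float, float, float, float]:
        return (self.alpha1, self.beta1, self.alpha2, self.beta2, self.w)


#: Conventional DuMouchel starting point for the hyperparameter search.
DEFAULT_PRIOR_START = GammaMixturePrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass
class PriorFit:
    """Fitted prior plus convergence diagnostics."""

    prior: GammaMixturePrior
    loglik: float
    converged: bool
    n_restarts: int
    message: str = ""


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    """log P(a) for the gamma-Poisson (negative binomial) marginal."""
    logp = np.log(beta) - np.log(beta + e)
    log1mp = np.log(e) - np.log(beta + e)
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * logp
        + a * log1mp
    )


def _mixture_loglik_terms(
    prior: GammaMixturePrior, a: np.ndarray, e: np.ndarray
) -> np.ndarray:
    l1 = np.log(prior.w) + _nb_logpmf(a, prior.alpha1, prior.beta1, e)
    l2 = np.log1p(-prior.w) + _nb_logpmf(a, prior.alpha2, prior.beta2, e)
    return np.logaddexp(l1, l2)


def marginal_loglik(prior: GammaMixturePrior, a: Sequence[float], e: Sequence[float]) -> float:
    """Total log marginal likelihood of observed counts under the prior."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")
    return float(_mixture_loglik_terms(prior, a, e).sum())


def _unpack(u: np.ndarray) -> GammaMixturePrior:
    return GammaMixturePrior(
        math.exp(u[0]), math.exp(u[1]), math.exp(u[2]), math.exp(u[3]),
        1.0 / (1.0 + math.exp(-u[4])),
    )


def fit_gamma_mixture_prior(
    a: Sequence[float],
    e: Sequence[float],
    start: GammaMixturePrior = DEFAULT_PRIOR_START,
    n_restarts: int = 5,
    seed: int = 20090,
    tol: float = 1e-6,
) -> PriorFit:
    """Fit the five hyperparameters by maximum marginal likelihood.

    The search runs in unconstrained (log shapes/rates, logit weight) space
    with L-BFGS-B and finite-difference gradients, from the documented start
    point plus ``n_restarts`` deterministically jittered restarts; the best
    optimum wins, and it is guaranteed to be at least as good as the start.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise ValueError("a and E must be equal-length 1-d sequences")
    if len(a) < 2:
        raise ValueError("need at least two pairs to fit the prior")
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")

    scale = 1.0 / len(a)

    def negloglik(u: np.ndarray) -> float:
        try:
            prior = _unpack(u)
        except (OverflowError, ValueError):
            return 1e12
        val = _mixture_loglik_terms(prior, a, e).sum() * scale
        return 1e12 if not np.isfinite(val) else -float(val)

    s = start.as_tuple()
    u0 = np.array([
        math.log(s[0]), math.log(s[1]), math.log(s[2]), math.log(s[3]),
        math.log(s[4] / (1.0 - s[4])),
    ])
    rng = np.random.default_rng(seed)
    starts = [u0] + [u0 + rng.normal(0.0, 0.5, size=5) for _ in range(n_restarts)]

    # Box in log/logit space: shapes and rates in [e^-15, e^15].  Outside it the
    # NB log-pmf loses all precision (gammaln cancellation) and the flat, noisy
    # surface can fake arbitrarily good objective values.
    bounds = [(-15.0, 15.0)] * 5

    best = None
    any_converged = False
    for u_init in starts:
        res = optimize.minimize(
            negloglik, np.clip(u_init, -14.0, 14.0), method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": tol * scale, "gtol": 1e-8},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    ll_start = marginal_loglik(start, a, e)
    ll_best = -best.fun / scale
    if ll_best < ll_start:  # never return worse than the documented start
        return PriorFit(start, ll_start, any_converged, n_restarts, "kept start point")
    fit = PriorFit(_unpack(best.x), ll_best, any_converged, n_restarts, str(best.message))
    if not any_converged:
        logger.warning("MGPS prior fit did not converge: %s", fit.message)
    return fit


def ebgm_posterior(
    t: ContingencyTable | Tuple[float, float], prior: GammaMixturePrior
) -> Tuple[float, float]:
    """EBGM (posterior geometric mean of lambda) and EB05 (5th percentile).

    Accepts either a contingency table (E is derived from its margins) or a
    raw ``(a, E)`` pair.  The posterior is the two-component gamma mixture
    ``Q * Gamma(alpha1 + a, beta1 + E) + (1-Q) * Gamma(alpha2 + a, beta2 + E)``
    with Q the posterior component weight; the geometric mean uses the
    digamma closed form and EB05 is found by bracketed root-finding on the
    mixture CDF.
    """
    if isinstance(t, ContingencyTable):
        a, e = float(t.a), t.expected
    else:
        a, e = float(t[0]), float(t[1])
    if e <= 0:
        raise NotComputable("expected count E must be positive")

    arr = np.array([a])
    earr = np.array([e])
    l1 = math.log(prior.w) + float(_nb_logpmf(arr, prior.alpha1, prior.beta1, earr)[0])
    l2 = math.log1p(-prior.w) + float(_nb_logpmf(arr, prior.alpha2, prior.beta2, earr)[0])
    q = math.exp(l1 - np.logaddexp(l1, l2))  # stable posterior component weight

    sh1, rt1 = prior.alpha1 + a, prior.beta1 + e
    sh2, rt2 = prior.alpha2 + a, prior.beta2 + e
    mean_log = q * (special.digamma(sh1) - math.log(rt1)) + (1.0 - q) * (
        special.digamma(sh2) - math.log(rt2)
    )
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return q * stats.gamma.cdf(x, sh1, scale=1.0 / rt1) + (1.0 - q) * stats.gamma.cdf(
            x, sh2, scale=1.0 / rt2
        )

    lo, hi = 1e-12, max(ebgm * 10.0, 1e-6)
    while cdf(hi) < 0.05:
        hi *= 10.0
    eb05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12, rtol=1e-12))
    return ebgm, eb05


# --------------------------------------------------------------------------
# Signal evaluation and the per-drug sweep


def evaluate_signal_criteria(
    r: DisproportionalityResult, c: SignalCriteria = SignalCriteria()
) -> bool:
    """True iff every screening condition holds; NaN components fail theirs."""
    checks = (
        r.n_reports >= c.min_reports,
        r.ror_lo > c.ror_lo_gt,
        r.prr >= c.prr_ge,
        r.chi2 >= c.chi2_ge,
        r.ic025 > c.ic025_gt,
        r.eb05 > c.eb05_gt,
    )
    return all(bool(x) and not (isinstance(x, float) and math.isnan(x)) for x in checks)


def compute_signals(
    tables: pd.DataFrame,
    criteria: SignalCriteria = SignalCriteria(),
    chi2_mode: str = "yates",
    prior: Optional[GammaMixturePrior] = None,
    z: float = 1.96,
    correction: bool = True,
) -> Tuple[pd.DataFrame, PriorFit | None]:
    """All four statistics plus the signal flag for every drug in ``tables``.

    The MGPS prior, unless supplied, is fitted once across *all* pairs
    (including a = 0 pairs, which carry information about the null
    component); shrinkage needs that shared prior.  Pairs with a = 0 are
    then skipped in the per-drug statistics with a logged reason.
    """
    a_all = tables["a"].to_numpy(dtype=float)
    e_all = (
        (tables["a"] + tables["b"]) * (tables["a"] + tables["c"]) / tables["N"]
    ).to_numpy(dtype=float)
    keep = e_all > 0
    fit: PriorFit | None = None
    if prior is None:
        fit = fit_gamma_mixture_prior(a_all[keep], e_all[keep])
        prior = fit.prior

    rows = []
    for rec in tables.itertuples(index=False):
        t = ContingencyTable(int(rec.a), int(rec.b), int(rec.c), int(rec.d))
        if t.a == 0:
            logger.info("pair %r skipped: a = 0", rec.drug)
            continue
        r = DisproportionalityResult(n_reports=t.a)
        try:
            r.ror, r.ror_lo, r.ror_hi = ror_with_ci(t, z=z, correction=correction)
        except NotComputable as exc:
            logger.info("ROR not computable for %r: %s", rec.drug, exc)
        try:
            r.prr, r.chi2 = prr_with_chi2(t, chi2_mode=chi2_mode, correction=correction)
        except NotComputable as exc:
            logger.info("PRR not computable for %r: %s", rec.drug, exc)
        r.ic, r.ic025 = bcpnn_ic(t)
        if t.expected > 0:
            r.ebgm, r.eb05 = ebgm_posterior(t, prior)
        r.is_signal = evaluate_signal_criteria(r, criteria)
        rows.append(
            {
                "drug": rec.drug, "n": t.a, "ror": r.ror, "ror_lo": r.ror_lo,
                "ror_hi": r.ror_hi, "prr": r.prr, "chi2": r.chi2, "ic": r.ic,
                "ic025": r.ic025, "ebgm": r.ebgm, "eb05": r.eb05,
                "is_signal": r.is_signal,
            }
        )
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return results, fit


def write_results(results: pd.DataFrame, path) -> None:
    """Write the fixed-order results table, floats at 4 decimals."""
    results.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"drug": str})
    df["is_signal"] = df["is_signal"].astype(bool)
    return df[RESULT_COLUMNS]
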