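"""Significance estimation for spectral library hits.

Two complementary routes from a list of best-hit scores to FDRs/q-values:

**Separated target–decoy.**  Queries are searched once against the target
library and once against the decoy library; the merged, score-sorted hit
list gives, at any score threshold t,

    FDR(t) = PIT · D(t) / T(t)

where T(t), D(t) count target/decoy hits scoring ≥ t and PIT (percentage of
incorrect targets) is the fraction of *all* target hits that are wrong,
estimated from the empirical-Bayes mixture below.  The q-value of a hit is
the minimal FDR at which it would still be reported (a running minimum over
thresholds at or below its score).  With PIT = 1 this reduces to the
classical separated target–decoy estimator.

**Empirical Bayes.**  Target best-hit scores are modeled as a two-component
mixture: false hits follow a Gamma distribution of the score s, true hits a
*mirrored* Gamma, Gumbel or Weibull — the named distribution applied to
(1 − s), so its mass sits near the top of the cosine score range.
Expectation–Maximization fits the mixture weight π₀ and both components;
the posterior error probability of a hit is

    PEP(s) = π₀ f₀(s) / (π₀ f₀(s) + (1 − π₀) f₁(s)),

FDR at a threshold is the average PEP of hits above it, and PIT = π₀ (the
area under the scaled false-component curve).

A decoy-based p-value is also provided: the fraction of decoy hits scoring
above a given score, which must be uniformly distributed for false hits if
the decoy library truly models the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import special, stats
from scipy.optimize import brentq

from .scoring import SpectrumMatch

logger = logging.getLogger("specfdr")

TrueFamily = Literal["gamma", "gumbel", "weibull"]

#: Smallest sample size for which the mixture fit is attempted.
MIN_SCORES_FOR_EB = 50

_EPS = 1e-12
_X_FLOOR = 1e-6  # mirrored variable clipped away from 0 (scores of exactly 1)


def sort_hits(hits: Sequence[SpectrumMatch]) -> list[SpectrumMatch]:
    """Score-descending order; at equal score decoys come first (conservative)."""
    return sorted(hits, key=lambda m: (-m.score, m.origin != "decoy", m.query_id))


# ---------------------------------------------------------------------------
# Separated target-decoy FDR
# ---------------------------------------------------------------------------

@dataclass
class FdrCurve:
    """FDR and q-values along the score-sorted target hit list."""

    target_hits: list[SpectrumMatch] = field(default_factory=list)
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))
    n_target: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_decoy: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    fdr: np.ndarray = field(default_factory=lambda: np.array([]))
    q: np.ndarray = field(default_factory=lambda: np.array([]))
    pit: float = 1.0

    def __len__(self) -> int:
        return len(self.target_hits)

    def q_at_fdr(self, level: float) -> tuple[float, int]:
        """(score threshold, number of target hits) accepted at q ≤ level."""
        ok = np.nonzero(self.q <= level)[0]
        if ok.size == 0:
            return float("nan"), 0
        last = int(ok[-1])
        return float(self.thresholds[last]), last + 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "query_id": [m.query_id for m in self.target_hits],
                "reference_id": [m.reference_id for m in self.target_hits],
                "score": self.thresholds,
                "n_target": self.n_target,
                "n_decoy": self.n_decoy,
                "fdr": self.fdr,
                "q": self.q,
            }
        )


def estimate_fdr_tda(
    targets: Sequence[SpectrumMatch],
    decoys: Sequence[SpectrumMatch],
    pit: float = 1.0,
) -> FdrCurve:
    """Separated target–decoy FDR/q-values: FDR(t) = pit · D(t)/T(t).

    Candidate thresholds are the target hit scores; counting decoys before
    targets at tied scores makes the estimate conservative.  q-values are
    the running minimum of FDR over thresholds at or below each hit's score.
    """
    if not 0.0 <= pit <= 1.0:
        raise ValueError(f"pit must be in [0,1], got {pit}")
    if not targets:
        logger.warning("estimate_fdr_tda: empty target hit list")
        return FdrCurve(pit=pit)
    merged = sort_hits(list(targets) + list(decoys))
    t_count = d_count = 0
    rows = []
    for m in merged:
        if m.origin == "decoy":
            d_count += 1
        else:
            t_count += 1
            rows.append((m, m.score, t_count, d_count))
    thresholds = np.array([r[1] for r in rows])
    n_target = np.array([r[2] for r in rows], dtype=int)
    n_decoy = np.array([r[3] for r in rows], dtype=int)
    fdr = pit * n_decoy / n_target
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    return FdrCurve(
        target_hits=[r[0] for r in rows],
        thresholds=thresholds,
        n_target=n_target,
        n_decoy=n_decoy,
        fdr=fdr,
        q=q,
        pit=pit,
    )


def estimate_p_value(
    score: float, decoys: Sequence[SpectrumMatch], laplace: bool = False
) -> float:
    """Decoy-based p-value: fraction of decoy hits scoring strictly above ``score``.

    ``laplace`` applies the add-one correction (k+1)/(n+1), for users who
    cannot work with p = 0.
    """
    if not decoys:
        raise ValueError("estimate_p_value requires a non-empty decoy hit list")
    n = len(decoys)
    k = sum(1 for d in decoys if d.score > score)
    if laplace:
        return (k + 1) / (n + 1)
    return k / n


# ---------------------------------------------------------------------------
# Empirical-Bayes mixture
# ---------------------------------------------------------------------------

def _wmean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def _fit_gamma_weighted(x: np.ndarray, w: np.ndarray,
                        start: tuple[float, float]) -> tuple[float, float]:
    """Weighted Gamma MLE (shape, scale) via the digamma equation."""
    mx = _wmean(x, w)
    mlog = _wmean(np.log(x), w)
    s = np.log(mx) - mlog
    if s <= 0:  # degenerate (near-constant data): keep current parameters
        return start

    def f(a: float) -> float:
        return np.log(a) - special.digamma(a) - s

    try:
        a = brentq(f, 1e-3, 1e4)
    except ValueError:
        return start
    return a, mx / a


def _fit_gumbel_weighted(x: np.ndarray, w: np.ndarray,
                         start: tuple[float, float]) -> tuple[float, float]:
    """Weighted Gumbel (right-skewed, location/scale) MLE via profile equation."""
    mx = _wmean(x, w)
    xmin = float(np.min(x))

    def f(beta: float) -> float:
        # shift the exponent so the weights cannot all underflow to zero
        e = np.exp(-(x - xmin) / beta)
        return beta - mx + np.sum(w * x * e) / np.sum(w * e)

    lo, hi = 1e-4, 10.0
    try:
        beta = brentq(f, lo, hi)
    except ValueError:
        return start
    loc = -beta * np.log(np.sum(w * np.exp(-x / beta)) / np.sum(w))
    return loc, beta


def _fit_weibull_weighted(x: np.ndarray, w: np.ndarray,
                          start: tuple[float, float]) -> tuple[float, float]:
    """Weighted Weibull MLE (shape c, scale) via the standard profile equation."""
    logs = np.log(x)
    mlog = _wmean(logs, w)

    def f(c: float) -> float:
        xc = x ** c
        return np.sum(w * xc * logs) / np.sum(w * xc) - mlog - 1.0 / c

    try:
        c = brentq(f, 1e-2, 1e3)
    except ValueError:
        return start
    scale = (np.sum(w * x ** c) / np.sum(w)) ** (1.0 / c)
    return c, scale


@dataclass
class MixtureModel:
    """Fitted two-component score mixture.

    ``false_params`` are Gamma (shape, scale) on the score s itself;
    ``true_params`` parameterize the mirrored family on x = 1 − s
    (Gamma/Weibull: shape, scale; Gumbel: location, scale).
    """

    pi0: float
    true_family: TrueFamily
    false_params: tuple[float, float]
    true_params: tuple[float, float]
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    loglik_history: list[float] = field(default_factory=list)
    score_max: float = 1.0

    def false_density(self, s: np.ndarray | float) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), _X_FLOOR, None)
        a, b = self.false_params
        return stats.gamma.pdf(s, a, scale=b)

    def true_density(self, s: np.ndarray | float) -> np.ndarray:
        x = np.clip(self.score_max - np.asarray(s, dtype=float), _X_FLOOR, None)
        p1, p2 = self.true_params
        if self.true_family == "gamma":
            return stats.gamma.pdf(x, p1, scale=p2)
        if self.true_family == "gumbel":
            return stats.gumbel_r.pdf(x, loc=p1, scale=p2)
        return stats.weibull_min.pdf(x, p1, scale=p2)

    def mixture_density(self, s: np.ndarray | float) -> np.ndarray:
        return self.pi0 * self.false_density(s) + (1 - self.pi0) * self.true_density(s)


def _loglik(scores: np.ndarray, m: MixtureModel) -> float:
    return float(np.sum(np.log(m.mixture_density(scores) + _EPS)))


def fit_mixture_em(
    scores: Sequence[float],
    true_family: TrueFamily | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MixtureModel:
    """Fit the two-component mixture by EM.

    When ``true_family`` is None, all three mirrored families are fitted and
    the maximum-likelihood one returned.  Initialization is deterministic:
    method-of-moments on the lower/upper score halves for the false/true
    component and π₀ = 0.5.  Each M-step solves the exact weighted MLE for
    its component (falling back to the current parameters when the update
    would lower the expected complete-data log-likelihood), so the observed
    log-likelihood is non-decreasing.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < MIN_SCORES_FOR_EB:
        raise ValueError(
            f"empirical-Bayes mixture needs at least {MIN_SCORES_FOR_EB} scores, "
            f"got {s.size}; use the target-decoy estimator for small hit lists"
        )
    if np.any(s <= 0) or np.any(s > 1.0 + 1e-9):
        raise ValueError("scores must lie in (0, 1]")
    if true_family is None:
        fits = [fit_mixture_em(s, fam, max_iter, tol) for fam in ("gamma", "gumbel", "weibull")]
        return max(fits, key=lambda m: m.loglik)

    # deterministic moment init on the score halves
    med = float(np.median(s))
    lo = s[s <= med]
    hi = s[s > med]
    if hi.size < 2 or lo.size < 2:
        lo = hi = s

    def mom_gamma(v: np.ndarray) -> tuple[float, float]:
        mu, var = float(np.mean(v)), float(np.var(v)) + _EPS
        shape = max(mu * mu / var, 1e-2)
        return shape, mu / shape

    false_params = mom_gamma(np.clip(lo, _X_FLOOR, None))
    x_hi = np.clip(1.0 - hi, _X_FLOOR, None)
    if true_family == "gamma":
        true_params = mom_gamma(x_hi)
    elif true_family == "gumbel":
        mu, sd = float(np.mean(x_hi)), float(np.std(x_hi)) + _EPS
        beta = sd * np.sqrt(6) / np.pi
        true_params = (mu - np.euler_gamma * beta, beta)
    else:  # weibull
        true_params = (1.5, float(np.mean(x_hi)) + _EPS)

    model = MixtureModel(0.5, true_family, false_params, true_params)
    model.loglik = _loglik(s, model)
    model.loglik_history = [model.loglik]
    x = np.clip(model.score_max - s, _X_FLOOR, None)
    s_clip = np.clip(s, _X_FLOOR, None)

    def component_obj_false(params: tuple[float, float], w: np.ndarray) -> float:
        a, b = params
        return float(np.sum(w * stats.gamma.logpdf(s_clip, a, scale=b)))

    def component_obj_true(params: tuple[float, float], w: np.ndarray) -> float:
        p1, p2 = params
        if true_family == "gamma":
            lp = stats.gamma.logpdf(x, p1, scale=p2)
        elif true_family == "gumbel":
            lp = stats.gumbel_r.logpdf(x, loc=p1, scale=p2)
        else:
            lp = stats.weibull_min.logpdf(x, p1, scale=p2)
        return float(np.sum(w * lp))

    converged = False
    for it in range(1, max_iter + 1):
        # E-step
        f0 = model.false_density(s) + _EPS
        f1 = model.true_density(s) + _EPS
        r0 = model.pi0 * f0 / (model.pi0 * f0 + (1 - model.pi0) * f1)
        # M-step (guarded exact weighted MLEs)
        pi0 = float(np.mean(r0))
        new_false = _fit_gamma_weighted(s_clip, r0 + _EPS, model.false_params)
        if component_obj_false(new_false, r0) < component_obj_false(model.false_params, r0):
            new_false = model.false_params
        w1 = (1 - r0) + _EPS
        if true_family == "gamma":
            new_true = _fit_gamma_weighted(x, w1, model.true_params)
        elif true_family == "gumbel":
            new_true = _fit_gumbel_weighted(x, w1, model.true_params)
        else:
            new_true = _fit_weibull_weighted(x, w1, model.true_params)
        if component_obj_true(new_true, w1) < component_obj_true(model.true_params, w1):
            new_true = model.true_params
        model.pi0, model.false_params, model.true_params = pi0, new_false, new_true
        ll = _loglik(s, model)
        model.loglik_history.append(ll)
        delta = ll - model.loglik
        model.loglik = ll
        model.n_iter = it
        if abs(delta) < tol:
            converged = True
            break
    model.converged = converged
    if not converged:
        logger.warning("EM did not converge in %d iterations (family=%s)", max_iter, true_family)
    return model


def posterior_error_probability(m: MixtureModel, score: np.ndarray | float) -> np.ndarray | float:
    """PEP(s) = π₀ f₀(s) / (π₀ f₀(s) + (1−π₀) f₁(s)); 1 where the density vanishes."""
    s = np.asarray(score, dtype=float)
    num = m.pi0 * m.false_density(s)
    den = num + (1 - m.pi0) * m.true_density(s)
    with np.errstate(invalid="ignore", divide="ignore"):
        pep = np.where(den > 0, num / np.maximum(den, _EPS), 1.0)
    pep = np.clip(pep, 0.0, 1.0)
    return float(pep) if np.isscalar(score) else pep


def fdr_from_pep(m: MixtureModel, hits: Sequence[SpectrumMatch]) -> FdrCurve:
    """Empirical-Bayes FDR: mean PEP of hits above each threshold, monotonized into q."""
    ordered = sort_hits(hits)
    scores = np.array([h.score for h in ordered])
    pep = np.asarray(posterior_error_probability(m, scores))
    fdr = np.cumsum(pep) / np.arange(1, len(pep) + 1)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    return FdrCurve(
        target_hits=ordered,
        thresholds=scores,
        n_target=np.arange(1, len(pep) + 1),
        n_decoy=np.zeros(len(pep), dtype=int),
        fdr=fdr,
        q=q,
        pit=m.pi0,
    )


def estimate_pit(m: MixtureModel) -> float:
    """PIT = π₀: the area under the scaled false-component curve.

    For normalized densities the area under π₀·f₀ over the score domain is
    exactly the mixture weight, so no numerical integration is needed.  The
    model must be fitted on the complete, unthresholded target hit list for
    this to estimate the percentage of incorrect targets.
    """
    return float(m.pi0)
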