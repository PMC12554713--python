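"""Multi-item gamma-Poisson shrinker (MGPS) for EBGM scores.

Model: each drug-event cell has observed count O ~ Poisson(lambda * E),
where E is the count expected under row-column independence of the full
drug x PT case-count matrix, and the relative reporting rate lambda follows
a two-component gamma mixture prior

    lambda ~ w * Gamma(alpha1, beta1) + (1 - w) * Gamma(alpha2, beta2)

(shape/rate parameterization). The marginal of O is then a two-component
negative-binomial mixture, so the five hyperparameters are fit by direct
maximum likelihood (bounded quasi-Newton on log/logit scale with a small
multi-start grid) rather than EM. Per cell the posterior on lambda is again
a gamma mixture; EBGM = exp(E[ln lambda | O]) and EBGM05 is the posterior
5th percentile.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import gamma as gamma_dist

from .faers_io import CaseData

_BOUND_LO, _BOUND_HI = 1e-4, 1e4
_W_EPS = 1e-4


@dataclass(frozen=True)
class MgpsPrior:
    """The five hyperparameters of the gamma-mixture prior."""

    w: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float

    def __post_init__(self):
        if not (0.0 < self.w < 1.0):
            raise ValueError(f"mixture weight w={self.w} must lie in (0, 1)")
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MgpsPrior":
        return cls(**json.loads(text))


#: Classic starting point for the optimizer.
DEFAULT_INIT = MgpsPrior(w=1.0 / 3.0, alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0)


@dataclass(frozen=True)
class EbgmScore:
    ebgm: float
    ebgm05: float


def _nb_logpmf(o: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    """log P(O=o) when lambda ~ Gamma(alpha, beta) and O|lambda ~ Poisson(lambda e).

    Negative binomial with size alpha and success probability beta/(beta+e).
    """
    return (
        gammaln(alpha + o) - gammaln(alpha) - gammaln(o + 1)
        + alpha * (math.log(beta) - np.log(beta + e))
        + o * (np.log(e) - np.log(beta + e))
    )


def _mixture_logpmf(prior: MgpsPrior, o: np.ndarray, e: np.ndarray) -> np.ndarray:
    comp = np.stack(
        [
            math.log(prior.w) + _nb_logpmf(o, prior.alpha1, prior.beta1, e),
            math.log1p(-prior.w) + _nb_logpmf(o, prior.alpha2, prior.beta2, e),
        ]
    )
    return logsumexp(comp, axis=0)


def marginal_loglik(
    prior: MgpsPrior, observed: Sequence[float], expected: Sequence[float]
) -> float:
    """Marginal log-likelihood of the cell counts under the mixture prior."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")
    ll = _mixture_logpmf(prior, o, e)
    if not np.all(np.isfinite(ll)):
        idx = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(
            f"non-finite log-likelihood at cell {idx} (O={o[idx]}, E={e[idx]})"
        )
    return float(ll.sum())


def _pack(prior: MgpsPrior) -> np.ndarray:
    return np.array(
        [
            math.log(prior.w / (1.0 - prior.w)),
            math.log(prior.alpha1),
            math.log(prior.beta1),
            math.log(prior.alpha2),
            math.log(prior.beta2),
        ]
    )


def _unpack(theta: np.ndarray) -> MgpsPrior:
    w = 1.0 / (1.0 + math.exp(-float(theta[0])))
    w = min(max(w, _W_EPS), 1.0 - _W_EPS)
    a1, b1, a2, b2 = (
        float(np.clip(math.exp(t), _BOUND_LO, _BOUND_HI)) for t in theta[1:]
    )
    return MgpsPrior(w=w, alpha1=a1, beta1=b1, alpha2=a2, beta2=b2)


_MULTISTART = (
    DEFAULT_INIT,
    MgpsPrior(w=0.5, alpha1=1.0, beta1=1.0, alpha2=2.0, beta2=2.0),
    MgpsPrior(w=0.2, alpha1=0.5, beta1=0.5, alpha2=5.0, beta2=5.0),
    MgpsPrior(w=0.8, alpha1=0.1, beta1=0.1, alpha2=10.0, beta2=10.0),
)


def fit_prior(
    observed: Sequence[float],
    expected: Sequence[float],
    init: MgpsPrior | None = None,
    *,
    multi_start: bool = True,
) -> tuple[MgpsPrior, dict]:
    """Maximum-likelihood fit of the five hyperparameters.

    Returns the best prior found plus an info dict (loglik, converged flag,
    number of starts). The returned log-likelihood never falls below the
    starting point's: the start itself is a candidate. With fewer than 50
    cells a warning flag is set (the empirical prior is then poorly
    determined).
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    init = init or DEFAULT_INIT
    info: dict = {"n_cells": int(o.size), "few_cells_warning": bool(o.size < 50)}

    def neg_ll(theta: np.ndarray) -> tuple[float, np.ndarray]:
        # analytic gradient on the (logit w, log alpha, log beta) scale
        p = _unpack(theta)
        l1 = math.log(p.w) + _nb_logpmf(o, p.alpha1, p.beta1, e)
        l2 = math.log1p(-p.w) + _nb_logpmf(o, p.alpha2, p.beta2, e)
        ll = np.logaddexp(l1, l2)
        if not np.all(np.isfinite(ll)):
            return np.inf, np.zeros(5)
        r1 = np.exp(l1 - ll)
        r2 = 1.0 - r1
        g_w = float(np.sum(r1 - p.w))  # d/d logit(w)
        grads = []
        for r, alpha, beta in ((r1, p.alpha1, p.beta1), (r2, p.alpha2, p.beta2)):
            da = digamma(alpha + o) - digamma(alpha) + math.log(beta) - np.log(
                beta + e
            )
            db = alpha / beta - (alpha + o) / (beta + e)
            grads.append(alpha * float(np.sum(r * da)))  # d/d log alpha
            grads.append(beta * float(np.sum(r * db)))   # d/d log beta
        grad = np.array([g_w, grads[0], grads[1], grads[2], grads[3]])
        return -float(ll.sum()), -grad

    lim = math.log(_BOUND_HI)
    wlim = math.log((1 - _W_EPS) / _W_EPS)
    bounds = [(-wlim, wlim)] + [(-lim, lim)] * 4
    starts = [init, *(_MULTISTART if multi_start else [])]
    candidates: list[tuple[float, MgpsPrior, bool]] = [
        (marginal_loglik(init, o, e), init, True)
    ]
    for start in starts:
        res = optimize.minimize(
            neg_ll, _pack(start), method="L-BFGS-B", jac=True, bounds=bounds,
            options={"maxiter": 500},
        )
        if np.isfinite(res.fun):
            candidates.append((-float(res.fun), _unpack(res.x), bool(res.success)))
    best_ll, best_prior, best_ok = max(candidates, key=lambda c: c[0])
    info.update(
        loglik=best_ll, init_loglik=candidates[0][0], converged=best_ok,
        n_starts=len(starts),
    )
    return best_prior, info


def posterior_weight(prior: MgpsPrior, o: float, e: float) -> float:
    """Posterior probability that lambda came from mixture component 1."""
    l1 = math.log(prior.w) + float(_nb_logpmf(np.array([o]), prior.alpha1,
                                              prior.beta1, np.array([e]))[0])
    l2 = math.log1p(-prior.w) + float(_nb_logpmf(np.array([o]), prior.alpha2,
                                                 prior.beta2, np.array([e]))[0])
    m = max(l1, l2)
    return math.exp(l1 - m) / (math.exp(l1 - m) + math.exp(l2 - m))


def _posterior_cdf(prior: MgpsPrior, o: float, e: float, q: float, x) -> float:
    return (
        q * gamma_dist.cdf(x, prior.alpha1 + o, scale=1.0 / (prior.beta1 + e))
        + (1 - q) * gamma_dist.cdf(x, prior.alpha2 + o, scale=1.0 / (prior.beta2 + e))
    )


def ebgm_score(o: float, e: float, prior: MgpsPrior) -> EbgmScore:
    """EBGM (posterior geometric mean of lambda) and EBGM05 for one cell.

    The posterior is Q * Gamma(alpha1+O, beta1+E) + (1-Q) * Gamma(alpha2+O,
    beta2+E) with Q from :func:`posterior_weight`; the 5th percentile is
    found by Brent root-finding on the monotone mixture CDF (the bracket is
    always valid: CDF(0)=0 and CDF -> 1).
    """
    if e <= 0:
        raise ValueError("expected count must be positive")
    q = posterior_weight(prior, o, e)
    mean_log = q * (digamma(prior.alpha1 + o) - math.log(prior.beta1 + e)) + (
        1 - q
    ) * (digamma(prior.alpha2 + o) - math.log(prior.beta2 + e))
    ebgm = math.exp(mean_log)
    # bracket the 5% quantile around the component quantiles
    q1 = gamma_dist.ppf(0.05, prior.alpha1 + o, scale=1.0 / (prior.beta1 + e))
    q2 = gamma_dist.ppf(0.05, prior.alpha2 + o, scale=1.0 / (prior.beta2 + e))
    lo = max(min(q1, q2) * 0.5, 1e-300)
    hi = max(q1, q2) * 2.0 + 1e-12
    while _posterior_cdf(prior, o, e, q, lo) > 0.05:
        lo *= 0.5
    while _posterior_cdf(prior, o, e, q, hi) < 0.05:
        hi *= 2.0
    ebgm05 = optimize.brentq(
        lambda x: _posterior_cdf(prior, o, e, q, x) - 0.05, lo, hi,
        xtol=1e-12, rtol=1e-12,
    )
    return EbgmScore(ebgm=float(ebgm), ebgm05=float(ebgm05))


def build_cell_counts(
    case_data: CaseData, universe: str = "all_ingested"
) -> pd.DataFrame:
    """Observed and expected counts for every drug x PT cell in the universe.

    One unit per case per (canonical PS drug, PT) pair. Expected counts come
    from the row/column margins of the full drug x PT case-count matrix, so
    the shrinkage borrows strength across the whole grid, not just the
    target pairs. Returns columns drug, pt, observed, expected (cells with a
    zero margin are excluded: their E is 0).
    """
    drugs = case_data.drugs
    if "canonical" not in drugs.columns:
        raise ValueError("case drugs lack a 'canonical' column")
    ps = drugs[(drugs["role_cod"] == "PS") & drugs["canonical"].notna()]
    ps = ps.drop_duplicates(["primaryid", "canonical"])
    if universe == "all_ingested":
        universe_ids = set(case_data.cases["primaryid"])
    elif universe == "study_drugs_only":
        universe_ids = set(ps["primaryid"])
    else:
        raise ValueError(f"unknown universe {universe!r}")
    n = len(universe_ids)
    if n == 0:
        raise ValueError("empty analysis universe")
    ps = ps[ps["primaryid"].isin(universe_ids)]
    reac = case_data.reactions
    reac = reac[reac["primaryid"].isin(universe_ids)].drop_duplicates(
        ["primaryid", "pt"]
    )
    n_drug = ps.groupby("canonical")["primaryid"].nunique()
    n_pt = reac.groupby("pt")["primaryid"].nunique()
    pairs = (
        ps.merge(reac, on="primaryid")
        .groupby(["canonical", "pt"])["primaryid"].nunique()
    )
    index = pd.MultiIndex.from_product(
        [sorted(n_drug.index), sorted(n_pt.index)], names=["drug", "pt"]
    )
    observed = pairs.reindex(index, fill_value=0).astype(float)
    expected = pd.Series(
        np.outer(n_drug.reindex(sorted(n_drug.index)),
                 n_pt.reindex(sorted(n_pt.index))).ravel() / n,
        index=index,
    )
    out = pd.DataFrame({"observed": observed, "expected": expected}).reset_index()
    return out[out["expected"] > 0].reset_index(drop=True)
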