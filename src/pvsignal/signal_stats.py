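"""2x2 contingency tables and frequentist disproportionality statistics.

For one drug-event pair the universe of deduplicated cases is cross-
classified as

    a  target drug & target event        b  target drug, other events
    c  other drugs, target event         d  other drugs, other events

and screened with the four conventional methods: the reporting odds ratio
(ROR) with a log-scale Wald 95% CI, the proportional reporting ratio (PRR)
with a Yates-corrected chi-square companion, the Bayesian-shrinkage
information component (IC, with its IC025 lower credibility bound), and the
empirical-Bayes geometric mean (EBGM, computed in :mod:`pvsignal.mgps`). A
pair is flagged when any method exceeds its threshold and the case count
passes the minimum-count gate; a two-sided Fisher exact p-value with
Bonferroni adjustment accompanies every pair.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.special import gammaln
from scipy.special import logsumexp

from .faers_io import CaseData
from .vocab import TargetEventSet

Z975 = 1.959963984540054  # standard normal 97.5th percentile


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name}={v} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """E = (a+b)(a+c)/n, the expected count under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n if self.n else math.nan


def build_contingency(
    case_data: CaseData,
    drug: str,
    events: TargetEventSet,
    universe: str = "all_ingested",
) -> ContingencyTable:
    """Cross-classify cases for one drug against one target event set.

    A case falls in the drug row iff the canonical drug is among its
    primary-suspect drugs (the ``canonical`` column added by normalization;
    PS entries only), and in the event column iff any of its reaction PTs
    belongs to ``events``. Each case counts once.

    ``universe`` selects the comparator background: ``all_ingested`` (every
    loaded case) or ``study_drugs_only`` (cases with at least one normalized
    PS study drug).
    """
    drugs = case_data.drugs
    if "canonical" not in drugs.columns:
        raise ValueError("case drugs lack a 'canonical' column; run "
                         "pipeline.normalize_case_drugs first")
    ps = drugs[(drugs["role_cod"] == "PS") & drugs["canonical"].notna()]
    if universe == "all_ingested":
        universe_ids = set(case_data.cases["primaryid"])
    elif universe == "study_drugs_only":
        universe_ids = set(ps["primaryid"])
    else:
        raise ValueError(f"unknown universe {universe!r}")
    if not universe_ids:
        raise ValueError("empty analysis universe")
    drug_ids = set(ps.loc[ps["canonical"] == drug, "primaryid"]) & universe_ids
    reac = case_data.reactions
    event_ids = set(
        reac.loc[reac["pt"].isin(events.pts), "primaryid"]
    ) & universe_ids
    a = len(drug_ids & event_ids)
    b = len(drug_ids) - a
    c = len(event_ids) - a
    d = len(universe_ids) - a - b - c
    return ContingencyTable(a, b, c, d)


def ror_stats(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI.

    If any cell is zero the Haldane-Anscombe +0.5 correction is applied to
    all four cells for this computation.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-Z975 * se), ror * math.exp(Z975 * se)


def prr_stats(t: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and its Yates-corrected chi-square.

    Undefined (NaN, NaN) when a margin is zero; such pairs are never called
    positive.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return math.nan, math.nan
    prr = math.inf if c == 0 else (a / (a + b)) / (c / (c + d))
    diff = abs(a * d - b * c)
    if diff <= n / 2:
        chi2 = 0.0
    else:
        chi2 = n * (diff - n / 2) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, chi2


def ic_stats(t: ContingencyTable) -> tuple[float, float]:
    """Shrinkage information component IC = log2((a+.5)/(E+.5)) and its
    IC025 lower credibility bound (Noren's approximation)."""
    a = t.a
    e = (t.a + t.b) * (t.a + t.c) / t.n if t.n else 0.0
    ic = math.log2((a + 0.5) / (e + 0.5))
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    return ic, ic025


def _log_hypergeom_pmf(k: np.ndarray, n: int, K: int, N: int) -> np.ndarray:
    # P(X=k) drawing N from population n containing K successes
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(n - K + 1) - gammaln(N - k + 1) - gammaln(n - K - N + k + 1)
        - (gammaln(n + 1) - gammaln(N + 1) - gammaln(n - N + 1))
    )


def p_value(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p (method of small p-values).

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one, with a tiny relative
    tolerance for floating-point ties.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    r, cc = a + b, a + c
    if n == 0 or r == 0 or cc == 0 or r == n or cc == n:
        return 1.0
    kmin, kmax = max(0, r + cc - n), min(r, cc)
    k = np.arange(kmin, kmax + 1)
    logpmf = _log_hypergeom_pmf(k, n, cc, r)
    log_obs = logpmf[a - kmin]
    mask = logpmf <= log_obs + 1e-8
    return float(min(1.0, math.exp(logsumexp(logpmf[mask]))))


def bonferroni(p_list: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment p_adj = min(1, m * p); order-preserving."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < len(p_list):
        raise ValueError("family size m smaller than the number of p-values")
    return [min(1.0, m * p) if not math.isnan(p) else math.nan for p in p_list]


@dataclass(frozen=True)
class Thresholds:
    """Positivity thresholds for the four screening methods."""

    min_cases: int = 3
    ror_lo_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0
    alpha: float = 0.05
    bonferroni_m: int | str = "auto"
    rule: str = "any"

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "Thresholds":
        if path is None:
            source = resources.files("pvsignal.data").joinpath(
                "thresholds.yaml"
            ).read_text()
        else:
            source = Path(path).read_text()
        raw = yaml.safe_load(source)
        return cls(**{k: raw[k] for k in raw if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class SignalVerdict:
    ror_pos: bool
    prr_pos: bool
    ic_pos: bool
    ebgm_pos: bool
    min_case_ok: bool
    overall: bool


@dataclass
class FrequentistStats:
    """All four statistics with interval estimates for one pair."""

    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float = math.nan
    ebgm05: float = math.nan
    p_raw: float = math.nan
    p_adj: float = math.nan


def _pos(value: float, threshold: float, strict: bool) -> bool:
    if math.isnan(value):
        return False  # undefined methods count as negative
    return value > threshold if strict else value >= threshold


def classify(
    stats: FrequentistStats,
    thresholds: Thresholds = Thresholds(),
) -> SignalVerdict:
    """Apply the positivity rule: minimum case count AND (any / all of the
    four method criteria)."""
    ror_pos = _pos(stats.ror_lo, thresholds.ror_lo_gt, strict=True)
    prr_pos = _pos(stats.prr, thresholds.prr_ge, strict=False) and _pos(
        stats.chi2, thresholds.chi2_ge, strict=False
    )
    ic_pos = _pos(stats.ic025, thresholds.ic025_gt, strict=True)
    ebgm_pos = _pos(stats.ebgm05, thresholds.ebgm05_gt, strict=True)
    min_case_ok = stats.a >= thresholds.min_cases
    flags = (ror_pos, prr_pos, ic_pos, ebgm_pos)
    combined = any(flags) if thresholds.rule == "any" else all(flags)
    return SignalVerdict(
        ror_pos=ror_pos,
        prr_pos=prr_pos,
        ic_pos=ic_pos,
        ebgm_pos=ebgm_pos,
        min_case_ok=min_case_ok,
        overall=bool(min_case_ok and combined),
    )


def compute_stats(t: ContingencyTable) -> FrequentistStats:
    """ROR, PRR, IC and Fisher p for one table (EBGM filled in by the
    caller from the fitted MGPS prior)."""
    ror, lo, hi = ror_stats(t)
    prr, chi2 = prr_stats(t)
    ic, ic025 = ic_stats(t)
    return FrequentistStats(
        a=t.a, ror=ror, ror_lo=lo, ror_hi=hi, prr=prr, chi2=chi2,
        ic=ic, ic025=ic025, p_raw=p_value(t),
    )
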