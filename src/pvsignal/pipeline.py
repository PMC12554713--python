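"""End-to-end orchestration: descriptives, signal tables, SOC aggregation.

The analysis flow mirrors standard spontaneous-report practice: ingest and
deduplicate the quarterly tables, normalize primary-suspect drug names
against the study vocabulary, then for each study drug build the 2x2 table
against the target event set, compute ROR/PRR/IC with a Fisher exact p
(Bonferroni-adjusted over the drug hypotheses), fit the MGPS prior across
the full drug x PT grid of the same analysis universe, score EBGM/EBGM05,
and apply the any-of-four positivity rule. Subgroup analyses re-run the
full statistic set inside each sex stratum (F/M) and age stratum (younger
< 60 years / older >= 60), excluding cases with the value unknown. All
outputs carry the config hash, universe, thresholds and the fitted prior.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import mgps, signal_stats, vocab
from .faers_io import CaseData
from .signal_stats import Thresholds
from .vocab import DrugVocabulary, EventHierarchy, TargetEventSet

AGE_CUTOFF_YEARS = 60.0

#: Descriptive age bins (display bins; the analysis cutoff is 60).
AGE_DISPLAY_BINS = ("<18", "18-64.9", "65-85", ">85", "Unknown")
OUTCOME_ORDER = ("CA", "DE", "DS", "HO", "LT", "OT", "RI", "Unknown")


@dataclass
class RunConfig:
    """Validated run configuration for one analysis."""

    data_dir: str | None = None
    vocab_path: str | None = None
    hierarchy_path: str | None = None
    target_events_path: str | None = None
    target_event_set: str = "osteopenia"
    universe: str = "all_ingested"
    thresholds: Thresholds = field(default_factory=Thresholds)
    subgroup_drugs: str = "positive"  # positive | all
    age_cutoff: float = AGE_CUTOFF_YEARS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = raw.pop("thresholds", None)
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in cls.__dataclass_fields__})
        if thr:
            cfg.thresholds = Thresholds(**thr)
        for attr in ("data_dir", "vocab_path", "hierarchy_path",
                     "target_events_path"):
            value = getattr(cfg, attr)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{attr}: {value} does not exist")
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def load_vocab(self) -> DrugVocabulary:
        return DrugVocabulary.from_yaml(self.vocab_path)

    def load_hierarchy(self) -> EventHierarchy:
        return EventHierarchy.from_csv(self.hierarchy_path)

    def load_target_events(self) -> TargetEventSet:
        sets = vocab.load_target_events(self.target_events_path)
        if self.target_event_set not in sets:
            raise KeyError(f"unknown target event set {self.target_event_set!r}")
        return sets[self.target_event_set]


def normalize_case_drugs(
    case_data: CaseData, drug_vocab: DrugVocabulary
) -> CaseData:
    """Attach a ``canonical`` column to the drug table; out-of-vocabulary
    names map to NA and are counted in meta."""
    drugs = case_data.drugs.copy()
    drugs["canonical"] = drug_vocab.normalize_series(drugs["drugname"])
    meta = dict(case_data.meta)
    meta["drug_rows_unmatched"] = int(drugs["canonical"].isna().sum())
    return CaseData(
        cases=case_data.cases, drugs=drugs, reactions=case_data.reactions,
        outcomes=case_data.outcomes, meta=meta,
    )


def _case_attrs(case_data: CaseData, drug: str) -> pd.DataFrame:
    drugs = case_data.drugs
    ps_ids = set(
        drugs.loc[
            (drugs["role_cod"] == "PS") & (drugs["canonical"] == drug),
            "primaryid",
        ]
    )
    return case_data.cases[case_data.cases["primaryid"].isin(ps_ids)]


def descriptives(case_data: CaseData, drugs: Iterable[str]) -> pd.DataFrame:
    """Per-drug counts/percentages by sex, display age bin and outcome code.

    A case with several outcome codes contributes to each code's row, so the
    outcome dimension may exceed 100%; sex and age partition each drug's
    total exactly. Returns a tidy frame (drug, dimension, category, count,
    pct).
    """
    out_by_case = case_data.outcomes.groupby("primaryid")["outc_cod"].agg(set)
    rows = []
    for drug in drugs:
        sub = _case_attrs(case_data, drug)
        total = len(sub)
        rows.append({"drug": drug, "dimension": "total", "category": "total",
                     "count": total, "pct": 100.0})
        denom = max(total, 1)
        sex_counts = {
            "Female": int((sub["sex"] == "F").sum()),
            "Male": int((sub["sex"] == "M").sum()),
        }
        sex_counts["Unknown"] = total - sum(sex_counts.values())
        for cat, cnt in sex_counts.items():
            rows.append({"drug": drug, "dimension": "sex", "category": cat,
                         "count": cnt, "pct": round(100.0 * cnt / denom, 1)})
        age = pd.to_numeric(sub["age_years"], errors="coerce")
        age_counts = {
            "<18": int((age < 18).sum()),
            "18-64.9": int(((age >= 18) & (age < 65)).sum()),
            "65-85": int(((age >= 65) & (age <= 85)).sum()),
            ">85": int((age > 85).sum()),
        }
        age_counts["Unknown"] = total - sum(age_counts.values())
        for cat, cnt in age_counts.items():
            rows.append({"drug": drug, "dimension": "age", "category": cat,
                         "count": cnt, "pct": round(100.0 * cnt / denom, 1)})
        outcome_sets = [out_by_case.get(pid, set()) for pid in sub["primaryid"]]
        for code in OUTCOME_ORDER[:-1]:
            cnt = sum(code in s for s in outcome_sets)
            rows.append({"drug": drug, "dimension": "outcome", "category": code,
                         "count": cnt, "pct": round(100.0 * cnt / denom, 1)})
        unknown = sum(not s for s in outcome_sets)
        rows.append({"drug": drug, "dimension": "outcome", "category": "Unknown",
                     "count": unknown, "pct": round(100.0 * unknown / denom, 1)})
    return pd.DataFrame(rows)


def _signal_row(
    case_data: CaseData,
    drug: str,
    events: TargetEventSet,
    cfg: RunConfig,
    prior: mgps.MgpsPrior | None,
) -> dict:
    table = signal_stats.build_contingency(case_data, drug, events,
                                           universe=cfg.universe)
    stats = signal_stats.compute_stats(table)
    if prior is not None and table.n > 0 and table.expected_a > 0:
        score = mgps.ebgm_score(table.a, table.expected_a, prior)
        stats.ebgm, stats.ebgm05 = score.ebgm, score.ebgm05
    defined = table.a + table.b > 0
    row = {
        "drug": drug, "N": table.a,
        "a": table.a, "b": table.b, "c": table.c, "d": table.d,
        "ror": stats.ror, "ror_lo": stats.ror_lo, "ror_hi": stats.ror_hi,
        "prr": stats.prr, "chi2": stats.chi2,
        "ebgm": stats.ebgm, "ebgm05": stats.ebgm05,
        "ic": stats.ic, "ic025": stats.ic025,
        "p_raw": stats.p_raw, "defined": defined,
    }
    row["_stats"] = stats
    return row


def _finalize_rows(rows: list[dict], thresholds: Thresholds, m: int) -> pd.DataFrame:
    p_adj = signal_stats.bonferroni([r["_stats"].p_raw for r in rows], m)
    for r, padj in zip(rows, p_adj):
        stats = r.pop("_stats")
        stats.p_adj = padj
        verdict = signal_stats.classify(stats, thresholds)
        r.update(
            p_adj=padj,
            ror_pos=verdict.ror_pos, prr_pos=verdict.prr_pos,
            ic_pos=verdict.ic_pos, ebgm_pos=verdict.ebgm_pos,
            min_case_ok=verdict.min_case_ok, positive=verdict.overall,
        )
    return pd.DataFrame(rows)


def _bonferroni_m(cfg: RunConfig, n_hypotheses: int) -> int:
    m = cfg.thresholds.bonferroni_m
    return n_hypotheses if m in (None, "auto") else int(m)


def run_overall(
    case_data: CaseData, cfg: RunConfig, drugs: Iterable[str] | None = None
) -> tuple[pd.DataFrame, mgps.MgpsPrior, dict]:
    """One signal row per study drug against the target event set.

    The MGPS prior is fit once on the full drug x PT grid of the analysis
    universe and reused for every drug's EBGM. Deterministic given config
    and input data.
    """
    events = cfg.load_target_events()
    if drugs is None:
        drugs = cfg.load_vocab().canonicals
    cells = mgps.build_cell_counts(case_data, universe=cfg.universe)
    if len(cells):
        prior, fit_info = mgps.fit_prior(cells["observed"], cells["expected"])
    else:  # no drug-PT pairs at all: fall back to the diffuse default prior
        prior, fit_info = mgps.DEFAULT_INIT, {"n_cells": 0, "converged": False}
    rows = [_signal_row(case_data, d, events, cfg, prior) for d in drugs]
    m = _bonferroni_m(cfg, len(rows))
    frame = _finalize_rows(rows, cfg.thresholds, m)
    return frame, prior, {"mgps_fit": fit_info, "bonferroni_m": m}


def stratum_masks(case_data: CaseData, age_cutoff: float) -> dict[str, pd.Series]:
    """Sex and age strata; cases with the value unknown fall in neither
    stratum of that dimension (but remain in the overall analysis)."""
    cases = case_data.cases
    age = pd.to_numeric(cases["age_years"], errors="coerce")
    return {
        "Female": cases["sex"] == "F",
        "Male": cases["sex"] == "M",
        "Younger": age.notna() & (age < age_cutoff),
        "Older": age.notna() & (age >= age_cutoff),
    }


def run_subgroups(
    case_data: CaseData,
    cfg: RunConfig,
    drugs: Iterable[str],
) -> pd.DataFrame:
    """Re-run the full statistic set within each sex/age stratum.

    Both the 2x2 tables and the MGPS expected counts are stratum-internal.
    Strata where the drug has no target-event case (a = 0) keep their row
    with undefined statistics, mirroring how report tables print dashes.
    """
    drugs = list(drugs)
    events = cfg.load_target_events()
    frames = []
    for stratum, mask in stratum_masks(case_data, cfg.age_cutoff).items():
        sub = case_data.subset(case_data.cases.loc[mask, "primaryid"])
        if sub.n_cases == 0:
            rows = [
                {"drug": d, "stratum": stratum, "N": 0, "defined": False}
                for d in drugs
            ]
            frames.append(pd.DataFrame(rows))
            continue
        cells = mgps.build_cell_counts(sub, universe=cfg.universe)
        if len(cells):
            prior, _ = mgps.fit_prior(cells["observed"], cells["expected"])
        else:
            prior = mgps.DEFAULT_INIT
        rows = [_signal_row(sub, d, events, cfg, prior) for d in drugs]
        m = _bonferroni_m(cfg, len(rows))
        frame = _finalize_rows(rows, cfg.thresholds, m)
        frame.insert(1, "stratum", stratum)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    # undefined statistics for empty drug-stratum combinations stay NaN
    return out.sort_values(["drug", "stratum"], kind="mergesort").reset_index(
        drop=True
    )


def soc_summary(
    case_data: CaseData,
    hierarchy: EventHierarchy,
    drugs: Iterable[str],
) -> pd.DataFrame:
    """Per drug, reaction-PT occurrence counts aggregated by SOC, sorted
    descending with the UNMAPPED sentinel last."""
    rows = []
    for drug in drugs:
        sub = _case_attrs(case_data, drug)
        reac = case_data.reactions[
            case_data.reactions["primaryid"].isin(set(sub["primaryid"]))
        ]
        soc = hierarchy.soc_series(reac["pt"])
        counts = soc.value_counts()
        ordered = counts.drop(vocab.UNMAPPED, errors="ignore")
        for name, cnt in ordered.items():
            rows.append({"drug": drug, "soc": name, "count": int(cnt)})
        if vocab.UNMAPPED in counts.index:
            rows.append({"drug": drug, "soc": vocab.UNMAPPED,
                         "count": int(counts[vocab.UNMAPPED])})
    return pd.DataFrame(rows, columns=["drug", "soc", "count"])


def analyze(
    case_data: CaseData,
    cfg: RunConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Full analysis: normalize, descriptives, overall + subgroup signal
    tables, SOC summary. Optionally writes the CSV/JSON output set."""
    drug_vocab = cfg.load_vocab()
    hierarchy = cfg.load_hierarchy()
    if "canonical" not in case_data.drugs.columns:
        case_data = normalize_case_drugs(case_data, drug_vocab)
    drugs = list(drug_vocab.canonicals)
    overall, prior, info = run_overall(case_data, cfg, drugs)
    if cfg.subgroup_drugs == "all":
        sub_drugs = drugs
    else:
        sub_drugs = overall.loc[overall["positive"], "drug"].tolist()
    subgroup = (
        run_subgroups(case_data, cfg, sub_drugs) if sub_drugs else pd.DataFrame(
            columns=["drug", "stratum", "N"]
        )
    )
    desc = descriptives(case_data, drugs)
    soc = soc_summary(case_data, hierarchy, drugs)
    report = {
        "config_hash": cfg.config_hash(),
        "universe": cfg.universe,
        "thresholds": asdict(cfg.thresholds),
        "bonferroni_m": info["bonferroni_m"],
        "mgps_prior": asdict(prior),
        "mgps_fit": {k: v for k, v in info["mgps_fit"].items()},
        "n_cases": case_data.n_cases,
        "meta": {k: v for k, v in case_data.meta.items()
                 if isinstance(v, (int, float, str))},
    }
    results = {
        "descriptives": desc,
        "signals_overall": overall,
        "signals_subgroup": subgroup,
        "soc_summary": soc,
        "run_report": report,
    }
    if out_dir is not None:
        write_outputs(results, out_dir)
    return results


def write_outputs(results: Mapping, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("descriptives", "signals_overall", "signals_subgroup",
                 "soc_summary"):
        results[name].to_csv(out_dir / f"{name}.csv", index=False,
                             float_format="%.10g")
    (out_dir / "run_report.json").write_text(
        json.dumps(results["run_report"], sort_keys=True, indent=2,
                   default=str) + "\n"
    )


def family_wise_positive(overall: pd.DataFrame, alpha: float = 0.05) -> bool:
    """True if any drug's Bonferroni-adjusted p falls below alpha."""
    p = pd.to_numeric(overall["p_adj"], errors="coerce")
    return bool((p < alpha).any())
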