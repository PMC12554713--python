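"""Seeded generator of FAERS-format datasets with known ground truth.

Each simulated case draws sex, age and outcome from marginals calibrated to
the descriptive distributions of real antiepileptic-drug reports (about 50%
female, 33% male; ~38% missing age; outcome mix dominated by
hospitalization and "other serious"), one primary-suspect study drug from
marginals proportional to the drugs' real report volumes, 0-2 concomitant
non-study drugs, and 1-5 reaction PTs. PT probabilities are shared across
drugs except where a signal multiplier is injected: for a (drug, PT) pair
with multiplier m (optionally restricted to a sex or age stratum) the PT's
selection weight is scaled by m and the per-slot distribution renormalized,
giving every disproportionality statistic a known truth.

A configurable fraction of cases additionally emits an earlier-dated
duplicate report version (same CASEID, distinct PRIMARYID) whose child rows
become orphans after deduplication — exercising the ingest contract.

Identical config + seed produces byte-identical files.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .vocab import DrugVocabulary

#: Study-drug report volumes used for the default marginals (proportions of
#: real per-drug report counts for the 12 antiepileptic drugs, 2005Q1-2025Q1).
DEFAULT_DRUG_COUNTS: dict[str, int] = {
    "CARBAMAZEPINE": 15199,
    "ETHOSUXIMIDE": 478,
    "PHENYTOIN": 7844,
    "VALPROIC ACID": 8149,
    "GABAPENTIN": 54126,
    "LAMOTRIGINE": 33937,
    "LEVETIRACETAM": 47801,
    "OXCARBAZEPINE": 6159,
    "TOPIRAMATE": 17567,
    "ZONISAMIDE": 2451,
    "ESLICARBAZEPINE": 59,
    "LACOSAMIDE": 13617,
}

#: Per-slot PT selection weights (normalized at validation). OSTEOPENIA's
#: weight of 3e-4, with 1-5 PT slots per case, yields a case-level
#: osteopenia rate of ~0.09%, matching the observed 181 / 206,680 reports.
DEFAULT_EVENT_MARGINALS: dict[str, float] = {
    "OSTEOPENIA": 0.0003,
    "SEIZURE": 0.09, "DIZZINESS": 0.06, "SOMNOLENCE": 0.05, "HEADACHE": 0.05,
    "TREMOR": 0.03, "ATAXIA": 0.02, "MEMORY IMPAIRMENT": 0.02,
    "FATIGUE": 0.06, "ASTHENIA": 0.03, "MALAISE": 0.03,
    "DRUG INEFFECTIVE": 0.08, "PYREXIA": 0.02, "GAIT DISTURBANCE": 0.02,
    "NAUSEA": 0.05, "VOMITING": 0.03, "DIARRHOEA": 0.02, "CONSTIPATION": 0.015,
    "RASH": 0.04, "PRURITUS": 0.015, "ALOPECIA": 0.01,
    "STEVENS-JOHNSON SYNDROME": 0.005,
    "DEPRESSION": 0.025, "CONFUSIONAL STATE": 0.02, "AGGRESSION": 0.01,
    "SUICIDAL IDEATION": 0.015, "INSOMNIA": 0.02,
    "ANAEMIA": 0.01, "THROMBOCYTOPENIA": 0.01,
    "HYPONATRAEMIA": 0.015, "DECREASED APPETITE": 0.01,
    "WEIGHT INCREASED": 0.02, "BLOOD SODIUM DECREASED": 0.005,
    "BONE DENSITY DECREASED": 0.0005,
    "HEPATOTOXICITY": 0.005, "HEPATIC FUNCTION ABNORMAL": 0.005,
    "ACUTE KIDNEY INJURY": 0.01, "FALL": 0.02,
    "VISION BLURRED": 0.02, "DIPLOPIA": 0.01,
}

#: Non-study concomitant drug pool (normalize to None in the vocabulary).
OTHER_DRUG_POOL = (
    "IBUPROFEN", "ASPIRIN", "PARACETAMOL", "OMEPRAZOLE",
    "LISINOPRIL", "METFORMIN", "ATORVASTATIN", "SERTRALINE",
)

#: Age-bin edges (years) and default known-age mixture weights, matching the
#: descriptive bins <18 / 18-64.9 / 65-85 / >85.
AGE_BINS = ((0.5, 17.9), (18.0, 64.9), (65.0, 85.0), (85.1, 99.9))
DEFAULT_AGE_BIN_PROBS = (0.1578, 0.6196, 0.1998, 0.0228)

DEFAULT_OUTCOME_PROBS: dict[str, float] = {
    "CA": 0.022, "DE": 0.066, "DS": 0.016, "HO": 0.198,
    "LT": 0.038, "OT": 0.320, "RI": 0.001,
}  # remainder: no outcome row ("unknown" in descriptives)


@dataclass(frozen=True)
class Multiplier:
    """Relative reporting-rate multiplier for one (drug, PT) pair, optionally
    restricted to a sex ("F"/"M") or age group ("younger"/"older")."""

    drug: str
    pt: str
    value: float
    sex: str | None = None
    age_group: str | None = None


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification for one simulated FAERS dataset."""

    n_reports: int
    seed: int
    drug_marginals: Mapping[str, float] | None = None
    event_marginals: Mapping[str, float] | None = None
    signal_multipliers: tuple[Multiplier, ...] = ()
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.50, "M": 0.33, "UNK": 0.17}
    )
    age_bin_probs: tuple[float, ...] = DEFAULT_AGE_BIN_PROBS
    age_missing_rate: float = 0.382
    outcome_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS)
    )
    duplicate_rate: float = 0.1
    brand_name_rate: float = 0.2
    role_mix: Mapping[str, float] = field(
        default_factory=lambda: {"SS": 0.3, "C": 0.5, "I": 0.2}
    )
    max_extra_drugs: int = 2
    max_pts: int = 5

    def resolved_drug_marginals(self) -> dict[str, float]:
        raw = dict(self.drug_marginals) if self.drug_marginals is not None else {
            k: v / sum(DEFAULT_DRUG_COUNTS.values())
            for k, v in DEFAULT_DRUG_COUNTS.items()
        }
        total = sum(raw.values())
        if total > 1 + 1e-9 or any(v < 0 for v in raw.values()):
            raise ValueError("drug marginals must be non-negative and sum to <= 1")
        rem = 1.0 - total
        if rem > 1e-9:  # remainder to a background non-study PS drug pool
            per = rem / len(OTHER_DRUG_POOL)
            for name in OTHER_DRUG_POOL:
                raw[name] = raw.get(name, 0.0) + per
        total = sum(raw.values())
        return {k: v / total for k, v in raw.items()}

    def resolved_event_marginals(self) -> dict[str, float]:
        raw = dict(self.event_marginals) if self.event_marginals is not None else dict(
            DEFAULT_EVENT_MARGINALS
        )
        total = sum(raw.values())
        if total <= 0 or total > 1 + 1e-9 or any(v < 0 for v in raw.values()):
            raise ValueError("event marginals must be non-negative and sum to <= 1")
        return {k: v / total for k, v in raw.items()}

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must lie in [0, 1)")
        if abs(sum(self.sex_probs.values()) - 1) > 1e-9:
            raise ValueError("sex probabilities must sum to 1")
        if abs(sum(self.age_bin_probs) - 1) > 1e-9:
            raise ValueError("age bin probabilities must sum to 1")
        if sum(self.outcome_probs.values()) > 1 + 1e-9:
            raise ValueError("outcome probabilities must sum to <= 1")
        self.resolved_drug_marginals()
        events = self.resolved_event_marginals()
        for m in self.signal_multipliers:
            if m.value < 0:
                raise ValueError("signal multipliers must be >= 0")
            if m.pt not in events:
                raise ValueError(f"multiplier PT {m.pt!r} not in event marginals")
            if m.sex not in (None, "F", "M"):
                raise ValueError(f"multiplier sex {m.sex!r} invalid")
            if m.age_group not in (None, "younger", "older"):
                raise ValueError(f"multiplier age_group {m.age_group!r} invalid")


@dataclass
class GroundTruth:
    """The exact generative truth serialized next to every dataset."""

    seed: int
    n_base_cases: int
    n_duplicates: int
    drug_marginals: dict[str, float]
    event_marginals: dict[str, float]
    multipliers: list[dict]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)


@dataclass
class SyntheticDataset:
    frames: dict[str, pd.DataFrame]  # demo / drug / reac / outc
    ground_truth: GroundTruth


def _younger_prob_given_known(config: SyntheticConfig) -> float:
    """P(age < 60 | age known) implied by the bin mixture (uniform within bin)."""
    p = 0.0
    for (lo, hi), w in zip(AGE_BINS, config.age_bin_probs):
        if hi < 60:
            p += w
        elif lo < 60:
            p += w * (60 - lo) / (hi - lo)
    return p


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; deterministic in config + seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    drug_marg = config.resolved_drug_marginals()
    drug_names = np.array(sorted(drug_marg))
    drug_p = np.array([drug_marg[d] for d in drug_names])
    event_marg = config.resolved_event_marginals()
    pt_names = np.array(sorted(event_marg))
    pt_p = np.array([event_marg[p] for p in pt_names])
    pt_index = {p: i for i, p in enumerate(pt_names)}

    caseid = 10_000_000 + np.arange(n, dtype=np.int64)
    primaryid = caseid * 10 + 1

    sex_labels = np.array(["F", "M", "UNK"])
    sex = sex_labels[rng.choice(
        3, n, p=[config.sex_probs[s] for s in sex_labels]
    )]

    age_known = rng.random(n) >= config.age_missing_rate
    bin_idx = rng.choice(len(AGE_BINS), n, p=np.asarray(config.age_bin_probs))
    lo = np.array([b[0] for b in AGE_BINS])[bin_idx]
    hi = np.array([b[1] for b in AGE_BINS])[bin_idx]
    age_years = np.round(lo + rng.random(n) * (hi - lo), 1)

    start = np.datetime64("2005-01-01")
    dates = start + rng.integers(0, 7390, n).astype("timedelta64[D]")

    ps_idx = rng.choice(len(drug_names), n, p=drug_p)
    ps_canonical = drug_names[ps_idx]

    # some PS entries use brand/salt spellings to exercise normalization
    vocab = DrugVocabulary.from_yaml()
    synonyms = {
        canon: sorted(s for s, c in vocab.lookup.items() if c == canon and s != canon)
        for canon in vocab.canonicals
    }
    ps_name = ps_canonical.astype(object).copy()
    use_brand = rng.random(n) < config.brand_name_rate
    brand_pick = rng.random(n)
    for i in np.flatnonzero(use_brand):
        alts = synonyms.get(ps_canonical[i], [])
        if alts:
            ps_name[i] = alts[int(brand_pick[i] * len(alts))]

    # reaction PTs: per-slot categorical, weights modulated by multipliers
    n_pts = rng.integers(1, config.max_pts + 1, n)
    entries = config.signal_multipliers
    applies = np.zeros((len(entries), n), dtype=bool)
    for j, ent in enumerate(entries):
        m = ps_canonical == ent.drug
        if ent.sex is not None:
            m &= sex == ent.sex
        if ent.age_group == "younger":
            m &= age_known & (age_years < 60)
        elif ent.age_group == "older":
            m &= age_known & (age_years >= 60)
        applies[j] = m
    if entries:
        pattern = np.zeros(n, dtype=np.int64)
        for j in range(len(entries)):
            pattern |= applies[j].astype(np.int64) << j
    else:
        pattern = np.zeros(n, dtype=np.int64)
    pt_rows_pid: list[np.ndarray] = []
    pt_rows_case: list[np.ndarray] = []
    pt_rows_pt: list[np.ndarray] = []
    for code in np.unique(pattern):
        weights = pt_p.copy()
        for j, ent in enumerate(entries):
            if code >> j & 1:
                weights[pt_index[ent.pt]] *= ent.value
        weights = weights / weights.sum()
        members = np.flatnonzero(pattern == code)
        counts = n_pts[members]
        draws = rng.choice(len(pt_names), size=int(counts.sum()), p=weights)
        pt_rows_pid.append(np.repeat(primaryid[members], counts))
        pt_rows_case.append(np.repeat(caseid[members], counts))
        pt_rows_pt.append(pt_names[draws])
    reac = pd.DataFrame(
        {
            "primaryid": np.concatenate(pt_rows_pid),
            "caseid": np.concatenate(pt_rows_case),
            "pt": np.concatenate(pt_rows_pt),
        }
    ).drop_duplicates(["primaryid", "pt"])

    # drug rows: PS first, then 0-2 concomitant non-study drugs
    n_extra = rng.integers(0, config.max_extra_drugs + 1, n)
    extra_pid = np.repeat(primaryid, n_extra)
    extra_case = np.repeat(caseid, n_extra)
    extra_seq = np.concatenate([np.arange(2, 2 + k) for k in n_extra]) if n_extra.sum() else np.array([], dtype=int)
    pool = np.array(OTHER_DRUG_POOL)
    extra_name = pool[rng.choice(len(pool), int(n_extra.sum()))]
    roles = np.array(sorted(config.role_mix))
    role_p = np.array([config.role_mix[r] for r in roles])
    role_p = role_p / role_p.sum()
    extra_role = roles[rng.choice(len(roles), int(n_extra.sum()), p=role_p)]
    drug = pd.DataFrame(
        {
            "primaryid": np.concatenate([primaryid, extra_pid]),
            "caseid": np.concatenate([caseid, extra_case]),
            "drug_seq": np.concatenate([np.ones(n, dtype=int), extra_seq]),
            "role_cod": np.concatenate([np.full(n, "PS"), extra_role]),
            "drugname": np.concatenate([ps_name, extra_name]),
            "prod_ai": np.concatenate([ps_canonical, extra_name]),
        }
    )

    # outcomes: at most one code per case; remainder emit no OUTC row
    out_codes = np.array(sorted(config.outcome_probs))
    out_p = np.array([config.outcome_probs[c] for c in out_codes])
    p_none = 1.0 - out_p.sum()
    draw = rng.choice(len(out_codes) + 1, n, p=np.append(out_p, p_none))
    has_out = draw < len(out_codes)
    outc = pd.DataFrame(
        {
            "primaryid": primaryid[has_out],
            "caseid": caseid[has_out],
            "outc_cod": out_codes[draw[has_out]],
        }
    )

    demo = pd.DataFrame(
        {
            "primaryid": primaryid,
            "caseid": caseid,
            "fda_dt": dates,
            "sex": sex,
            "age_known": age_known,
            "age_years": age_years,
        }
    )

    # duplicate report versions: same caseid, earlier date, lower primaryid
    dup_mask = rng.random(n) < config.duplicate_rate
    dup = demo.loc[dup_mask].copy()
    dup["primaryid"] = dup["caseid"] * 10
    dup["fda_dt"] = dup["fda_dt"].to_numpy() - rng.integers(
        1, 400, int(dup_mask.sum())
    ).astype("timedelta64[D]")
    demo_all = pd.concat([demo, dup], ignore_index=True)

    def _dup_children(frame: pd.DataFrame) -> pd.DataFrame:
        child = frame[frame["caseid"].isin(set(dup["caseid"]))].copy()
        child["primaryid"] = child["caseid"] * 10
        return pd.concat([frame, child], ignore_index=True)

    drug_all = _dup_children(drug)
    reac_all = _dup_children(reac)
    outc_all = _dup_children(outc)

    demo_out = _format_demo(demo_all)
    frames = {
        "demo": demo_out.sort_values("primaryid", key=lambda s: s.astype(np.int64))
        .reset_index(drop=True),
        "drug": drug_all.sort_values(["primaryid", "drug_seq"]).reset_index(drop=True),
        "reac": reac_all.sort_values(["primaryid", "pt"]).reset_index(drop=True),
        "outc": outc_all.sort_values(["primaryid", "outc_cod"]).reset_index(drop=True),
    }
    for name in ("drug", "reac", "outc"):
        frames[name]["primaryid"] = frames[name]["primaryid"].astype(str)
        frames[name]["caseid"] = frames[name]["caseid"].astype(str)
    truth = GroundTruth(
        seed=config.seed,
        n_base_cases=n,
        n_duplicates=int(dup_mask.sum()),
        drug_marginals=drug_marg,
        event_marginals=event_marg,
        multipliers=[asdict(m) for m in entries],
    )
    return SyntheticDataset(frames=frames, ground_truth=truth)


def _format_demo(demo: pd.DataFrame) -> pd.DataFrame:
    """Render the internal demo frame in the FAERS text dialect (ages of
    young children reported in months, missing values as empty fields)."""
    dates = pd.to_datetime(demo["fda_dt"])
    fda = (dates.dt.year * 10000 + dates.dt.month * 100 + dates.dt.day).astype(str)
    quarter = dates.dt.year.astype(str) + "Q" + dates.dt.quarter.astype(str)
    known = demo["age_known"].to_numpy()
    years = demo["age_years"].to_numpy()
    use_mon = known & (years < 3.0)
    age = np.where(use_mon, np.round(years * 12, 1), years)
    age_str = np.where(known, np.char.mod("%.1f", age), "")
    cod = np.where(known, np.where(use_mon, "MON", "YR"), "")
    return pd.DataFrame(
        {
            "primaryid": demo["primaryid"].astype(str),
            "caseid": demo["caseid"].astype(str),
            "fda_dt": fda,
            "sex": demo["sex"],
            "age": age_str,
            "age_cod": cod,
            "quarter": quarter,
        }
    )


_FILE_COLUMNS = {
    "demo": ["primaryid", "caseid", "fda_dt", "sex", "age", "age_cod", "quarter"],
    "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "reac": ["primaryid", "caseid", "pt"],
    "outc": ["primaryid", "caseid", "outc_cod"],
}


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write DEMO/DRUG/REAC/OUTC in the $-delimited dialect plus
    ground_truth.json; byte-identical for identical config + seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for kind, cols in _FILE_COLUMNS.items():
        frame = dataset.frames[kind][cols].astype(str)
        path = out_dir / f"{kind.upper()}.txt"
        lines = ["$".join(cols)]
        lines.extend("$".join(row) for row in frame.itertuples(index=False))
        path.write_text("\n".join(lines) + "\n")
        paths[kind] = path
    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(dataset.ground_truth.to_json() + "\n")
    paths["ground_truth"] = gt_path
    return paths


def expected_table(
    config: SyntheticConfig,
    drug: str,
    event_pts: Sequence[str] | frozenset[str],
    sex: str | None = None,
    age_group: str | None = None,
) -> tuple[float, float, float, float]:
    """Closed-form expected (a, b, c, d) cell probabilities.

    Marginalizes the generative model analytically over the PT-slot count
    (uniform 1..max_pts, slots i.i.d. with set semantics) and over the
    sex x age strata, honoring stratum-restricted multipliers. Restricting
    ``sex``/``age_group`` conditions on that stratum instead. The four
    probabilities sum to 1.
    """
    config.validate()
    drug_marg = config.resolved_drug_marginals()
    event_marg = config.resolved_event_marginals()
    targets = {p.upper() for p in event_pts}
    py = _younger_prob_given_known(config)
    age_states = {
        "younger": (1 - config.age_missing_rate) * py,
        "older": (1 - config.age_missing_rate) * (1 - py),
        None: config.age_missing_rate,  # unknown age: no age stratum applies
    }
    sex_states = dict(config.sex_probs)  # UNK matches no sex stratum
    if sex is not None:
        sex_states = {sex: 1.0}
    if age_group is not None:
        age_states = {age_group: 1.0}

    def p_event(d: str) -> float:
        total = 0.0
        for s, ps in sex_states.items():
            for ag, pa in age_states.items():
                w = {pt: q for pt, q in event_marg.items()}
                for ent in config.signal_multipliers:
                    if ent.drug != d:
                        continue
                    if ent.sex is not None and ent.sex != s:
                        continue
                    if ent.age_group is not None and ent.age_group != ag:
                        continue
                    w[ent.pt] *= ent.value
                z = sum(w.values())
                qt = sum(w[pt] for pt in targets if pt in w) / z
                hit = np.mean(
                    [1 - (1 - qt) ** k for k in range(1, config.max_pts + 1)]
                )
                total += ps * pa * hit
        return total / (sum(sex_states.values()) * sum(age_states.values()))

    pa = drug_marg.get(drug, 0.0) * p_event(drug)
    pb = drug_marg.get(drug, 0.0) - pa
    pc = sum(drug_marg[d] * p_event(d) for d in drug_marg if d != drug)
    pd_ = 1.0 - pa - pb - pc
    return pa, pb, pc, pd_
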