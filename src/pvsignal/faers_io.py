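"""Reading, linking and deduplicating FAERS-format quarterly ASCII files.

FAERS quarters arrive as ``$``-delimited text tables (DEMO, DRUG, REAC,
OUTC, THER, INDI) keyed by PRIMARYID (report version) and CASEID (case).
One case may have many report versions; analysis keeps a single version per
case: the one with the latest FDA_DT, ties broken by the higher PRIMARYID.
Child-table rows are joined to the surviving version on PRIMARYID.

FAERS files do not quote fields, so an embedded ``$`` is unsupported; lines
with the wrong field count are counted as malformed (fatal only above a
configurable rate).
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DELIMITER = "$"

#: Required (lowercase) columns per table kind. Extra columns are carried.
REQUIRED_COLUMNS: dict[str, set[str]] = {
    "demo": {"primaryid", "caseid"},
    "drug": {"primaryid", "drugname", "role_cod"},
    "reac": {"primaryid", "pt"},
    "outc": {"primaryid", "outc_cod"},
    "ther": {"primaryid"},
    "indi": {"primaryid"},
}

ROLE_CODES = {"PS", "SS", "C", "I"}
OUTCOME_CODES = {"CA", "DE", "DS", "HO", "LT", "OT", "RI"}

#: Multiplicative factors converting (age, age_cod) to years.
AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


def convert_age(age: float | None, age_cod: str | None) -> float | None:
    """Convert a FAERS age/unit pair to years.

    Returns None for missing or negative age, or for a missing/unknown unit
    code (an age with no unit is not assumed to be years — mis-stratifying
    silently is worse than dropping).
    """
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return None
    code = str(age_cod).strip().upper() if age_cod is not None else ""
    if code not in AGE_FACTORS:
        return None
    if age < 0:
        log.warning("negative age %r ignored", age)
        return None
    return float(age) * AGE_FACTORS[code]


def convert_age_series(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    age = pd.to_numeric(age, errors="coerce")
    factors = age_cod.astype("string").str.strip().str.upper().map(AGE_FACTORS)
    years = age * factors
    return years.where(years >= 0)


def _decode(path: Path) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def read_quarter(
    path: str | Path,
    table_kind: str,
    *,
    max_error_rate: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Read one ``$``-delimited FAERS table file.

    Returns the parsed frame (string cells; one row per well-formed data
    line; column names lowercased) and an issues dict with row/malformed
    counts and per-kind validation counters.

    Raises ValueError if a required column is absent or the malformed-line
    rate exceeds ``max_error_rate``.
    """
    path = Path(path)
    kind = table_kind.lower()
    if kind not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    text = _decode(path)
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    missing = REQUIRED_COLUMNS[kind] - set(header)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    ncol = len(header)
    rows, malformed = [], 0
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split(DELIMITER)
        if len(fields) != ncol:
            malformed += 1
            continue
        rows.append(fields)
    n_data = len(rows) + malformed
    if n_data and malformed / n_data > max_error_rate:
        raise ValueError(
            f"{path}: {malformed}/{n_data} malformed lines exceeds "
            f"max_error_rate={max_error_rate}"
        )
    if malformed:
        log.warning("%s: %d malformed line(s) skipped", path, malformed)
    frame = pd.DataFrame(rows, columns=header, dtype="object")
    frame = frame.apply(lambda s: s.str.strip())
    frame = frame.replace("", pd.NA)
    issues = {"file": str(path), "kind": kind, "rows": len(frame),
              "malformed_lines": malformed}
    frame = _postprocess(frame, kind, issues)
    return frame, issues


def _postprocess(frame: pd.DataFrame, kind: str, issues: dict) -> pd.DataFrame:
    if kind == "demo":
        # validate FDA_DT against the calendar; invalid -> missing + counter
        if "fda_dt" in frame.columns:
            parsed = pd.to_datetime(frame["fda_dt"], format="%Y%m%d",
                                    errors="coerce")
            bad = parsed.isna() & frame["fda_dt"].notna()
            issues["invalid_fda_dt"] = int(bad.sum())
            if bad.any():
                log.warning("%d invalid FDA_DT value(s) flagged missing",
                            int(bad.sum()))
            frame["fda_dt"] = pd.to_numeric(
                frame["fda_dt"].where(~bad), errors="coerce"
            )
        else:
            frame["fda_dt"] = np.nan
            issues["invalid_fda_dt"] = 0
        sex_col = "sex" if "sex" in frame.columns else (
            "gndr_cod" if "gndr_cod" in frame.columns else None
        )
        sex = (frame[sex_col].astype("string").str.upper()
               if sex_col else pd.Series(pd.NA, index=frame.index, dtype="string"))
        frame["sex"] = sex.where(sex.isin(["F", "M"]), "UNK").fillna("UNK")
        if "age" in frame.columns:
            missing_cod = (pd.to_numeric(frame["age"], errors="coerce").notna()
                           & ~frame.get("age_cod", pd.Series(pd.NA, index=frame.index))
                           .astype("string").str.strip().str.upper()
                           .isin(AGE_FACTORS))
            issues["age_without_unit"] = int(missing_cod.sum())
            frame["age_years"] = convert_age_series(
                frame["age"], frame.get("age_cod", pd.Series(pd.NA, index=frame.index))
            )
        else:
            frame["age_years"] = np.nan
            issues["age_without_unit"] = 0
    elif kind == "drug":
        role = frame["role_cod"].astype("string").str.upper()
        unknown = role.notna() & ~role.isin(ROLE_CODES)
        issues["unknown_role_cod"] = int(unknown.sum())
        frame["role_cod"] = role.where(role.isin(ROLE_CODES), "UNK").fillna("UNK")
    elif kind == "reac":
        empty = frame["pt"].isna()
        issues["empty_pt"] = int(empty.sum())
        frame = frame.loc[~empty].reset_index(drop=True)
        frame["pt"] = frame["pt"].str.upper().str.strip()
    elif kind == "outc":
        code = frame["outc_cod"].astype("string").str.upper().str.strip()
        unknown = code.notna() & ~code.isin(OUTCOME_CODES)
        issues["unknown_outc_cod"] = int(unknown.sum())  # preserved verbatim
        frame["outc_cod"] = code
    return frame


def deduplicate(demos: pd.DataFrame) -> pd.DataFrame:
    """Keep one DEMO row per CASEID.

    Within a case, the row with the latest FDA_DT survives; ties on FDA_DT
    are broken by the higher PRIMARYID (numeric comparison when the whole
    column is numeric, else lexicographic). A missing FDA_DT sorts lowest,
    so any dated version beats an undated one. Output is sorted by caseid.
    """
    if demos.empty:
        return demos.copy()
    work = demos.copy()
    fda = pd.to_numeric(work.get("fda_dt"), errors="coerce")
    work["_fda_key"] = fda.fillna(-1.0)
    pid_num = pd.to_numeric(work["primaryid"], errors="coerce")
    work["_pid_key"] = pid_num if not pid_num.isna().any() else work[
        "primaryid"
    ].astype(str)
    work = work.sort_values(
        ["caseid", "_fda_key", "_pid_key"], kind="mergesort"
    ).drop_duplicates("caseid", keep="last")
    work = work.sort_values("caseid", kind="mergesort").reset_index(drop=True)
    return work.drop(columns=["_fda_key", "_pid_key"])


@dataclass
class CaseReport:
    """One deduplicated safety report."""

    primaryid: str
    caseid: str
    fda_dt: int | None
    sex: str
    age_years: float | None
    outcomes: frozenset[str]
    drugs: tuple[tuple[str, str], ...]  # (name, role_cod), report order
    reactions: frozenset[str]


@dataclass
class CaseData:
    """Column-oriented container for a set of deduplicated, linked cases.

    ``cases`` has one row per case; ``drugs``/``reactions``/``outcomes`` are
    long tables keyed by primaryid. Reaction PTs are uppercased, trimmed and
    de-duplicated per case (set semantics).
    """

    cases: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def subset(self, primaryids: Iterable[str]) -> "CaseData":
        keep = set(primaryids)
        return CaseData(
            cases=self.cases[self.cases["primaryid"].isin(keep)].reset_index(drop=True),
            drugs=self.drugs[self.drugs["primaryid"].isin(keep)].reset_index(drop=True),
            reactions=self.reactions[
                self.reactions["primaryid"].isin(keep)
            ].reset_index(drop=True),
            outcomes=self.outcomes[
                self.outcomes["primaryid"].isin(keep)
            ].reset_index(drop=True),
            meta=dict(self.meta),
        )

    def iter_reports(self) -> Iterator[CaseReport]:
        drug_cols = ["drugname", "role_cod"]
        drugs_by = {
            pid: list(zip(g["drugname"], g["role_cod"]))
            for pid, g in self.drugs.groupby("primaryid", sort=False)[drug_cols]
        }
        reac_by = {
            pid: frozenset(g) for pid, g in
            self.reactions.groupby("primaryid", sort=False)["pt"]
        }
        outc_by = {
            pid: frozenset(g.dropna()) for pid, g in
            self.outcomes.groupby("primaryid", sort=False)["outc_cod"]
        }
        for row in self.cases.itertuples(index=False):
            fda = getattr(row, "fda_dt", None)
            age = getattr(row, "age_years", None)
            yield CaseReport(
                primaryid=row.primaryid,
                caseid=row.caseid,
                fda_dt=None if pd.isna(fda) else int(fda),
                sex=row.sex,
                age_years=None if pd.isna(age) else float(age),
                outcomes=outc_by.get(row.primaryid, frozenset()),
                drugs=tuple(drugs_by.get(row.primaryid, [])),
                reactions=reac_by.get(row.primaryid, frozenset()),
            )


def link_case(
    demo: pd.DataFrame,
    drugs: pd.DataFrame,
    reactions: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> CaseData:
    """Attach child-table rows to deduplicated DEMO records by primaryid.

    Child rows referencing a primaryid absent from the deduplicated DEMO
    (i.e. belonging to an eliminated report version) are dropped and
    counted. Cases with zero reactions are retained but counted.
    """
    keep = set(demo["primaryid"])

    def _attach(child: pd.DataFrame, name: str, counters: dict) -> pd.DataFrame:
        mask = child["primaryid"].isin(keep)
        counters[f"orphan_{name}_rows_dropped"] = int((~mask).sum())
        return child.loc[mask].reset_index(drop=True)

    meta: dict = {}
    drugs = _attach(drugs, "drug", meta)
    reactions = _attach(reactions, "reac", meta)
    outcomes = _attach(outcomes, "outc", meta)

    reactions = reactions.copy()
    reactions["pt"] = reactions["pt"].str.upper().str.strip()
    reactions = reactions.drop_duplicates(["primaryid", "pt"]).reset_index(drop=True)
    outcomes = outcomes.drop_duplicates(["primaryid", "outc_cod"]).reset_index(
        drop=True
    )

    cases_cols = ["primaryid", "caseid", "fda_dt", "sex", "age_years"]
    cases = demo.reindex(columns=cases_cols).reset_index(drop=True)
    meta["cases_without_reactions"] = int(
        (~cases["primaryid"].isin(set(reactions["primaryid"]))).sum()
    )
    meta["n_cases"] = len(cases)
    return CaseData(
        cases=cases,
        drugs=drugs.reset_index(drop=True),
        reactions=reactions,
        outcomes=outcomes,
        meta=meta,
    )


def ingest_tables(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    outc: pd.DataFrame | None = None,
) -> tuple[CaseData, dict]:
    """Deduplicate and link already-parsed FAERS-dialect tables (string
    cells, as read from the quarterly files or produced by the synthetic
    generator). Applies the same per-kind validation as :func:`read_quarter`.
    """
    report: dict = {}
    tables = {}
    for kind, frame in (("demo", demo), ("drug", drug), ("reac", reac),
                        ("outc", outc)):
        if frame is None:
            frame = pd.DataFrame(columns=["primaryid", "outc_cod"])
        frame = frame.copy()
        frame.columns = [c.strip().lower() for c in frame.columns]
        missing = REQUIRED_COLUMNS[kind] - set(frame.columns)
        if missing:
            raise ValueError(f"{kind}: missing required column(s) {sorted(missing)}")
        frame = frame.replace("", pd.NA)
        issues = {"kind": kind, "rows": len(frame), "malformed_lines": 0}
        tables[kind] = _postprocess(frame, kind, issues)
        report[kind] = issues
    n_raw = len(tables["demo"])
    demo_d = deduplicate(tables["demo"])
    report["demo_rows"] = n_raw
    report["duplicates_removed"] = n_raw - len(demo_d)
    case_data = link_case(demo_d, tables["drug"], tables["reac"], tables["outc"])
    report.update(case_data.meta)
    case_data.meta["ingest_report"] = report
    return case_data, report


def ingest_quarters(
    data_dir: str | Path, *, max_error_rate: float = 0.05
) -> tuple[CaseData, dict]:
    """Read all DEMO/DRUG/REAC/OUTC files under ``data_dir``, deduplicate
    across quarters and link. Returns the CaseData and a JSON-able ingest
    report."""
    data_dir = Path(data_dir)
    report: dict = {"files": [], "data_dir": str(data_dir)}
    frames: dict[str, list[pd.DataFrame]] = {k: [] for k in ("demo", "drug",
                                                             "reac", "outc")}
    for kind in frames:
        paths = sorted(data_dir.glob(f"{kind.upper()}*.txt")) + sorted(
            data_dir.glob(f"{kind}*.txt")
        )
        for path in dict.fromkeys(paths):  # dedupe, keep order
            frame, issues = read_quarter(path, kind, max_error_rate=max_error_rate)
            frames[kind].append(frame)
            report["files"].append(issues)
    for kind, req in (("demo", "DEMO"), ("drug", "DRUG"), ("reac", "REAC")):
        if not frames[kind]:
            raise FileNotFoundError(f"no {req}*.txt files under {data_dir}")
    demo = pd.concat(frames["demo"], ignore_index=True)
    drug = pd.concat(frames["drug"], ignore_index=True)
    reac = pd.concat(frames["reac"], ignore_index=True)
    outc = (pd.concat(frames["outc"], ignore_index=True) if frames["outc"]
            else pd.DataFrame(columns=["primaryid", "outc_cod"]))
    n_raw = len(demo)
    demo = deduplicate(demo)
    report["demo_rows"] = n_raw
    report["duplicates_removed"] = n_raw - len(demo)
    case_data = link_case(demo, drug, reac, outc)
    report.update(case_data.meta)
    case_data.meta["ingest_report"] = report
    return case_data, report


# ---------------------------------------------------------------------------
# Intermediate case-table format: one CSV row per case, list columns joined
# with "|", drug entries as NAME:ROLE. Round-trips exactly.

_LIST_SEP = "|"
_ROLE_SEP = ":"


def write_cases(case_data: CaseData, path: str | Path) -> None:
    bad = case_data.drugs["drugname"].str.contains(
        f"[{_LIST_SEP}{_ROLE_SEP}]", regex=True, na=False
    )
    if bad.any():
        raise ValueError(
            "drug names containing '|' or ':' cannot be serialized: "
            f"{case_data.drugs.loc[bad, 'drugname'].unique()[:5]}"
        )
    rows = []
    for rep in case_data.iter_reports():
        rows.append(
            {
                "primaryid": rep.primaryid,
                "caseid": rep.caseid,
                "fda_dt": "" if rep.fda_dt is None else str(rep.fda_dt),
                "sex": rep.sex,
                "age_years": "" if rep.age_years is None else repr(rep.age_years),
                "outcomes": _LIST_SEP.join(sorted(rep.outcomes)),
                "drugs": _LIST_SEP.join(
                    f"{n}{_ROLE_SEP}{r}" for n, r in rep.drugs
                ),
                "reactions": _LIST_SEP.join(sorted(rep.reactions)),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cases(path: str | Path) -> CaseData:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    cases, drugs, reactions, outcomes = [], [], [], []
    for row in frame.itertuples(index=False):
        cases.append(
            {
                "primaryid": row.primaryid,
                "caseid": row.caseid,
                "fda_dt": float(row.fda_dt) if row.fda_dt else np.nan,
                "sex": row.sex,
                "age_years": float(row.age_years) if row.age_years else np.nan,
            }
        )
        for entry in row.drugs.split(_LIST_SEP) if row.drugs else []:
            name, role = entry.rsplit(_ROLE_SEP, 1)
            drugs.append({"primaryid": row.primaryid, "drugname": name,
                          "role_cod": role})
        for pt in row.reactions.split(_LIST_SEP) if row.reactions else []:
            reactions.append({"primaryid": row.primaryid, "pt": pt})
        for oc in row.outcomes.split(_LIST_SEP) if row.outcomes else []:
            outcomes.append({"primaryid": row.primaryid, "outc_cod": oc})
    return CaseData(
        cases=pd.DataFrame(cases, columns=["primaryid", "caseid", "fda_dt",
                                           "sex", "age_years"]),
        drugs=pd.DataFrame(drugs, columns=["primaryid", "drugname", "role_cod"]),
        reactions=pd.DataFrame(reactions, columns=["primaryid", "pt"]),
        outcomes=pd.DataFrame(outcomes, columns=["primaryid", "outc_cod"]),
    )
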