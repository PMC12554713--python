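"""Drug-name normalization and MedDRA-style event hierarchy mapping.

Spontaneous reports carry free-text drug names (brands, salts, dose/form
suffixes). This module maps them onto a fixed set of canonical study drugs
via an editable synonym dictionary, and maps reaction preferred terms (PTs)
through a four-level PT -> HLT -> HLGT -> SOC hierarchy. A small mock
hierarchy ships with the package for testing; a user-supplied full hierarchy
in the same tabular format is accepted by the same loader.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

UNMAPPED = "UNMAPPED"

#: Trailing tokens stripped from raw drug names before dictionary lookup.
#: Dosage strengths (e.g. "100MG", "250 MG") are handled by a regex.
DEFAULT_STOP_TOKENS = frozenset(
    {
        "TABLET", "TABLETS", "TAB", "TABS",
        "CAPSULE", "CAPSULES", "CAP", "CAPS",
        "ER", "XR", "CR", "SR", "DR", "ODT", "IR",
        "ORAL", "INJECTION", "SOLUTION", "SUSPENSION", "SYRUP",
        "MG", "ML", "MG/ML", "%",
    }
)

_DOSE_RE = re.compile(r"^\d+(\.\d+)?(MG|MCG|G|ML|MG/ML|%)?$")


def _bundled(name: str):
    return resources.files("pvsignal.data").joinpath(name)


def _clean(raw: str) -> str:
    return re.sub(r"\s+", " ", str(raw).strip().upper())


@dataclass(frozen=True)
class DrugVocabulary:
    """Synonym dictionary over a fixed set of canonical drug names.

    Synonym sets must be pairwise disjoint across canonicals (validated
    loudly at construction, not per lookup); every canonical is implicitly
    its own synonym.
    """

    canonicals: tuple[str, ...]
    lookup: Mapping[str, str]  # uppercase synonym -> canonical

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "DrugVocabulary":
        lookup: dict[str, str] = {}
        canonicals = []
        for canonical, synonyms in mapping.items():
            canonical = _clean(canonical)
            canonicals.append(canonical)
            for syn in [canonical, *(synonyms or [])]:
                syn = _clean(syn)
                prior = lookup.get(syn)
                if prior is not None and prior != canonical:
                    raise ValueError(
                        f"synonym {syn!r} maps to both {prior!r} and {canonical!r}"
                    )
                lookup[syn] = canonical
        return cls(canonicals=tuple(canonicals), lookup=lookup)

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "DrugVocabulary":
        source = Path(path).read_text() if path is not None else _bundled(
            "drug_vocab.yaml"
        ).read_text()
        return cls.from_mapping(yaml.safe_load(source))

    def normalize(
        self, raw_name: str, stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS
    ) -> str | None:
        """Map a raw drug-name string to its canonical study drug, or None.

        Uppercases, trims, then strips trailing dosage/form tokens one at a
        time, retrying an exact dictionary lookup after each strip. No fuzzy
        matching.
        """
        if raw_name is None or (isinstance(raw_name, float)):
            return None
        name = _clean(raw_name)
        if not name:
            return None
        hit = self.lookup.get(name)
        if hit is not None:
            return hit
        tokens = name.split(" ")
        while len(tokens) > 1:
            last = tokens[-1]
            if last in stop_tokens or _DOSE_RE.match(last):
                tokens = tokens[:-1]
                hit = self.lookup.get(" ".join(tokens))
                if hit is not None:
                    return hit
            else:
                break
        return None

    def normalize_series(self, names: pd.Series) -> pd.Series:
        """Vectorized :meth:`normalize` (unique values looked up once)."""
        uniq = names.dropna().unique()
        table = {u: self.normalize(u) for u in uniq}
        return names.map(table)


def filter_primary_suspect(
    drugs: Sequence[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Keep only (drug, role_cod) entries whose role is primary suspect."""
    return [(name, role) for name, role in drugs if role == "PS"]


@dataclass(frozen=True)
class EventHierarchy:
    """PT -> (HLT, HLGT, SOC) mapping; unmapped PTs route to ``UNMAPPED``."""

    table: pd.DataFrame  # indexed by uppercase PT; columns hlt, hlgt, soc

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventHierarchy":
        frame = frame.copy()
        frame.columns = [c.strip().lower() for c in frame.columns]
        required = {"pt", "hlt", "hlgt", "soc"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"hierarchy missing columns: {sorted(missing)}")
        frame["pt"] = frame["pt"].map(_clean)
        if frame["pt"].duplicated().any():
            dups = frame.loc[frame["pt"].duplicated(), "pt"].tolist()
            raise ValueError(f"hierarchy maps PTs to multiple paths: {dups}")
        n_soc = frame["soc"].nunique()
        if n_soc > 27:  # MedDRA defines 27 system organ classes
            raise ValueError(f"hierarchy has {n_soc} SOCs; MedDRA has at most 27")
        return cls(table=frame.set_index("pt")[["hlt", "hlgt", "soc"]])

    @classmethod
    def from_csv(cls, path: str | Path | None = None) -> "EventHierarchy":
        if path is None:
            with resources.as_file(_bundled("event_hierarchy.csv")) as p:
                frame = pd.read_csv(p)
        else:
            frame = pd.read_csv(path)
        return cls.from_frame(frame)

    @property
    def pts(self) -> frozenset[str]:
        return frozenset(self.table.index)

    def map_pt(self, pt: str) -> tuple[str, str, str]:
        key = _clean(pt)
        if key in self.table.index:
            row = self.table.loc[key]
            return (row["hlt"], row["hlgt"], row["soc"])
        return (UNMAPPED, UNMAPPED, UNMAPPED)

    def soc_series(self, pts: pd.Series) -> pd.Series:
        """Vectorized SOC lookup with the UNMAPPED sentinel."""
        return pts.map(self.table["soc"]).fillna(UNMAPPED)


@dataclass(frozen=True)
class TargetEventSet:
    """A named set of PTs defining the target adverse event."""

    name: str
    pts: frozenset[str]

    def __post_init__(self):
        if not self.pts:
            raise ValueError(f"target event set {self.name!r} is empty")

    @classmethod
    def from_pts(cls, name: str, pts: Iterable[str]) -> "TargetEventSet":
        return cls(name=name, pts=frozenset(_clean(p) for p in pts))


def load_target_events(
    path: str | Path | None = None,
) -> dict[str, TargetEventSet]:
    source = Path(path).read_text() if path is not None else _bundled(
        "target_events.yaml"
    ).read_text()
    raw = yaml.safe_load(source)
    return {name: TargetEventSet.from_pts(name, pts) for name, pts in raw.items()}
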