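"""Replicated simulation studies over the synthetic generator.

Drives generate -> ingest -> analyze loops with derived per-replicate seeds
to estimate operating characteristics of the screening pipeline: the
familywise false-positive rate under a null generative model, and detection
power / subgroup patterns for injected signals.
"""
from __future__ import annotations

from . import faers_io, pipeline, synthetic
from .pipeline import RunConfig
from .synthetic import Multiplier, SyntheticConfig

_SEED_MOD = 2**31 - 1


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic, collision-free child seed below 2^31."""
    return (base_seed * 1_000_003 + 7919 * index + 1) % _SEED_MOD


def run_replicate(
    sim_cfg: SyntheticConfig,
    run_cfg: RunConfig,
    subgroup_drugs: list[str] | None = None,
) -> dict:
    """Generate one dataset and run the signal pipeline on it in memory."""
    dataset = synthetic.generate(sim_cfg)
    case_data, ingest_report = faers_io.ingest_tables(
        dataset.frames["demo"], dataset.frames["drug"],
        dataset.frames["reac"], dataset.frames["outc"],
    )
    case_data = pipeline.normalize_case_drugs(case_data, run_cfg.load_vocab())
    overall, prior, info = pipeline.run_overall(case_data, run_cfg)
    out = {
        "overall": overall,
        "prior": prior,
        "case_data": case_data,
        "ingest_report": ingest_report,
        "ground_truth": dataset.ground_truth,
    }
    if subgroup_drugs:
        out["subgroup"] = pipeline.run_subgroups(case_data, run_cfg,
                                                 subgroup_drugs)
    return out


def null_family_wise_rate(
    n_reports: int,
    n_replicates: int,
    base_seed: int,
    run_cfg: RunConfig | None = None,
) -> tuple[float, int]:
    """Fraction of null replicates (all multipliers 1) in which any drug's
    Bonferroni-adjusted Fisher p falls below alpha."""
    run_cfg = run_cfg or RunConfig()
    hits = 0
    for i in range(n_replicates):
        sim = SyntheticConfig(n_reports=n_reports,
                              seed=derive_seed(base_seed, i))
        rep = run_replicate(sim, run_cfg)
        hits += pipeline.family_wise_positive(rep["overall"],
                                              run_cfg.thresholds.alpha)
    return hits / n_replicates, hits


def signal_detection_rate(
    drug: str,
    pt: str,
    multiplier: float,
    n_reports: int,
    n_replicates: int,
    base_seed: int,
    run_cfg: RunConfig | None = None,
) -> float:
    """Fraction of replicates in which the injected pair's drug is flagged
    positive by the any-of-four rule."""
    run_cfg = run_cfg or RunConfig()
    hits = 0
    for i in range(n_replicates):
        sim = SyntheticConfig(
            n_reports=n_reports,
            seed=derive_seed(base_seed, 10_000 + i),
            signal_multipliers=(Multiplier(drug, pt, multiplier),),
        )
        rep = run_replicate(sim, run_cfg)
        row = rep["overall"].set_index("drug").loc[drug]
        hits += bool(row["positive"])
    return hits / n_replicates


def subgroup_pattern_rate(
    drug: str,
    pt: str,
    multiplier: float,
    n_reports: int,
    n_replicates: int,
    base_seed: int,
    run_cfg: RunConfig | None = None,
    sex: str = "F",
) -> float:
    """Fraction of replicates reproducing the one-sex signal pattern: the
    stratum carrying the injected signal positive, the other negative."""
    run_cfg = run_cfg or RunConfig()
    target = "Female" if sex == "F" else "Male"
    other = "Male" if sex == "F" else "Female"
    hits = 0
    for i in range(n_replicates):
        sim = SyntheticConfig(
            n_reports=n_reports,
            seed=derive_seed(base_seed, 20_000 + i),
            signal_multipliers=(Multiplier(drug, pt, multiplier, sex=sex),),
        )
        rep = run_replicate(sim, run_cfg, subgroup_drugs=[drug])
        sub = rep["subgroup"].set_index("stratum")
        hits += bool(sub.loc[target, "positive"]) and not bool(
            sub.loc[other, "positive"]
        )
    return hits / n_replicates
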