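"""Synthetic case-control study streams with known truth.

Emulates the statistical structure the sequential pipeline assumes: a
candidate locus with control minor-allele frequency ``maf``, a true
allelic odds ratio, and between-study normal heterogeneity on the log-OR
scale.  Control genotypes are drawn from Hardy-Weinberg proportions at
``maf``; each study perturbs the log odds ratio by N(0, tau^2), converts
the perturbed OR into a case-group allele frequency, and draws case
genotypes from Hardy-Weinberg proportions at that frequency.  (Case
genotypes under a strong allelic OR deviate slightly from HWE; at the
effect sizes of candidate-gene work this is second order and HWE sampling
is used in both arms.)

Randomness is reproducible: one scenario seed, with per-study substreams
spawned deterministically by study index, so adding a study to a stream
never reshuffles the earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifier import VerdictCategory, classify_locus
from .meta_engine import cumulative_series, effects_from_records
from .sequential import (
    SequentialDesign,
    boundaries_for_schedule,
    build_design,
    comparator_proportion,
)
from .study_data import Ethnicity, LocusDesignConfig, StudyRecord

__all__ = ["SimScenario", "simulate_locus", "operating_characteristics", "OperatingSummary"]


@dataclass(frozen=True)
class SimScenario:
    """One locus's simulated study stream configuration."""

    true_or: float
    maf: float
    tau: float = 0.0
    k: int = 10
    case_n: int | Sequence[int] = 200
    ctrl_n: int | Sequence[int] = 200
    seed: int = 0
    start_year: int = 2000
    locus_id: str = "rs0000001"
    ethnicity: Ethnicity = Ethnicity.CAUCASIAN

    def __post_init__(self) -> None:
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if not 0.0 < self.maf < 1.0:
            raise ValueError(f"maf must be in (0, 1), got {self.maf}")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.k < 1:
            raise ValueError("k must be at least 1")

    def arm_sizes(self, index: int) -> tuple[int, int]:
        case = self.case_n if isinstance(self.case_n, int) else self.case_n[index]
        ctrl = self.ctrl_n if isinstance(self.ctrl_n, int) else self.ctrl_n[index]
        return int(case), int(ctrl)


def _hwe_genotypes(rng: np.random.Generator, n: int, q: float) -> tuple[int, int, int]:
    """(AA, Aa, aa) counts for n subjects at minor-allele frequency q."""
    p = 1.0 - q
    counts = rng.multinomial(n, [p * p, 2.0 * p * q, q * q])
    return int(counts[0]), int(counts[1]), int(counts[2])


def simulate_locus(scenario: SimScenario) -> list[StudyRecord]:
    """Draw the scenario's study stream, ordered by (year, study id)."""
    records = []
    for i in range(scenario.k):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=scenario.seed, spawn_key=(i,))
        )
        log_or_i = math.log(scenario.true_or) + rng.normal(0.0, scenario.tau)
        q_case = comparator_proportion(scenario.maf, math.exp(log_or_i))
        case_n, ctrl_n = scenario.arm_sizes(i)
        records.append(
            StudyRecord(
                study_id=f"sim{i:03d}",
                year=scenario.start_year + i,
                ethnicity=scenario.ethnicity,
                locus_id=scenario.locus_id,
                case_genotypes=_hwe_genotypes(rng, case_n, q_case),
                control_genotypes=_hwe_genotypes(rng, ctrl_n, scenario.maf),
            )
        )
    return records


@dataclass(frozen=True)
class OperatingSummary:
    """Monte-Carlo operating characteristics of the sequential procedure."""

    replicates: int
    crossing_rate: float  # significance-boundary crossings (either direction)
    null_rate: float  # conclusive-null verdicts (futility or RIS complete)
    inconclusive_rate: float
    naive_rate: float  # any look with nominal two-sided p < alpha (no boundary)
    mean_stop_look: float  # mean 1-based first-crossing look among crossers
    mean_final_log_or: float
    mc_se_crossing: float
    mc_se_naive: float
    mc_se_final_log_or: float

    def empty(self) -> bool:
        return self.replicates == 0


def operating_characteristics(
    scenario: SimScenario,
    replicates: int,
    design_config: LocusDesignConfig | None = None,
) -> OperatingSummary:
    """Run the full sequential pipeline on many simulated streams.

    Each replicate simulates a study stream, pools cumulatively, and
    classifies against the sequential design.  ``design_config`` defaults
    to the scenario's MAF with the standard assumed OR 1.5, alpha 0.05,
    power 0.8 and fixed 80% heterogeneity adjustment.  The per-study arm
    sizes fix the subject schedule, so boundaries are computed once and
    shared by all replicates.  Also reports the naive repeated-testing
    rate: a replicate counts as naive-significant if ANY look has nominal
    two-sided p < alpha — the multiplicity inflation the monitored
    procedure exists to control.
    """
    if design_config is None:
        design_config = LocusDesignConfig(locus_id=scenario.locus_id, maf=min(scenario.maf, 0.5))
    design = build_design(design_config)
    if replicates == 0:
        nan = math.nan
        return OperatingSummary(0, nan, nan, nan, nan, nan, nan, nan, nan, nan)

    subjects = []
    total = 0
    for i in range(scenario.k):
        c, t = scenario.arm_sizes(i)
        total += c + t
        subjects.append(total)
    boundaries = boundaries_for_schedule(subjects, design)

    n_cross = n_null = n_naive = 0
    stop_looks: list[int] = []
    final_log_ors: list[float] = []
    for rep in range(replicates):
        rep_seed = int(
            np.random.SeedSequence(entropy=scenario.seed, spawn_key=(rep, 0)).generate_state(1)[0]
            % 2**31
        )
        rep_scenario = SimScenario(
            true_or=scenario.true_or,
            maf=scenario.maf,
            tau=scenario.tau,
            k=scenario.k,
            case_n=scenario.case_n,
            ctrl_n=scenario.ctrl_n,
            seed=rep_seed,
            start_year=scenario.start_year,
            locus_id=scenario.locus_id,
            ethnicity=scenario.ethnicity,
        )
        records = simulate_locus(rep_scenario)
        effects = effects_from_records(records)
        series = cumulative_series(effects, alpha=design.alpha)
        verdict = classify_locus(series, design, boundaries, ethnicity=scenario.ethnicity.value)
        if verdict.category in (
            VerdictCategory.CONCLUSIVE_RISK,
            VerdictCategory.CONCLUSIVE_PROTECTIVE,
        ):
            n_cross += 1
            stop_looks.append(verdict.crossing_look + 1)
        elif verdict.category is VerdictCategory.CONCLUSIVE_NULL:
            n_null += 1
        if any(r.p_value < design.alpha for r in series):
            n_naive += 1
        final_log_ors.append(series[-1].pooled_log_or)

    p_cross = n_cross / replicates
    p_naive = n_naive / replicates
    return OperatingSummary(
        replicates=replicates,
        crossing_rate=p_cross,
        null_rate=n_null / replicates,
        inconclusive_rate=1.0 - (n_cross + n_null) / replicates,
        naive_rate=p_naive,
        mean_stop_look=float(np.mean(stop_looks)) if stop_looks else math.nan,
        mean_final_log_or=float(np.mean(final_log_ors)),
        mc_se_crossing=math.sqrt(max(p_cross * (1 - p_cross), 1e-12) / replicates),
        mc_se_naive=math.sqrt(max(p_naive * (1 - p_naive), 1e-12) / replicates),
        mc_se_final_log_or=float(np.std(final_log_ors, ddof=1) / math.sqrt(replicates))
        if replicates > 1
        else math.nan,
    )
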