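"""Per-study effect estimation and cumulative DerSimonian-Laird pooling.

Effects are log odds ratios from the allele-model 2x2 table (Woolf method
with a Haldane-Anscombe 0.5 correction applied only when a zero cell
occurs).  Pooling uses inverse-variance weights; the random-effects model
adds the DerSimonian-Laird moment estimate of the between-study variance
tau-squared.  Alongside Cochran's Q and I-squared, each pooled result
carries the diversity D-squared = 1 - v_F / v_R (fixed- over random-model
pooled variance), the quantity used to inflate the required information
size of the sequential design.

The DerSimonian-Laird estimator (rather than REML) is the package default
because it is the estimator sequential meta-analysis practice standardised
on; the pooling entry points are pure functions so another estimator can be
swapped in front of the sequential machinery.  p-values are two-sided
normal-theory; no small-k t-type (Hartung-Knapp) correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .study_data import AlleleTable2x2, StudyRecord, genotype_to_alleles

__all__ = [
    "EffectEstimate",
    "PooledResult",
    "UnusableStudyError",
    "study_effect",
    "effects_from_records",
    "pool_fixed",
    "pool_random",
    "cumulative_series",
]


class UnusableStudyError(ValueError):
    """A study whose 2x2 table cannot yield an odds ratio (an empty arm)."""


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log odds ratio with its standard error."""

    log_or: float
    se: float
    study_id: str = ""
    year: int = 1900
    subjects: int = 1

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"se must be positive, got {self.se}")
        if self.subjects < 1:
            raise ValueError(f"subjects must be >= 1, got {self.subjects}")


@dataclass(frozen=True)
class PooledResult:
    """Pooled effect and heterogeneity statistics at one cumulative look."""

    k: int
    pooled_log_or: float
    se: float
    ci_low: float  # on the OR scale
    ci_high: float  # on the OR scale
    z: float
    p_value: float
    q: float
    tau2: float
    i2: float  # percent, [0, 100]
    d2: float  # proportion, [0, 1)
    cumulative_subjects: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.pooled_log_or)


def study_effect(table: AlleleTable2x2) -> EffectEstimate:
    """Woolf log odds ratio and SE from an allele 2x2 table.

    If any cell is zero, 0.5 is added to all four cells (Haldane-Anscombe);
    otherwise raw counts are used.  A study with an entirely empty case or
    control arm carries no information and raises
    :class:`UnusableStudyError`.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise UnusableStudyError("empty case or control arm")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    subjects = int(round((table.a + table.b + table.c + table.d) / 2))
    return EffectEstimate(log_or=log_or, se=se, subjects=max(subjects, 1))


def effects_from_records(records: Sequence[StudyRecord]) -> list[EffectEstimate]:
    """Allele-model effect per study, carrying id, year and subject count."""
    effects = []
    for r in records:
        e = study_effect(genotype_to_alleles(r))
        effects.append(
            EffectEstimate(
                log_or=e.log_or,
                se=e.se,
                study_id=r.study_id,
                year=r.year,
                subjects=r.subjects,
            )
        )
    return effects


def _pooled_from(
    effects: Sequence[EffectEstimate],
    weights: np.ndarray,
    q: float,
    tau2: float,
    d2: float,
    alpha: float,
) -> PooledResult:
    y = np.array([e.log_or for e in effects])
    wsum = weights.sum()
    pooled = float((weights * y).sum() / wsum)
    se = float(math.sqrt(1.0 / wsum))
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    zcrit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    k = len(effects)
    i2 = 0.0 if k <= 1 or q <= 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return PooledResult(
        k=k,
        pooled_log_or=pooled,
        se=se,
        ci_low=math.exp(pooled - zcrit * se),
        ci_high=math.exp(pooled + zcrit * se),
        z=z,
        p_value=p,
        q=q,
        tau2=tau2,
        i2=i2,
        d2=d2,
        cumulative_subjects=int(sum(e.subjects for e in effects)),
    )


def _q_statistic(effects: Sequence[EffectEstimate]) -> tuple[float, np.ndarray]:
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    pooled_f = (w * y).sum() / w.sum()
    q = float((w * (y - pooled_f) ** 2).sum())
    return q, w


def pool_fixed(effects: Sequence[EffectEstimate], alpha: float = 0.05) -> PooledResult:
    """Inverse-variance fixed-effect pooling (tau2 and D2 are zero)."""
    if not effects:
        raise ValueError("cannot pool an empty collection of effects")
    q, w = _q_statistic(effects)
    return _pooled_from(effects, w, q=q, tau2=0.0, d2=0.0, alpha=alpha)


def pool_random(effects: Sequence[EffectEstimate], alpha: float = 0.05) -> PooledResult:
    """DerSimonian-Laird random-effects pooling with heterogeneity statistics."""
    if not effects:
        raise ValueError("cannot pool an empty collection of effects")
    k = len(effects)
    q, w = _q_statistic(effects)
    if k == 1:
        tau2 = 0.0
    else:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = np.array([1.0 / (e.se**2 + tau2) for e in effects])
    v_f = 1.0 / w.sum()
    v_r = 1.0 / w_re.sum()
    d2 = 0.0 if tau2 == 0.0 else max(0.0, 1.0 - v_f / v_r)
    return _pooled_from(effects, w_re, q=q, tau2=tau2, d2=d2, alpha=alpha)


def cumulative_series(
    effects: Sequence[EffectEstimate], alpha: float = 0.05
) -> list[PooledResult]:
    """Random-effects pooling at every cumulative look.

    ``effects`` must already be in look order (year, then study id — the
    order :func:`decigene.study_data.read_studies` returns).  Element ``j``
    pools the first ``j + 1`` studies; subject accumulation is
    non-decreasing.
    """
    return [pool_random(effects[: j + 1], alpha=alpha) for j in range(len(effects))]
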