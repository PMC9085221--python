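"""Required information size and sequential monitoring/futility boundaries.

The sequential design treats each added study as an interim look at a
cumulative meta-analysis.  Information is measured in SUBJECTS accumulated
across studies; the information fraction at a look is
``cumulative subjects / RIS`` capped at 1.

Required information size (RIS)
    The fixed-sample size for a two-proportion comparison on the allele
    scale: the control proportion is the reference minor-allele frequency
    ``p_c`` and the case proportion ``p_t`` is implied by an assumed allelic
    odds ratio (default 1.5).  Per-group allele count

        m = (z_{1-a/2} + z_{1-b})^2 (p_c(1-p_c) + p_t(1-p_t)) / (p_t - p_c)^2

    Because every subject contributes two alleles split across the two
    arms, the subject total equals ``ceil(m)``.  Heterogeneity inflates
    this to the diversity-adjusted RIS = ceil(n_fixed / (1 - D2)).

Boundaries
    Lan-DeMets alpha spending of the O'Brien-Fleming type,
    ``a*(t) = 2(1 - Phi(z_{1-a/2} / sqrt(t)))``, turned into symmetric
    two-sided Z thresholds by recursive numerical integration of the
    non-crossing sub-density over the independent-increment Brownian
    representation of the Z process.  Futility uses the analogous
    beta-spending function computed one-sided (non-binding) under the
    alternative drift ``theta = z_{1-a/2} + z_{1-b}`` at full information;
    the two-sided inner wedge is ``|Z| <= f_k`` and is undefined at looks
    where the computed value is not positive.

Numerical tolerances: crossing probabilities are integrated on a
trapezoid grid accurate to well below 1e-4 in probability; thresholds are
capped at Z = 8 when the incremental spend is negligibly small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .study_data import LocusDesignConfig

__all__ = [
    "SequentialDesign",
    "BoundarySet",
    "CrossingReport",
    "DesignError",
    "comparator_proportion",
    "fixed_information_size",
    "diversity_adjusted_is",
    "build_design",
    "alpha_spending",
    "beta_spending",
    "monitoring_boundaries",
    "futility_boundaries",
    "design_boundaries",
    "schedule_fractions",
    "evaluate_crossing",
    "Z_CAP",
]

Z_CAP = 8.0  # threshold reported when a look's incremental spend is ~0
_GRID = 1001  # points in the continuation-region sub-density grid
_MIN_SPEND = 1e-12


class DesignError(ValueError):
    """Raised for infeasible or ill-ordered sequential designs."""


# --------------------------------------------------------------------------
# information size
# --------------------------------------------------------------------------


def comparator_proportion(maf: float, odds_ratio: float) -> float:
    """Case-group minor-allele proportion implied by an allelic odds ratio.

    Solves OR = [p_t/(1-p_t)] / [p_c/(1-p_c)] for p_t given p_c = maf:
    p_t = OR * maf / (1 + maf (OR - 1)).
    """
    if not 0.0 < maf < 1.0:
        raise DesignError(f"maf must be in (0, 1), got {maf}")
    if odds_ratio <= 0:
        raise DesignError(f"odds ratio must be positive, got {odds_ratio}")
    return odds_ratio * maf / (1.0 + maf * (odds_ratio - 1.0))


def fixed_information_size(alpha: float, power: float, p_c: float, p_t: float) -> int:
    """Subjects required by the fixed-sample two-proportion design.

    Normal-approximation sample size on alleles; with two alleles per
    subject split across two equal arms, the per-group allele count equals
    the total subject count.
    """
    if not (0.0 < p_c < 1.0 and 0.0 < p_t < 1.0):
        raise DesignError("proportions must lie strictly in (0, 1)")
    if p_c == p_t:
        raise DesignError("p_c == p_t: the design has no detectable effect")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    m = (z_a + z_b) ** 2 * (p_c * (1 - p_c) + p_t * (1 - p_t)) / (p_t - p_c) ** 2
    return int(math.ceil(m))


def diversity_adjusted_is(n_fixed: int, d2: float) -> int:
    """Inflate the fixed-sample size by the diversity D2: ceil(n / (1 - D2))."""
    if not 0.0 <= d2 < 1.0:
        raise DesignError(f"d2 must be in [0, 1), got {d2}")
    # tiny slack so e.g. 389 / (1 - 0.8) ceils to 1945, not 1946
    return int(math.ceil(n_fixed / (1.0 - d2) - 1e-9))


@dataclass(frozen=True)
class SequentialDesign:
    """Resolved per-locus design: proportions, sample sizes, error rates."""

    locus_id: str
    alpha: float
    power: float
    assumed_or: float
    maf: float
    p_t: float
    n_fixed: int
    d2_applied: float
    ris: int

    def __post_init__(self) -> None:
        if self.ris < self.n_fixed:
            raise DesignError("diversity-adjusted RIS cannot be below n_fixed")


def build_design(
    config: LocusDesignConfig, estimated_d2: float | None = None
) -> SequentialDesign:
    """Resolve a locus config into a concrete design.

    In ``"estimate"`` heterogeneity mode the caller supplies the D2
    estimated from the accumulated studies (``estimated_d2``); in
    ``"fixed"`` mode the configured ``fixed_d2`` applies.
    """
    p_t = comparator_proportion(config.maf, config.assumed_or)
    n_fixed = fixed_information_size(config.alpha, config.power, config.maf, p_t)
    if config.heterogeneity_mode == "estimate":
        if estimated_d2 is None:
            raise DesignError(
                f"{config.locus_id}: heterogeneity_mode='estimate' requires "
                "an estimated D2"
            )
        d2 = float(estimated_d2)
    else:
        d2 = config.fixed_d2
    return SequentialDesign(
        locus_id=config.locus_id,
        alpha=config.alpha,
        power=config.power,
        assumed_or=config.assumed_or,
        maf=config.maf,
        p_t=p_t,
        n_fixed=n_fixed,
        d2_applied=d2,
        ris=diversity_adjusted_is(n_fixed, d2),
    )


# --------------------------------------------------------------------------
# spending functions
# --------------------------------------------------------------------------


def alpha_spending(t: float, alpha: float = 0.05) -> float:
    """O'Brien-Fleming-type Lan-DeMets spending: 2(1 - Phi(z_{1-a/2}/sqrt(t)))."""
    if t <= 0.0:
        return 0.0
    if t >= 1.0:
        return alpha
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(2.0 * stats.norm.sf(z / math.sqrt(t)))


def beta_spending(t: float, beta: float) -> float:
    """Type-II budget spent by information fraction ``t``.

    The same O'Brien-Fleming spending family, realised the way the
    two-sided alpha budget is: the budget is halved, run through the
    spending shape, and doubled back — ``2 * alpha_spending(t, beta/2)``.
    This matched construction makes the futility wedge close onto the
    monitoring boundary near full information.
    """
    return 2.0 * alpha_spending(t, beta / 2.0)


# --------------------------------------------------------------------------
# boundary sets via recursive numerical integration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundarySet:
    """Per-look Z thresholds; futility entries are NaN where undefined."""

    fractions: tuple[float, ...]
    monitor_upper: tuple[float, ...]
    monitor_lower: tuple[float, ...]
    futility_upper: tuple[float, ...] = ()
    futility_lower: tuple[float, ...] = ()
    spent_alpha: tuple[float, ...] = ()
    spent_beta: tuple[float, ...] = ()

    def to_table(self):
        """Tabular layout (fraction, monitor, futility, spent-alpha/beta)."""
        import pandas as pd

        n = len(self.fractions)
        nan = (math.nan,) * n
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "monitor_upper": self.monitor_upper,
                "monitor_lower": self.monitor_lower,
                "futility_upper": self.futility_upper or nan,
                "futility_lower": self.futility_lower or nan,
                "spent_alpha": self.spent_alpha or nan,
                "spent_beta": self.spent_beta or nan,
            }
        )


def _check_fractions(fractions: Sequence[float]) -> None:
    fr = list(fractions)
    if not fr:
        raise DesignError("at least one look is required")
    if any(not 0.0 < t <= 1.0 for t in fr):
        raise DesignError(f"fractions must lie in (0, 1], got {fr}")
    if any(b <= a for a, b in zip(fr, fr[1:])):
        raise DesignError(f"fractions must be strictly increasing, got {fr}")


def _normal_pdf(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)


class _SubDensity:
    """Sub-density of the Brownian-scale statistic among non-stopped paths.

    State after look k: a trapezoid grid over the continuation region and
    the sub-density values on it.  Propagating to look k+1 convolves with
    the N(theta * dt, dt) increment; masses are computed by integrating the
    Gaussian increment analytically (normal-CDF differences), so the only
    quadrature error is the trapezoid rule over the smooth stored density.
    """

    def __init__(self, drift: float = 0.0, grid: int = _GRID):
        self.drift = drift
        self.grid = grid
        self.x: np.ndarray | None = None  # None until the first look is absorbed
        self.f: np.ndarray | None = None
        self.t_prev = 0.0
        self.mass = 1.0  # probability not yet stopped

    def density_at(self, t: float, s: np.ndarray) -> np.ndarray:
        """Sub-density of S_t at points ``s`` given no stop before ``t``."""
        if self.x is None:
            sd = math.sqrt(t)
            return _normal_pdf((s - self.drift * t) / sd) / sd
        dt = t - self.t_prev
        sd = math.sqrt(dt)
        w = _trap_weights(self.x)
        kernel = _normal_pdf((s[:, None] - self.x[None, :] - self.drift * dt) / sd) / sd
        return kernel @ (w * self.f)

    def mass_between(self, t: float, lo: float, hi: float) -> float:
        """P(no stop before t and S_t in [lo, hi])."""
        if self.x is None:
            sd = math.sqrt(t)
            mu = self.drift * t
            return float(stats.norm.cdf((hi - mu) / sd) - stats.norm.cdf((lo - mu) / sd))
        dt = t - self.t_prev
        sd = math.sqrt(dt)
        mu = self.x + self.drift * dt
        inner = stats.norm.cdf((hi - mu) / sd) - stats.norm.cdf((lo - mu) / sd)
        w = _trap_weights(self.x)
        return float((w * self.f * inner).sum())

    def restrict(self, t: float, lo: float, hi: float) -> None:
        """Absorb paths outside [lo, hi] at time ``t``; keep the rest."""
        mass = self.mass_between(t, lo, hi)
        x = np.linspace(lo, hi, self.grid)
        f = self.density_at(t, x)
        self.x, self.f, self.t_prev = x, f, t
        self.mass = mass


def _trap_weights(x: np.ndarray) -> np.ndarray:
    w = np.empty_like(x)
    w[1:-1] = (x[2:] - x[:-2]) / 2.0
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    return w


def _mass_inside(state: _SubDensity, t: float, lo: float, hi: float) -> float:
    return state.mass_between(t, lo, hi)


def monitoring_boundaries(
    fractions: Sequence[float], alpha: float = 0.05
) -> BoundarySet:
    """Symmetric two-sided monitoring thresholds for an alpha-spending design.

    The two-sided design is realised as two mirrored one-sided halves, each
    spending ``alpha_spending(t, alpha/2)`` — the construction behind the
    published Lan-DeMets tables (e.g. two equal looks at two-sided 0.05
    give thresholds 2.963 and 1.969).  The reported ``spent_alpha`` is the
    two-sided account (twice the one-sided mass absorbed) and balances to
    ``alpha`` at the final look.
    """
    _check_fractions(fractions)
    state = _SubDensity(drift=0.0)
    uppers: list[float] = []
    spent: list[float] = []
    cum_prev = 0.0
    for t in fractions:
        cum = alpha_spending(t, alpha / 2.0)  # one-sided half-budget account
        inc = max(0.0, cum - cum_prev)
        sq = math.sqrt(t)
        lo = -Z_CAP * sq
        if inc <= _MIN_SPEND:
            z_k = Z_CAP
        else:

            def exit_prob(z: float) -> float:
                return state.mass - _mass_inside(state, t, lo, z * sq)

            if exit_prob(Z_CAP) >= inc:
                z_k = Z_CAP
            else:
                z_k = float(
                    optimize.brentq(lambda z: exit_prob(z) - inc, 1e-6, Z_CAP, xtol=1e-9)
                )
        state.restrict(t, lo, z_k * sq)
        cum_prev = 1.0 - state.mass  # one-sided alpha actually absorbed so far
        uppers.append(z_k)
        spent.append(2.0 * cum_prev)
    return BoundarySet(
        fractions=tuple(float(t) for t in fractions),
        monitor_upper=tuple(uppers),
        monitor_lower=tuple(-u for u in uppers),
        spent_alpha=tuple(spent),
    )


def futility_boundaries(
    fractions: Sequence[float], alpha: float = 0.05, power: float = 0.80
) -> BoundarySet:
    """Inner-wedge futility thresholds from one-sided beta spending.

    Computed under the alternative with Brownian drift
    ``theta = z_{1-a/2} + z_{1-b}``: the look-k value ``f_k`` spends the
    incremental type-II budget on paths falling to ``Z <= f_k`` having
    stayed above all earlier futility values (non-binding with respect to
    the monitoring boundary).  The symmetric wedge is ``|Z| <= f_k``; looks
    where ``f_k <= 0`` report NaN (the wedge does not exist that early).
    """
    _check_fractions(fractions)
    beta = 1.0 - power
    theta = float(stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power))
    state = _SubDensity(drift=theta)
    values: list[float] = []
    spent: list[float] = []
    cum_prev = 0.0
    for t in fractions:
        cum = beta_spending(t, beta)
        inc = max(0.0, cum - cum_prev)
        sq = math.sqrt(t)
        hi = theta * t + Z_CAP * sq  # effectively +infinity for the upper edge
        if inc <= _MIN_SPEND:
            l_s = -Z_CAP * sq  # no spend: absorb essentially nothing
        else:

            def accept_prob(l_s: float) -> float:
                return state.mass - _mass_inside(state, t, l_s, hi)

            lo_bracket = -Z_CAP * sq + min(0.0, theta * t)
            if accept_prob(lo_bracket) > inc:  # pathological; spend cannot be met
                l_s = lo_bracket
            else:
                l_s = float(
                    optimize.brentq(
                        lambda l: accept_prob(l) - inc, lo_bracket, hi - 1e-9, xtol=1e-10
                    )
                )
        state.restrict(t, l_s, hi)
        cum_prev = 1.0 - state.mass
        z_val = l_s / sq
        values.append(z_val)
        spent.append(cum_prev)
    fut_upper = tuple(v if v > 0.0 else math.nan for v in values)
    fut_lower = tuple(-v if v > 0.0 else math.nan for v in values)
    return BoundarySet(
        fractions=tuple(float(t) for t in fractions),
        monitor_upper=(),
        monitor_lower=(),
        futility_upper=fut_upper,
        futility_lower=fut_lower,
        spent_beta=tuple(spent),
    )


def design_boundaries(
    fractions: Sequence[float], alpha: float = 0.05, power: float = 0.80
) -> BoundarySet:
    """Monitoring and futility thresholds on one look grid."""
    mon = monitoring_boundaries(fractions, alpha)
    fut = futility_boundaries(fractions, alpha, power)
    return BoundarySet(
        fractions=mon.fractions,
        monitor_upper=mon.monitor_upper,
        monitor_lower=mon.monitor_lower,
        futility_upper=fut.futility_upper,
        futility_lower=fut.futility_lower,
        spent_alpha=mon.spent_alpha,
        spent_beta=fut.spent_beta,
    )


# --------------------------------------------------------------------------
# crossing evaluation
# --------------------------------------------------------------------------


def schedule_fractions(subject_series: Sequence[int], ris: int) -> list[float]:
    """Per-look information fractions: cumulative subjects / RIS, capped at 1.

    Looks arriving after the RIS is reached all share fraction 1 (no
    further alpha is spent there).
    """
    if any(b < a for a, b in zip(subject_series, subject_series[1:])):
        raise DesignError("cumulative subject counts must be non-decreasing")
    return [min(1.0, n / ris) for n in subject_series]


@dataclass(frozen=True)
class CrossingReport:
    """First boundary events along a Z curve (look indices are 0-based)."""

    fractions: tuple[float, ...]
    significance_look: int | None
    significance_direction: int  # +1 risk, -1 protective, 0 none
    futility_look: int | None
    ris_reached: bool


def boundaries_for_schedule(
    subject_series: Sequence[int], design: SequentialDesign
) -> BoundarySet:
    """Boundary set on the deduplicated fraction grid of a subject schedule."""
    fractions = schedule_fractions(subject_series, design.ris)
    unique = sorted(set(fractions))
    return design_boundaries(unique, design.alpha, design.power)


def _look_threshold(boundaries: BoundarySet, fraction: float) -> tuple[float, float]:
    """(monitoring, futility) thresholds at a fraction present in the grid."""
    idx = None
    for i, t in enumerate(boundaries.fractions):
        if abs(t - fraction) <= 1e-12:
            idx = i
            break
    if idx is None:
        raise DesignError(f"fraction {fraction} not in the boundary grid")
    fut = boundaries.futility_upper[idx] if boundaries.futility_upper else math.nan
    return boundaries.monitor_upper[idx], fut


def evaluate_crossing(
    z_series: Sequence[float],
    subject_series: Sequence[int],
    design: SequentialDesign,
    boundaries: BoundarySet,
) -> CrossingReport:
    """Scan the cumulative Z curve against monitoring and futility boundaries.

    The first look with ``|Z| >= monitoring threshold`` is the significance
    crossing (equality counts as crossed); the first look with
    ``|Z| <= futility threshold`` (where defined) is the futility crossing.
    The procedure is sequential: the scan stops at the first look whose
    information fraction reaches 1, where the verdict is final — looks
    accumulated beyond the RIS are not additional tests (re-testing them
    would spend type-I error with no budget left).
    """
    if len(z_series) != len(subject_series):
        raise DesignError("z_series and subject_series must have equal length")
    fractions = schedule_fractions(subject_series, design.ris)
    sig_look: int | None = None
    sig_dir = 0
    fut_look: int | None = None
    ris_reached = False
    for i, (z, t) in enumerate(zip(z_series, fractions)):
        mon, fut = _look_threshold(boundaries, t)
        if sig_look is None and abs(z) >= mon:
            sig_look = i
            sig_dir = 1 if z > 0 else -1
        if fut_look is None and not math.isnan(fut) and abs(z) <= fut:
            fut_look = i
        if t >= 1.0:
            ris_reached = True
            break
    return CrossingReport(
        fractions=tuple(fractions),
        significance_look=sig_look,
        significance_direction=sig_dir,
        futility_look=fut_look,
        ris_reached=ris_reached,
    )
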