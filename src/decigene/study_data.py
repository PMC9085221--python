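"""Data model and I/O for per-study genetic case-control counts.

Each primary study contributes genotype counts for a case group and a
control group at one locus in one ethnicity stratum.  Genotypes are coded
against the *major* allele A of the reference population: ``AA`` (homozygous
major), ``Aa`` (heterozygous), ``aa`` (homozygous minor).  The allele model
collapses each subject into two alleles, so a study becomes a 2x2
minor/major x case/control table.

The accumulated-information unit throughout the package is SUBJECTS
(cases + controls), not alleles; allele tables are internal to effect
estimation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Ethnicity",
    "StudyRecord",
    "AlleleTable2x2",
    "LocusDesignConfig",
    "StudyParseError",
    "ConfigError",
    "read_studies",
    "write_studies",
    "read_locus_configs",
    "genotype_to_alleles",
    "maf_conflicts",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
    "STUDY_COLUMNS",
]


class StudyParseError(ValueError):
    """Raised when a study table violates the documented schema."""


class ConfigError(ValueError):
    """Raised when a locus design configuration is invalid."""


class Ethnicity(str, enum.Enum):
    CAUCASIAN = "caucasian"
    ASIAN = "asian"
    OTHER = "other"

    @classmethod
    def parse(cls, label: str) -> "Ethnicity":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise StudyParseError(
                f"unknown ethnicity label {label!r}; expected one of "
                f"{[e.value for e in cls]}"
            ) from None


@dataclass(frozen=True)
class StudyRecord:
    """One primary study's genotype counts at one locus and stratum.

    ``case_genotypes`` / ``control_genotypes`` are ``(AA, Aa, aa)`` counts,
    with ``A`` the major allele of the design reference.
    """

    study_id: str
    year: int
    ethnicity: Ethnicity
    locus_id: str
    case_genotypes: tuple[int, int, int]
    control_genotypes: tuple[int, int, int]

    def __post_init__(self) -> None:
        for arm in (self.case_genotypes, self.control_genotypes):
            if len(arm) != 3 or any(int(c) != c or c < 0 for c in arm):
                raise StudyParseError(
                    f"study {self.study_id!r}: genotype counts must be three "
                    f"non-negative integers, got {arm!r}"
                )
        if sum(self.case_genotypes) + sum(self.control_genotypes) == 0:
            raise StudyParseError(f"study {self.study_id!r}: both arms empty")
        if not 1900 <= self.year <= 2100:
            raise StudyParseError(
                f"study {self.study_id!r}: year {self.year} outside [1900, 2100]"
            )

    @property
    def n_cases(self) -> int:
        return sum(self.case_genotypes)

    @property
    def n_controls(self) -> int:
        return sum(self.control_genotypes)

    @property
    def subjects(self) -> int:
        return self.n_cases + self.n_controls

    def control_minor_freq(self) -> float:
        """Observed minor-allele proportion in the control arm."""
        aa_major, het, aa_minor = self.control_genotypes
        total = 2 * (aa_major + het + aa_minor)
        if total == 0:
            return math.nan
        return (2 * aa_minor + het) / total


@dataclass(frozen=True)
class AlleleTable2x2:
    """Minor/major allele counts: a,b = cases; c,d = controls."""

    a: int  # minor alleles in cases
    b: int  # major alleles in cases
    c: int  # minor alleles in controls
    d: int  # major alleles in controls

    def __post_init__(self) -> None:
        if any(x < 0 for x in (self.a, self.b, self.c, self.d)):
            raise ValueError("allele counts must be non-negative")


def genotype_to_alleles(record: StudyRecord) -> AlleleTable2x2:
    """Collapse genotype counts to the allele-model 2x2 table.

    Each het subject contributes one minor and one major allele; each
    homozygote contributes two of its allele.  Subject conservation holds
    exactly: (a + b) / 2 == number of cases.
    """
    c_aa, c_het, c_min = record.case_genotypes
    k_aa, k_het, k_min = record.control_genotypes
    return AlleleTable2x2(
        a=2 * c_min + c_het,
        b=2 * c_aa + c_het,
        c=2 * k_min + k_het,
        d=2 * k_aa + k_het,
    )


# -- heterogeneity-adjustment mode ------------------------------------------

FIXED_D2_DEFAULT = 0.80


@dataclass(frozen=True)
class LocusDesignConfig:
    """Per-locus sequential-design settings.

    ``maf`` is the control-population minor-allele frequency taken from a
    reference panel (e.g. the 1000 Genomes Project); it is a config input
    and is never re-estimated from the included studies.  ``heterogeneity_mode``
    is either ``"fixed"`` (use ``fixed_d2``, default 0.80) or ``"estimate"``
    (use the diversity D-squared estimated from the accumulated studies).
    """

    locus_id: str
    maf: float
    assumed_or: float = 1.5
    alpha: float = 0.05
    power: float = 0.80
    heterogeneity_mode: str = "fixed"
    fixed_d2: float = FIXED_D2_DEFAULT

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ConfigError(f"{self.locus_id}: maf must be in (0, 0.5], got {self.maf}")
        if self.assumed_or <= 0:
            raise ConfigError(f"{self.locus_id}: assumed_or must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"{self.locus_id}: alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ConfigError(f"{self.locus_id}: power must be in (0, 1)")
        if self.heterogeneity_mode not in ("fixed", "estimate"):
            raise ConfigError(
                f"{self.locus_id}: heterogeneity_mode must be 'fixed' or "
                f"'estimate', got {self.heterogeneity_mode!r}"
            )
        if not 0.0 <= self.fixed_d2 < 1.0:
            raise ConfigError(f"{self.locus_id}: fixed_d2 must be in [0, 1)")


def read_locus_configs(path: str | Path) -> dict[str, LocusDesignConfig]:
    """Read a YAML/JSON mapping of locus id -> design settings.

    Expected layout::

        rs2228570:
          maf: 0.38
          assumed_or: 1.5     # optional, default 1.5
          alpha: 0.05         # optional
          power: 0.8          # optional
          d2: 0.8             # a number, or the string "estimate"
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"locus config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        return {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: expected a mapping of locus id -> settings")
    configs: dict[str, LocusDesignConfig] = {}
    for locus_id, entry in raw.items():
        if not isinstance(entry, Mapping) or "maf" not in entry:
            raise ConfigError(f"{path}: locus {locus_id!r} needs at least a 'maf' key")
        d2 = entry.get("d2", FIXED_D2_DEFAULT)
        if isinstance(d2, str):
            if d2 != "estimate":
                raise ConfigError(f"{locus_id}: d2 must be a number or 'estimate'")
            mode, fixed_d2 = "estimate", FIXED_D2_DEFAULT
        else:
            mode, fixed_d2 = "fixed", float(d2)
        configs[str(locus_id)] = LocusDesignConfig(
            locus_id=str(locus_id),
            maf=float(entry["maf"]),
            assumed_or=float(entry.get("assumed_or", 1.5)),
            alpha=float(entry.get("alpha", 0.05)),
            power=float(entry.get("power", 0.80)),
            heterogeneity_mode=mode,
            fixed_d2=fixed_d2,
        )
    return configs


# -- study table I/O ---------------------------------------------------------

STUDY_COLUMNS = [
    "study_id",
    "year",
    "ethnicity",
    "locus_id",
    "case_AA",
    "case_Aa",
    "case_aa",
    "ctrl_AA",
    "ctrl_Aa",
    "ctrl_aa",
]

_COUNT_COLUMNS = STUDY_COLUMNS[4:]


def read_studies(path: str | Path) -> list[StudyRecord]:
    """Read a delimited (comma or tab) study table into sorted records.

    Records are returned sorted by ``(year, study_id)`` — the look order of
    the cumulative analysis.  Rows with missing or malformed cells, unknown
    ethnicity labels, or duplicated ``(study_id, locus_id, ethnicity)`` keys
    raise :class:`StudyParseError` naming the offending row(s).
    """
    path = Path(path)
    if not path.exists():
        raise StudyParseError(f"study file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    missing_cols = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise StudyParseError(f"{path}: missing required columns {missing_cols}")

    bad_rows = df.index[df[STUDY_COLUMNS].isna().any(axis=1)].tolist()
    if bad_rows:
        # +2: header line plus 1-based numbering, matching what an editor shows
        rows = ", ".join(str(i + 2) for i in bad_rows)
        raise StudyParseError(f"{path}: missing cells in row(s) {rows}")

    records: list[StudyRecord] = []
    for i, row in df.iterrows():
        lineno = i + 2
        try:
            year = int(row["year"])
            counts = [int(row[c]) for c in _COUNT_COLUMNS]
        except (TypeError, ValueError) as exc:
            raise StudyParseError(f"{path}: row {lineno}: malformed integer ({exc})") from None
        if any(c < 0 for c in counts):
            raise StudyParseError(f"{path}: row {lineno}: negative genotype count")
        try:
            records.append(
                StudyRecord(
                    study_id=str(row["study_id"]),
                    year=year,
                    ethnicity=Ethnicity.parse(row["ethnicity"]),
                    locus_id=str(row["locus_id"]),
                    case_genotypes=(counts[0], counts[1], counts[2]),
                    control_genotypes=(counts[3], counts[4], counts[5]),
                )
            )
        except StudyParseError as exc:
            raise StudyParseError(f"{path}: row {lineno}: {exc}") from None

    seen: set[tuple[str, str, str]] = set()
    for i, rec in enumerate(records):
        key = (rec.study_id, rec.locus_id, rec.ethnicity.value)
        if key in seen:
            raise StudyParseError(f"{path}: duplicate (study_id, locus_id, ethnicity) {key}")
        seen.add(key)

    records.sort(key=lambda r: (r.year, r.study_id))
    return records


def write_studies(records: Iterable[StudyRecord], path: str | Path) -> None:
    """Write records in the same schema :func:`read_studies` accepts."""
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "year": r.year,
                "ethnicity": r.ethnicity.value,
                "locus_id": r.locus_id,
                "case_AA": r.case_genotypes[0],
                "case_Aa": r.case_genotypes[1],
                "case_aa": r.case_genotypes[2],
                "ctrl_AA": r.control_genotypes[0],
                "ctrl_Aa": r.control_genotypes[1],
                "ctrl_aa": r.control_genotypes[2],
            }
        )
    pd.DataFrame(rows, columns=STUDY_COLUMNS).to_csv(path, index=False)


def maf_conflicts(records: Iterable[StudyRecord], threshold: float = 0.5) -> list[str]:
    """Study ids whose observed control minor-allele proportion exceeds 0.5.

    The minor allele is fixed by the design reference; a study whose coding
    appears flipped relative to that reference is flagged for review, never
    silently re-oriented.
    """
    flagged = []
    for r in records:
        f = r.control_minor_freq()
        if not math.isnan(f) and f > threshold:
            flagged.append(r.study_id)
    return flagged


# -- verdict report ----------------------------------------------------------

REPORT_COLUMNS = [
    "locus_id",
    "ethnicity",
    "articles",
    "maf",
    "accumulated_samples",
    "verdict",
    "remaining_samples",
    "odds_ratio_ci",
    "p_value",
    "i2_percent",
]


def _format_or_ci(or_: float, lo: float, hi: float) -> str:
    return f"{or_:.2f} ({lo:.2f} to {hi:.2f})"


def write_report(rows: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write a verdict table as delimited text with documented formatting.

    Each row mapping must supply ``locus_id, ethnicity, articles, maf,
    accumulated_samples, verdict, remaining_samples, odds_ratio, ci_low,
    ci_high, p_value, i2_percent``.  ORs and CI bounds print to 2 decimal
    places (combined into one ``odds_ratio_ci`` cell), p-values to 4, I-squared
    as an integer percent.  An empty row list yields a header-only file.
    """
    out = []
    for r in rows:
        out.append(
            {
                "locus_id": r["locus_id"],
                "ethnicity": r["ethnicity"],
                "articles": int(r["articles"]),
                "maf": f"{float(r['maf']):.2f}",
                "accumulated_samples": int(r["accumulated_samples"]),
                "verdict": r["verdict"],
                "remaining_samples": int(r["remaining_samples"]),
                "odds_ratio_ci": _format_or_ci(
                    float(r["odds_ratio"]), float(r["ci_low"]), float(r["ci_high"])
                ),
                "p_value": f"{float(r['p_value']):.4f}",
                "i2_percent": int(round(float(r["i2_percent"]))),
            }
        )
    pd.DataFrame(out, columns=REPORT_COLUMNS).to_csv(path, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`.

    The combined ``odds_ratio_ci`` cell is split into numeric ``odds_ratio``,
    ``ci_low`` and ``ci_high`` columns (at the written 2-decimal precision).
    """
    df = pd.read_csv(path, dtype={"locus_id": str, "ethnicity": str, "verdict": str})
    if list(df.columns) != REPORT_COLUMNS:
        raise StudyParseError(f"{path}: unexpected report columns {list(df.columns)}")
    if len(df):
        parts = df["odds_ratio_ci"].str.extract(
            r"^(?P<odds_ratio>[\d.]+) \((?P<ci_low>[\d.]+) to (?P<ci_high>[\d.]+)\)$"
        )
        for col in ("odds_ratio", "ci_low", "ci_high"):
            df[col] = parts[col].astype(float)
    else:
        for col in ("odds_ratio", "ci_low", "ci_high"):
            df[col] = pd.Series(dtype=float)
    return df
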