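"""Packaged summary of published per-locus osteoporosis candidate-gene results.

The table holds, per locus and ethnicity stratum, the published pooled
allele-model odds ratio with 95% CI, p-value, I-squared, accumulated
subject count and sequential verdict for 17 Caucasian and 15 Asian gene
loci.  These are display/regression fixtures: the per-study counts behind
them are not part of the package, so the pooled values cannot be
recomputed here — they exercise the report and cross-tabulation layers
(e.g. the I-squared > 50% heterogeneity rule reproduces the published
9 high / 8 low Caucasian and 6 high / 9 low Asian splits).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classifier import DgsVerdict, HetLabel, VerdictCategory, heterogeneity_label

__all__ = ["load_published_summary", "published_verdicts"]


def load_published_summary() -> pd.DataFrame:
    """The published per-locus summary table as a DataFrame."""
    with resources.files("decigene.data").joinpath("published_summary.csv").open() as fh:
        return pd.read_csv(fh, dtype={"ethnicity": str, "locus_id": str, "verdict": str})


def published_verdicts(ethnicity: str | None = None) -> list[DgsVerdict]:
    """The published rows as verdict objects (pooled details omitted).

    The heterogeneity label is derived from the printed I-squared column by
    the package's own strict >50% rule.
    """
    df = load_published_summary()
    if ethnicity is not None:
        df = df[df["ethnicity"] == ethnicity.lower()]
    verdicts = []
    for _, row in df.iterrows():
        verdicts.append(
            DgsVerdict(
                locus_id=row["locus_id"],
                ethnicity=row["ethnicity"],
                category=VerdictCategory(row["verdict"]),
                remaining_subjects=int(row["remaining_samples"]),
                het_label=heterogeneity_label(float(row["i2_percent"])),
            )
        )
    return verdicts
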