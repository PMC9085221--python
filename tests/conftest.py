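import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from decigene import EffectEstimate, Ethnicity, StudyRecord


@pytest.fixture
def three_effects():
    """Three unequal studies with visible spread on the log-OR scale."""
    return [
        EffectEstimate(log_or=0.40, se=0.20, study_id="a", year=2001, subjects=400),
        EffectEstimate(log_or=-0.10, se=0.35, study_id="b", year=2003, subjects=150),
        EffectEstimate(log_or=0.75, se=0.15, study_id="c", year=2005, subjects=700),
    ]


@pytest.fixture
def study_rows():
    """Three well-formed study rows, deliberately out of year order."""
    return [
        "study_id,year,ethnicity,locus_id,case_AA,case_Aa,case_aa,ctrl_AA,ctrl_Aa,ctrl_aa",
        "smith2005,2005,caucasian,rs123,70,20,10,80,15,5",
        "ahn2001,2001,Asian,rs123,50,40,10,55,35,10",
        "li2003,2003,asian,rs123,60,30,10,58,32,10",
    ]


@pytest.fixture
def study_file(tmp_path, study_rows):
    path = tmp_path / "studies.csv"
    path.write_text("\n".join(study_rows) + "\n")
    return path


@pytest.fixture
def locus_config_file(tmp_path):
    path = tmp_path / "loci.yaml"
    path.write_text("rs123:\n  maf: 0.30\n  assumed_or: 1.5\n  d2: 0.8\n")
    return path


def make_record(
    study_id="s1",
    year=2000,
    ethnicity=Ethnicity.CAUCASIAN,
    locus_id="rs1",
    case=(70, 20, 10),
    ctrl=(80, 15, 5),
):
    return StudyRecord(
        study_id=study_id,
        year=year,
        ethnicity=ethnicity,
        locus_id=locus_id,
        case_genotypes=case,
        control_genotypes=ctrl,
    )
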