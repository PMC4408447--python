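import numpy as np
import pytest

from aldorecur import simulate
from aldorecur.labs import CensoredMeasure, LabPanel


@pytest.fixture(scope="session")
def wt_params():
    return simulate.default_params("WT")


@pytest.fixture(scope="session")
def mut_params():
    return simulate.default_params("M1549V")


@pytest.fixture(scope="session")
def wt_iv(wt_params):
    return simulate.iv_ensemble(wt_params)


@pytest.fixture(scope="session")
def mut_iv(mut_params):
    return simulate.iv_ensemble(mut_params)


@pytest.fixture(scope="session")
def kindred_panels():
    """Laboratory panels of the carrier/non-carrier family members.

    One row is dropped because its published aldosterone/PRA/ratio values are
    not mutually consistent.  The second carrier's direct renin is
    back-computed from the published aldosterone/direct-renin ratio (22 /
    37.3).
    """

    def m(v, rel="equal", units=""):
        return CensoredMeasure(v, rel, units)

    carriers = [
        LabPanel(
            aldosterone=m(37, units="ng/dl"),
            pra=m(0.42, units="ng/ml/hr"),
            potassium=m(3.7, units="mmol/l"),
            subject="1390-1",
        ),
        LabPanel(
            aldosterone=m(22, units="ng/dl"),
            direct_renin=m(22 / 37.3, units="uIU/ml"),
            potassium=m(3.5, units="mmol/l"),
            subject="1390-2",
        ),
    ]
    non_carriers = [
        LabPanel(
            aldosterone=m(2, units="ng/dl"),
            pra=m(1.65, units="ng/ml/hr"),
            potassium=m(4.3, units="mmol/l"),
            subject="1390-4",
        ),
        LabPanel(
            aldosterone=m(1, "below", "ng/dl"),
            pra=m(2.25, units="ng/ml/hr"),
            potassium=m(3.8, units="mmol/l"),
            subject="1390-8",
        ),
        LabPanel(
            aldosterone=m(4, units="ng/dl"),
            pra=m(1.87, units="ng/ml/hr"),
            potassium=m(4.0, units="mmol/l"),
            subject="1390-6",
        ),
        LabPanel(
            aldosterone=m(3, units="ng/dl"),
            pra=m(1.67, units="ng/ml/hr"),
            potassium=m(4.3, units="mmol/l"),
            subject="1390-7",
        ),
    ]
    return {"carriers": carriers, "non_carriers": non_carriers}


@pytest.fixture()
def toy_map():
    """10-marker symmetric map, constant ancestral-allele frequency 0.6."""
    mmap, ancestral = simulate.default_marker_map(
        n_per_side=5, spacing_bp=50_000, freq=0.6, focal_bp=1_000_000
    )
    return mmap, ancestral
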