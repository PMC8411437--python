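import numpy as np
import pytest

from addikit.instrument import canonical_addi
from addikit.scoring import CaseRecord, Evidence


@pytest.fixture(scope="session")
def instr():
    return canonical_addi()


@pytest.fixture
def female_child_case():
    def _make(evidence, case_id="c1", disease="CAPS", age=12.0, sex="female"):
        return CaseRecord(
            case_id=case_id, disease=disease, age_years=age, sex=sex, evidence=evidence
        )

    return _make


def asserted(item_id, grade="present", duration=12.0, **kw):
    return Evidence(
        item_id=item_id, mode="asserted", asserted_grade=grade,
        duration_months=duration, **kw,
    )


def measured(item_id, measurements, duration=12.0, **kw):
    return Evidence(
        item_id=item_id, mode="measured", measurements=measurements,
        duration_months=duration, **kw,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
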