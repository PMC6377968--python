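import numpy as np
import pytest

import oxyloop as ox


def reference_patient(phenotype: ox.Phenotype, **overrides) -> ox.VirtualPatient:
    """A virtual patient at the cohort-central admission state, on room air."""
    if phenotype is ox.Phenotype.HYPERCAPNIC:
        paco2 = 55.0
        hco3 = 24.0 + 0.35 * (paco2 - 40.0)
    else:
        paco2 = 38.0
        hco3 = 24.0
    pao2 = 52.73
    admission = ox.BloodGas(
        pao2=pao2,
        paco2=paco2,
        ph=ox.ph_from_paco2(paco2, hco3),
        spo2=ox.spo2_from_pao2(pao2),
        fio2=0.21,
    )
    overrides.setdefault("seed", 7)
    params, state = ox.init_from_admission(admission, phenotype, hco3=hco3, **overrides)
    return ox.VirtualPatient(params, state, patient_id=f"ref-{phenotype.value}")


@pytest.fixture
def hypercapnic_cfg() -> ox.ControllerConfig:
    return ox.default_config(ox.Phenotype.HYPERCAPNIC)


@pytest.fixture
def hypoxemic_cfg() -> ox.ControllerConfig:
    return ox.default_config(ox.Phenotype.PURELY_HYPOXEMIC)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
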