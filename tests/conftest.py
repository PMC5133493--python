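import pandas as pd
import pytest

from comorbnet.data_model import DiagnosisTable
from comorbnet.simulate import default_scenario, write_input_bundle


def make_diag(rows):
    """rows: iterable of (patient_id, code, age, sex)."""
    return DiagnosisTable(
        pd.DataFrame(rows, columns=["patient_id", "code", "age", "sex"])
    )


@pytest.fixture(scope="session")
def study():
    """Standard synthetic study: 20k patients, planted RR 3.0/2.0/1.2 and
    shared-gene counts 20/10/2 for DG1/DG2/DG3 versus index code 496."""
    return default_scenario(seed=1, n_patients=20_000)


@pytest.fixture(scope="session")
def study_bundle(study, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return write_input_bundle(study, outdir)
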