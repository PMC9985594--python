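import pandas as pd
import pytest

from ocspatterns import simulate


@pytest.fixture(scope="session")
def sim_bundle():
    """Medium synthetic cohort shared by read-only tests."""
    return simulate.generate(simulate.SimulationConfig(n_patients=120, seed=7))


@pytest.fixture()
def csv_dir(tmp_path, sim_bundle):
    """The three input tables written as CSVs."""
    for name, df in (("patients", sim_bundle.patients),
                     ("prescriptions", sim_bundle.prescriptions),
                     ("events", sim_bundle.events)):
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(tmp_path / f"{name}.csv", index=False)
    return tmp_path
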