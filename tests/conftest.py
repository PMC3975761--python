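from dataclasses import replace
from pathlib import Path

import pytest

from ffqkit.data_model import DataModel, load_data_model
from ffqkit.intake_engine import compute_cohort
from ffqkit.questionnaire_io import read_cohort
from ffqkit.synthetic_fixtures import TOY, FixtureSpec, generate_cohort, generate_data_model


@pytest.fixture(scope="session")
def toy_spec() -> FixtureSpec:
    return replace(TOY, seed=7, n_participants=30)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, toy_spec) -> Path:
    d = tmp_path_factory.mktemp("bundle")
    generate_data_model(toy_spec, d)
    return d


@pytest.fixture(scope="session")
def dm(bundle_dir) -> DataModel:
    return load_data_model(bundle_dir)


@pytest.fixture(scope="session")
def cohort_path(tmp_path_factory, dm, toy_spec) -> Path:
    p = tmp_path_factory.mktemp("cohort") / "cohort.csv"
    generate_cohort(dm, toy_spec, p)
    return p


@pytest.fixture(scope="session")
def cohort(cohort_path, dm):
    records, issues = read_cohort(cohort_path, dm)
    return records


@pytest.fixture(scope="session")
def intakes_and_log(cohort, dm):
    return compute_cohort(cohort, dm)


@pytest.fixture(scope="session")
def intakes(intakes_and_log):
    return intakes_and_log[0]
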