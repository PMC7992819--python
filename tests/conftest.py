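import pytest

from ontotab import encoding, fixtures, recognition


@pytest.fixture(scope="session")
def fixture_spec() -> fixtures.FixtureSpec:
    """Default-settings synthetic bundle specification."""
    return fixtures.FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def fixture_columns(fixture_spec):
    by_ds = fixtures.generate_columns(fixture_spec)
    return [c for cols in by_ds.values() for c in cols]


@pytest.fixture(scope="session")
def fixture_pairs(fixture_spec, fixture_columns):
    return encoding.build_pairs(
        fixture_columns,
        fixture_spec.class_labels(),
        method=encoding.CONTINUOUS,
        categories=fixture_spec.categories(),
    )


@pytest.fixture(scope="session")
def fixture_split(fixture_pairs):
    return encoding.split(fixture_pairs, 0.8, seed=11)


@pytest.fixture(scope="session")
def trained_model(fixture_split):
    train, _ = fixture_split
    return recognition.train_nne(train, recognition.TrainingConfig(seed=11, epochs=10))


@pytest.fixture(scope="session")
def mock_index_data(fixture_spec):
    return fixtures.generate_mock_ontology(fixture_spec)
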