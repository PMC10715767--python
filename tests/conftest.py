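import pandas as pd
import pytest

from plateparse.fixtures import generate_fixture, style_catalog


@pytest.fixture(scope="session")
def catalog_bundles():
    """All catalog fixtures generated once per session, keyed by style name."""
    return {style.name: generate_fixture(style) for style in style_catalog()}


@pytest.fixture(scope="session")
def written_bundles(catalog_bundles, tmp_path_factory):
    """Catalog fixtures written to disk once: {name: {kind: path}}."""
    root = tmp_path_factory.mktemp("bundles")
    return {
        name: bundle.write(root / name)
        for name, bundle in catalog_bundles.items()
    }


def assert_tables_equal(got: pd.DataFrame, want: pd.DataFrame) -> None:
    """Value-exact table comparison, indifferent to int/float dtype width."""
    pd.testing.assert_frame_equal(
        got.reset_index(drop=True),
        want.reset_index(drop=True),
        check_dtype=False,
        check_exact=True,
    )
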