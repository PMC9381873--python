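import numpy as np
import pytest

from pharmdemand import ChainPanel, WeeklySeries, generate_chain, table9_specs, table_fixtures


@pytest.fixture(scope="session")
def chain_no_shortage() -> WeeklySeries:
    """The packaged 13-week chain series with uninterrupted supply."""
    return table_fixtures()[0]


@pytest.fixture(scope="session")
def chain_shortage() -> WeeklySeries:
    """The packaged 13-week chain series with shortage weeks 8-9."""
    return table_fixtures()[1]


@pytest.fixture(scope="session")
def panel_8x13() -> ChainPanel:
    """A seeded 8-pharmacy x 13-week panel without shortages."""
    return generate_chain(table9_specs(shortage=False), seed=42)


@pytest.fixture(scope="session")
def shortage_panel() -> ChainPanel:
    """A seeded 8-pharmacy x 13-week panel with the shortage pattern."""
    return generate_chain(table9_specs(shortage=True), seed=42)


def series(values, series_id="s") -> WeeklySeries:
    """Shorthand: build a series from raw values (sentinels auto-flagged)."""
    return WeeklySeries.from_values(series_id, np.asarray(values, dtype=float))
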