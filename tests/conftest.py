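import numpy as np
import pytest

from fruitflux import (
    LayoutSpec,
    TransportParameters,
    build_layout,
    conceptual_table,
    solve_scenario,
)


@pytest.fixture(scope="session")
def tiny_layout():
    """Minimal 8-cell ring (one file and one row per tissue), ~100 sites."""
    spec = LayoutSpec(
        stage="15",
        rows=1,
        valve_files=1,
        replum_files=1,
        valve_width=4.0,
        replum_width=4.0,
        vm_width=4.0,
        cell_height=4.0,
    )
    return build_layout(spec)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced divided-VM layout: fast solves, all tissues present."""
    return LayoutSpec(
        stage="17b",
        rows=6,
        valve_files=3,
        replum_files=3,
        valve_width=16.0,
        replum_width=12.0,
        vm_width=8.0,
        cell_height=16.0,
    )


@pytest.fixture(scope="session")
def small_layout(small_spec):
    return build_layout(small_spec)


@pytest.fixture(scope="session")
def meso_layout():
    """Reduced-height layout with the default cell dimensions.

    Sweep and regime behaviour depends on realistic cell proportions, so
    these tests use the default widths/heights with fewer rows and files.
    """
    return build_layout(LayoutSpec(stage="17b", rows=6, valve_files=3))


@pytest.fixture(scope="session")
def params():
    return TransportParameters()


@pytest.fixture(scope="session")
def basic_state(small_layout, params):
    return solve_scenario(small_layout, conceptual_table("basic"), params)


@pytest.fixture(scope="session")
def export_state(small_layout, params):
    return solve_scenario(small_layout, conceptual_table("export"), params)


@pytest.fixture(scope="session")
def import_state(small_layout, params):
    return solve_scenario(small_layout, conceptual_table("import"), params)
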