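import pytest

from nanoyap import (IndentationSpec, build_cell_geometry, build_nucleus,
                     indent_nucleus, load_params)
from nanoyap.pipeline import (DEFAULT_SUBSTRATES, INDENT_SUBSTRATE,
                              substrate_from_config, undeformed_ne_patches)

COARSE_GRID = 0.05  # µm; test-suite resolution for indentation fields


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def flat_geometry(params):
    return build_cell_geometry(
        substrate_from_config(DEFAULT_SUBSTRATES["flat"]),
        params.v_cyto, params.v_nuc)


@pytest.fixture(scope="session")
def pillar_geometry(params):
    return build_cell_geometry(
        substrate_from_config(DEFAULT_SUBSTRATES["pillars_p2.5"]),
        params.v_cyto, params.v_nuc)


@pytest.fixture(scope="session")
def tall_pillar_substrate():
    """Indentation-experiment substrate: 0.5 µm radius, 3 µm tall pillars."""
    return substrate_from_config(INDENT_SUBSTRATE)


@pytest.fixture(scope="session")
def nucleus(params):
    return build_nucleus(params.v_nuc,
                         aspect_ratio=params.nuclear_aspect_ratio)


@pytest.fixture(scope="session")
def indented_28(nucleus, tall_pillar_substrate):
    """Deep (2.8 µm) indentation on the tall-pillar substrate."""
    return indent_nucleus(nucleus, tall_pillar_substrate,
                          IndentationSpec(depth=2.8, grid_um=COARSE_GRID))


@pytest.fixture(scope="session")
def ne_undeformed(params):
    return undeformed_ne_patches(params)


@pytest.fixture(scope="session")
def flat_steady(flat_geometry, ne_undeformed, params):
    from nanoyap.signaling import assemble_rhs, initial_state, simulate

    rhs = assemble_rhs(flat_geometry, ne_undeformed, params)
    return simulate(rhs, initial_state(params), params=params)
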