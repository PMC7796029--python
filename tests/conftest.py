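"""Shared fixtures: a seeded synthetic marker set and the panel designed
from it (session-scoped — panel assembly is the expensive step)."""

from __future__ import annotations

import pytest

from primerpanel.design import assemble_panel
from primerpanel.seqio import Primer, load_packaged_primers
from primerpanel.simulate import SimulationConfig, simulate_marker_set

# the published universal 16S pair, also used to flank the simulated marker
UNIVERSAL_16S_F = "AAGGGCCGCGGTAACTCTG"
UNIVERSAL_16S_R = "ACCCTGTTATCCCCGTGGT"


@pytest.fixture(scope="session")
def universal_primers() -> tuple[Primer, Primer]:
    return (
        Primer("P16sf", UNIVERSAL_16S_F, "forward", "universal"),
        Primer("S16sr", UNIVERSAL_16S_R, "reverse", "universal"),
    )


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(
        seed=1,
        universal_forward=UNIVERSAL_16S_F,
        universal_reverse=UNIVERSAL_16S_R,
    )


@pytest.fixture(scope="session")
def sim_set(sim_config):
    seq_set, truth = simulate_marker_set(sim_config)
    return seq_set, truth


@pytest.fixture(scope="session")
def panel(sim_set, universal_primers):
    seq_set, _ = sim_set
    uf, ur = universal_primers
    return assemble_panel(seq_set, uf, ur, marker="16s", orientation="reverse")


@pytest.fixture(scope="session")
def packaged_16s():
    return load_packaged_primers("16s")


@pytest.fixture(scope="session")
def packaged_coi():
    return load_packaged_primers("coi")
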