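import numpy as np
import pytest

from y1hscreen import (
    ArrayMap,
    ColonyRecord,
    PlantedInteraction,
    PlateMeta,
    generate_screen,
    small_config,
)


@pytest.fixture(scope="session")
def full_plate_records():
    """A complete 32x48 plate, every colony present, circular, 148 pixels."""
    return [
        ColonyRecord(r, c, 148, True, True)
        for r in range(1, 33)
        for c in range(1, 49)
    ]


@pytest.fixture(scope="session")
def tiny_array():
    """A 16x24 array map with TFs everywhere except 8 AD-only controls and
    trailing empty positions."""
    return ArrayMap.from_tf_list("p1", [f"TF{i:04d}" for i in range(1, 361)])


@pytest.fixture(scope="session")
def plate_meta():
    return PlateMeta(
        plate_id="mel_A1_10mM_d7_p1",
        bait_id="mel_A1",
        species="mel",
        selection_3at_mM=10,
        day=7,
        tf_array_id="p1",
    )


@pytest.fixture(scope="session")
def planted_screen():
    """A reduced screen with two strong planted interactions (boost = 5*sigma0
    at two 3AT levels each) plus defaults otherwise."""
    cfg = small_config(
        n_baits=2,
        n_tfs=360,
        interactions=[
            PlantedInteraction("mel_A1", "TF0010", {10: 1.5, 20: 1.5}),
            PlantedInteraction("mel_A2", "TF0200", {20: 1.5, 40: 1.5}),
        ],
    )
    return generate_screen(cfg, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
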