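import datetime as dt

import numpy as np
import pytest

from adlsense.domain import (
    CHANNELS,
    DataPacket,
    HomeLayout,
    default_layout,
)


@pytest.fixture
def layout() -> HomeLayout:
    return default_layout()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230306)


def make_random_packet(rng: np.random.Generator, node_ids) -> DataPacket:
    return DataPacket(
        node_id=int(rng.choice(node_ids)),
        date=dt.date(2023, 1, 1) + dt.timedelta(days=int(rng.integers(0, 400))),
        timestamp=int(rng.integers(0, 17280)) * 5,
        supply_voltage=round(float(rng.uniform(2.0, 3.3)), 4),
        status_word=int(rng.integers(0, 2**16)),
        values=(
            round(float(rng.uniform(-10, 40)), 3),
            round(float(rng.uniform(0, 30)), 3),
            round(float(rng.uniform(0, 1000)), 3),
            float(rng.integers(0, 2)),
            round(float(rng.uniform(0, 10)), 3),
        ),
    )


def make_random_packets(n: int, rng: np.random.Generator, layout):
    node_ids = layout.node_ids if isinstance(layout, HomeLayout) else list(layout)
    return [make_random_packet(rng, node_ids) for _ in range(n)]
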