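"""Shared synthetic fixtures, generated at test time (no packaged data)."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from remowear import accel
from remowear.synth import ActivityScript, Segment, generate_accel


@pytest.fixture(scope="session")
def gait_bout():
    """120 s of clean 110 steps/min gait with ground truth."""
    script = ActivityScript(
        segments=[Segment("gait", 120, cadence=110, amplitude_g=0.3)], seed=11
    )
    raw, truth = generate_accel(script)
    return accel.counts_to_g(raw), truth


@pytest.fixture(scope="session")
def mixed_record():
    """1 h wear, 100 min non-wear, 80 min wear — exercises the mask rules."""
    script = ActivityScript(
        segments=[
            Segment("stationary_wear", 3600),
            Segment("nonwear", 100 * 60),
            Segment("stationary_wear", 80 * 60),
        ],
        seed=13,
    )
    raw, truth = generate_accel(script)
    acc = accel.counts_to_g(raw)
    return acc, accel.epochize(acc), truth


@pytest.fixture
def constant_series():
    """Noiseless 1 g on z at 10 Hz for 5 min."""
    n = 3000
    return accel.AccelSeries(
        t=np.arange(n) / 10.0, x=np.zeros(n), y=np.zeros(n), z=np.ones(n)
    )


@pytest.fixture
def anchor_9am():
    return datetime(2026, 1, 10, 9, 0)
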