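import numpy as np
import pytest

from aecclamp import (
    NoiseProtocol,
    RigConfig,
    VirtualRig,
    estimate_full_kernel,
    generate_probe_current,
    separate_kernels,
)

# Ground-truth model cell: fast 50 MΩ / 0.35 ms electrode in series with a
# 50 MΩ / 23 ms passive membrane (the package defaults).
MODEL_RE = 50.0
MODEL_TAUE = 0.35
MODEL_RM = 50.0
MODEL_TAUM = 23.0


@pytest.fixture(scope="session")
def model_cell_config():
    return RigConfig(rng_seed=1)


@pytest.fixture(scope="session")
def probe_recording(model_cell_config):
    """Default 10 kHz / 0.5 nA / 5 s probe response of the model cell."""
    rig = VirtualRig(model_cell_config)
    proto = NoiseProtocol(rng_seed=1)
    probe = generate_probe_current(proto)
    rec = rig.record(probe, proto.dt)
    return proto, rec


@pytest.fixture(scope="session")
def default_separation(probe_recording):
    """Full kernel (50 ms) and separation (3 ms electrode support)."""
    proto, rec = probe_recording
    full, offset = estimate_full_kernel(
        rec["I"], rec["V_raw"], 500, bin_width=proto.dt
    )
    sep = separate_kernels(full, 30)
    return full, offset, sep


class SpikyRig(VirtualRig):
    """Rig whose recordings are corrupted by spike-like depolarizations.

    Emulates a cell firing during a measurement: smooth 2 ms-wide bumps
    are added to the raw voltage at random positions (different on every
    recording, like real evoked activity).
    """

    def __init__(self, config, n_spikes=3, height=60.0, seed=0):
        super().__init__(config)
        self.n_spikes = n_spikes
        self.height = height
        self._spike_rng = np.random.default_rng(seed)

    def record(self, I, dt):
        rec = super().record(I, dt)
        n = len(rec["t"])
        half = max(3, int(round(1.0 / dt)))  # 2 ms total width
        for _ in range(self.n_spikes):
            if n <= 2 * half + 2:
                break
            c = int(self._spike_rng.integers(half + 1, n - half - 1))
            idx = np.arange(c - half, c + half + 1)
            rec["V_raw"][idx] += self.height * 0.5 * (
                1.0 + np.cos(np.pi * (idx - c) / half)
            )
        return rec
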