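import numpy as np
import pytest

from gazeskill.gaze_io import GazeRecording, GazeSample
from gazeskill.synthgen import SynthConfig, generate_dataset


@pytest.fixture
def make_recording():
    """Factory for small hand-built recordings."""

    def _make(trial_id="t0", participant_id="p0", n=10, n_valid=None, seed=0):
        rng = np.random.default_rng(seed)
        if n_valid is None:
            n_valid = n
        samples = [
            GazeSample(
                t=float(i),
                x=float(rng.normal()),
                y=float(rng.normal()),
                valid=i < n_valid,
            )
            for i in range(n)
        ]
        return GazeRecording(trial_id, participant_id, samples)

    return _make


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(
        n_per_class=4,
        series_len=150,
        motif_len=20,
        frames_per_trial=4,
        frame_size=32,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory, small_cfg):
    d = tmp_path_factory.mktemp("synth") / "ds"
    generate_dataset(small_cfg, d)
    return d
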