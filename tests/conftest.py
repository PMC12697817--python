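import numpy as np
import pytest

from protodyn.signal_io import TimeSeries


@pytest.fixture
def tone():
    """Pure 0.1 Hz sinusoid, amplitude 5, fs 1 Hz, 4096 samples."""
    t = np.arange(4096.0)
    return TimeSeries(t, 5.0 * np.sin(2 * np.pi * 0.1 * t), unit="mV", label="tone")


@pytest.fixture
def write_csv(tmp_path):
    """Write a (time, value) CSV and return its path; cells may be strings."""

    def _write(times, values, name="data.csv", header="time_s,value"):
        path = tmp_path / name
        lines = [header] + [f"{t},{v}" for t, v in zip(times, values)]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
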