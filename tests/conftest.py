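import numpy as np
import pytest

import spiketype as st


def dataset_to_spikes(dataset, threshold_mv=-20.0):
    """Standard front half of the pipeline: preprocess, detect, extract."""
    parts = []
    for trace in dataset.traces:
        clean = st.preprocess(trace)
        markers = st.detect_peaks(clean, threshold_mv)
        parts.append(st.extract_spikes(clean, markers))
    return st.SpikeSet.concat(parts)


@pytest.fixture(scope="session")
def paper3_dataset():
    """Small three-class dataset shared by read-only tests."""
    specs = st.preset_specs("paper3", n_neurons=2, spikes_per_neuron=40)
    return st.make_dataset(specs, seed=11)


@pytest.fixture(scope="session")
def paper3_spikes(paper3_dataset):
    return dataset_to_spikes(paper3_dataset)


@pytest.fixture()
def triangle_spike():
    """60-sample epoch at 20 kHz: linear rise −60→0 mV over 1 ms, mirror fall."""
    x = np.full(60, -60.0)
    x[:21] = np.linspace(-60.0, 0.0, 21)
    x[20:41] = np.linspace(0.0, -60.0, 21)
    return st.SpikeSet(
        waveforms=x[None, :], peak_offset=20, fs=20000.0, pre_ms=1.0, post_ms=2.0
    )
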