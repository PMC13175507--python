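import numpy as np
import pytest

from flickervig.spectral import EpochSet


def epochs_from_array(data: np.ndarray, sfreq: float = 512.0,
                      ch_names=None) -> EpochSet:
    """Wrap a (trials, channels, samples) array as an EpochSet."""
    data = np.asarray(data, float)
    if ch_names is None:
        ch_names = [f"CH{i + 1}" for i in range(data.shape[1])]
    return EpochSet(data=data, sfreq=sfreq, ch_names=list(ch_names),
                    trial_indices=np.arange(data.shape[0]))


def epochs_from_recording(recording, epoch_s: float = 4.0) -> EpochSet:
    """Chop a continuous Recording into back-to-back epochs."""
    n = int(epoch_s * recording.sfreq)
    k = recording.n_samples // n
    data = np.stack([recording.data[:, i * n:(i + 1) * n] for i in range(k)])
    return EpochSet(data=data, sfreq=recording.sfreq,
                    ch_names=list(recording.ch_names),
                    trial_indices=np.arange(k))


def sinusoid_pair_epochs(n_epochs: int, lags, f0: float = 10.0,
                         sfreq: float = 512.0, epoch_samples: int = 1024,
                         phases=None) -> EpochSet:
    """Two-channel sinusoid epochs; channel y lags channel x by lags[i] rad."""
    t = np.arange(epoch_samples) / sfreq
    if phases is None:
        phases = np.zeros(n_epochs)
    lags = np.broadcast_to(np.asarray(lags, float), (n_epochs,))
    segs = [np.stack([np.sin(2 * np.pi * f0 * t + ph),
                      np.sin(2 * np.pi * f0 * t + ph - lag)])
            for ph, lag in zip(phases, lags)]
    return epochs_from_array(np.stack(segs), sfreq=sfreq, ch_names=["x", "y"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
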