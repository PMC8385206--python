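"""Trial-wise spectral phases and inter-trial phase coherence (ITPC).

The DFT is computed per trial and electrode on the trimmed 14.08 s epochs
(frequency step 1/14.08 s ~ 0.071 Hz, so the 0.78125/1.5625/3.125 Hz
target rates fall exactly on bins 11/22/44 -- no taper or zero padding is
applied for precisely this reason).  With theta_k the phase angle of the
complex Fourier coefficient of trial k and R = |K^-1 sum_k exp(i theta_k)|
the resultant length, three conventions are exposed:

* ``resultant_length``  : R in [0, 1] (default; the common M/EEG ITPC)
* ``squared_resultant`` : R^2 in [0, 1]
* ``literal_eq1``       : K * R^2 = (sum cos)^2/K + (sum sin)^2/K in [0, K]

The third is the coherence statistic written as a per-trial-count-scaled
squared resultant; it is unbounded above 1 and is kept selectable because
either normalisation appears in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .design import InvalidParameterError
from .simulate import EpochSet

__all__ = [
    "SpectralPhases",
    "ITPCMap",
    "trial_phases",
    "itpc_from_phases",
    "compute_itpc",
    "resultant_length",
    "CONVENTIONS",
]

CONVENTIONS = ("resultant_length", "squared_resultant", "literal_eq1")
Convention = Literal["resultant_length", "squared_resultant", "literal_eq1"]


class InsufficientTrialsError(ValueError):
    """Phase coherence over fewer than 2 trials is undefined."""


@dataclass
class SpectralPhases:
    """Per-trial phase angles at every one-sided DFT bin and electrode."""

    theta: np.ndarray  # (trials, electrodes, freqs), radians in (-pi, pi]
    freqs: np.ndarray  # (freqs,), Hz
    K: int

    @property
    def freq_step(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def bin_of(self, freq: float) -> int:
        """Index of the DFT bin nearest ``freq`` (exact for on-bin rates)."""
        return int(np.argmin(np.abs(self.freqs - freq)))


@dataclass
class ITPCMap:
    """Electrodes x frequencies phase-coherence values for one dataset."""

    values: np.ndarray  # (electrodes, freqs)
    freqs: np.ndarray
    convention: str
    K: int

    def bin_of(self, freq: float) -> int:
        return int(np.argmin(np.abs(self.freqs - freq)))

    def at(self, freq: float) -> np.ndarray:
        """Per-electrode values at the bin nearest ``freq``."""
        return self.values[:, self.bin_of(freq)]

    def electrode_average(self) -> np.ndarray:
        return self.values.mean(axis=0)


def trial_phases(epochs: EpochSet) -> SpectralPhases:
    """One-sided DFT phases per trial and electrode of trimmed epochs."""
    import scipy.fft as sfft

    if not epochs.trimmed:
        raise InvalidParameterError("epochs must be trimmed to the analysed window first")
    data = epochs.data if epochs.data.dtype in (np.float32, np.float64) else np.asarray(epochs.data, float)
    spec = sfft.rfft(data, axis=-1)  # preserves single precision
    freqs = np.fft.rfftfreq(epochs.n_samples, d=1.0 / epochs.sampling_rate)
    return SpectralPhases(theta=np.angle(spec), freqs=freqs, K=epochs.n_trials)


def resultant_length(theta: np.ndarray, axis: int = 0) -> np.ndarray:
    """Length of the mean unit phasor |K^-1 sum exp(i theta)| along ``axis``."""
    return np.abs(np.exp(1j * theta).mean(axis=axis))


def itpc_from_phases(
    phases: SpectralPhases, convention: Convention = "resultant_length"
) -> ITPCMap:
    """Collapse per-trial phases into an electrodes x frequencies ITPC map."""
    if phases.K < 2:
        raise InsufficientTrialsError("ITPC requires at least 2 trials")
    if convention not in CONVENTIONS:
        raise InvalidParameterError(f"convention must be one of {CONVENTIONS}")
    r = resultant_length(phases.theta, axis=0)
    if convention == "resultant_length":
        values = r
    elif convention == "squared_resultant":
        values = r**2
    else:
        values = phases.K * r**2
    return ITPCMap(values=values, freqs=phases.freqs, convention=convention, K=phases.K)


def compute_itpc(epochs: EpochSet, convention: Convention = "resultant_length") -> ITPCMap:
    """Convenience: phases + ITPC in one call."""
    return itpc_from_phases(trial_phases(epochs), convention)
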