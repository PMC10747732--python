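"""Truncated Fourier-series codes for periodic gait signals.

A running stride is periodic, so any kinematic or acceleration channel can
be compressed to a handful of Fourier coefficients.  Throughout the package
a channel is described by 11 numbers: the DC (mean) term plus five sine and
five cosine coefficients of the stride's fundamental frequency,

    s(t) = dc + sum_{k=1..5} cosine[k] * cos(k w t) + sine[k] * sin(k w t),

with w = 2 pi * fundamental_frequency.  Five harmonics are enough to
describe smooth gait signals, and the fixed truncation gives every channel
the same dimensionality regardless of sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_HARMONICS = 5
#: numbers per channel: DC + N_HARMONICS sines + N_HARMONICS cosines
N_COEFFICIENTS = 1 + 2 * N_HARMONICS


@dataclass(frozen=True)
class FourierCode:
    """Truncated Fourier description of one periodic channel."""

    dc: float
    sine: tuple
    cosine: tuple
    fundamental_frequency: float

    def __post_init__(self):
        if len(self.sine) != N_HARMONICS or len(self.cosine) != N_HARMONICS:
            raise ValueError(
                f"FourierCode needs exactly {N_HARMONICS} sine and cosine terms"
            )
        object.__setattr__(self, "sine", tuple(float(v) for v in self.sine))
        object.__setattr__(self, "cosine", tuple(float(v) for v in self.cosine))

    @property
    def coefficients(self) -> np.ndarray:
        """All 11 numbers in canonical order (dc, cos1..5, sin1..5)."""
        return np.concatenate(([self.dc], self.cosine, self.sine))

    def evaluate(self, t) -> np.ndarray:
        """Reconstruct the signal at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        w = 2.0 * np.pi * self.fundamental_frequency
        out = np.full(t.shape, self.dc, dtype=float)
        for k in range(1, N_HARMONICS + 1):
            out += self.cosine[k - 1] * np.cos(k * w * t)
            out += self.sine[k - 1] * np.sin(k * w * t)
        return out

    def derivative(self, order: int = 1) -> "FourierCode":
        """Term-wise time derivative (DC of any derivative is zero)."""
        w = 2.0 * np.pi * self.fundamental_frequency
        sine = np.asarray(self.sine)
        cosine = np.asarray(self.cosine)
        for _ in range(order):
            k = np.arange(1, N_HARMONICS + 1)
            # d/dt [a cos(kwt) + b sin(kwt)] = -a k w sin + b k w cos
            cosine, sine = k * w * sine, -k * w * cosine
        return FourierCode(
            dc=0.0 if order >= 1 else self.dc,
            sine=tuple(sine),
            cosine=tuple(cosine),
            fundamental_frequency=self.fundamental_frequency,
        )


def fourier_compress(window: np.ndarray, fundamental_frequency: float) -> FourierCode:
    """Compress one uniformly sampled stride to a :class:`FourierCode`.

    ``window`` must cover exactly one period with the endpoint *excluded*
    (the usual DFT convention).  Coefficients are scaled to the
    reconstruction convention of :class:`FourierCode`, i.e. for a pure
    ``sin(k w t)`` input ``sine[k] == 1``.

    Parameters
    ----------
    window:
        Uniform samples of one stride, length >= 11.
    fundamental_frequency:
        Stride frequency in Hz (1 / stride period).
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1:
        raise ValueError("window must be one-dimensional")
    n = x.size
    if n < N_COEFFICIENTS:
        raise ValueError(
            f"need at least {N_COEFFICIENTS} samples per stride, got {n}"
        )
    spec = np.fft.rfft(x)
    dc = spec[0].real / n
    ks = np.arange(1, N_HARMONICS + 1)
    cosine = 2.0 * spec[ks].real / n
    sine = -2.0 * spec[ks].imag / n
    return FourierCode(
        dc=float(dc),
        sine=tuple(sine),
        cosine=tuple(cosine),
        fundamental_frequency=float(fundamental_frequency),
    )
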