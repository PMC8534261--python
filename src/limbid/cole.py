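"""Single-dispersion Cole model for tissue impedance spectra.

Living tissue behaves electrically like a resistance ``r0`` at low
frequency (current confined to extracellular fluid) relaxing toward a
smaller resistance ``r_inf`` at high frequency (cell membranes become
transparent), with a characteristic frequency ``fc`` and a broadening
exponent ``alpha`` that flattens the dispersion.  The measured quantity
in an RMS-detecting instrument is the impedance *magnitude*, so only
``|Z(f)|`` is exposed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ColeParams", "cole_magnitude"]


@dataclass(frozen=True)
class ColeParams:
    """Parameters of a single Cole dispersion.

    Parameters
    ----------
    r_inf : float
        High-frequency resistance in ohms, ``0 < r_inf < r0``.
    r0 : float
        Low-frequency resistance in ohms.
    fc : float
        Characteristic (relaxation) frequency in Hz.
    alpha : float
        Dispersion broadening exponent in ``(0, 1]``; ``alpha = 1``
        recovers a single-time-constant Debye relaxation.
    """

    r_inf: float
    r0: float
    fc: float
    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 < self.r_inf < self.r0):
            raise ValueError(
                f"require 0 < r_inf < r0, got r_inf={self.r_inf}, r0={self.r0}"
            )
        if self.fc <= 0.0:
            raise ValueError(f"characteristic frequency must be positive, got {self.fc}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")


def cole_magnitude(params: ColeParams, frequencies: np.ndarray) -> np.ndarray:
    """Impedance magnitude ``|r_inf + (r0 - r_inf) / (1 + (i f / fc)^alpha)|``.

    Parameters
    ----------
    params : ColeParams
        Dispersion parameters.
    frequencies : array-like
        Strictly positive frequencies in Hz.

    Returns
    -------
    ndarray
        One magnitude (ohms) per frequency; non-increasing in frequency
        and bounded in ``[r_inf, r0]``.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0.0):
        raise ValueError("frequencies must be strictly positive")
    z = params.r_inf + (params.r0 - params.r_inf) / (
        1.0 + (1j * f / params.fc) ** params.alpha
    )
    return np.abs(z)
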