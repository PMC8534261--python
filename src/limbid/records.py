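"""In-memory containers for multi-electrode impedance measurements.

The device carries five electrodes: ``e0`` on the left wrist and
``e1..e4`` under the right index..little fingers.  One placement of the
hand ("session") measures the impedance magnitude spectrum of all
C(5,2) = 10 electrode pairs on a common frequency grid.  A wrist-finger
pair reads limb-plus-finger impedance in series; a finger-finger pair
reads the sum of the two finger impedances.

A study is held as a dense array of shape ``(n_sessions, 10, n_freq)``
plus a tidy metadata table, which keeps feature extraction vectorized;
:class:`SessionRecord` is the single-session view used by the
per-session operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ELECTRODES",
    "PAIRS",
    "FINGER_PAIRS",
    "WRIST_PAIRS",
    "DEFAULT_FREQUENCIES",
    "pair_index",
    "ConditionSpec",
    "SessionRecord",
    "StudyData",
]

#: Electrode ids: 0 = wrist, 1..4 = index..little finger.
ELECTRODES: tuple[int, ...] = (0, 1, 2, 3, 4)

#: Canonical ordering of the 10 unordered electrode pairs.
PAIRS: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (0, 3), (0, 4),
    (1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4),
)

#: The four wrist-to-finger pairs (limb + one finger in series).
WRIST_PAIRS: tuple[tuple[int, int], ...] = PAIRS[:4]

#: The six finger-to-finger pairs, in canonical listing order.
FINGER_PAIRS: tuple[tuple[int, int], ...] = PAIRS[4:]

_PAIR_INDEX: dict[tuple[int, int], int] = {p: i for i, p in enumerate(PAIRS)}

#: Default measurement grid: 20 kHz to 500 kHz in 20 kHz steps (25 points).
DEFAULT_FREQUENCIES: np.ndarray = np.arange(20_000.0, 500_000.0 + 1.0, 20_000.0)
DEFAULT_FREQUENCIES.setflags(write=False)


def pair_index(a: int, b: int) -> int:
    """Canonical index of the unordered electrode pair ``{a, b}``.

    Raises
    ------
    ValueError
        If ``a == b`` or either id is not a valid electrode.
    """
    if a == b:
        raise ValueError(f"electrode pair members must be distinct, got ({a}, {b})")
    key = (min(a, b), max(a, b))
    try:
        return _PAIR_INDEX[key]
    except KeyError:
        raise ValueError(f"unknown electrode pair ({a}, {b}); ids must be in 0..4") from None


@dataclass(frozen=True)
class ConditionSpec:
    """Measurement condition attached to one session.

    ``placement_factors`` are per-finger multiplicative path factors
    (1.0 = nominal contact position); ``noise_rel`` is the relative
    device noise scale.
    """

    day_index: int = 1
    hand_temp_c: float = 33.0
    placement_factors: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    noise_rel: float = 2e-5

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValueError("day_index must be >= 1")
        if self.noise_rel < 0.0:
            raise ValueError("noise_rel must be non-negative")
        if len(self.placement_factors) != 4:
            raise ValueError("placement_factors must give one factor per finger (4)")
        if any(p <= 0.0 for p in self.placement_factors):
            raise ValueError("placement factors must be positive")


@dataclass
class SessionRecord:
    """One placement of the device: the 10 channel spectra plus metadata."""

    subject_id: str
    day_index: int
    repeat_index: int
    frequencies: np.ndarray
    channels: np.ndarray  # shape (10, n_freq), rows in PAIRS order
    condition: ConditionSpec | None = None
    placement_label: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.shape != (len(PAIRS), self.frequencies.size):
            raise ValueError(
                f"channels must have shape (10, {self.frequencies.size}), "
                f"got {self.channels.shape}"
            )

    @classmethod
    def from_pairs(
        cls,
        pairs: Mapping[tuple[int, int], np.ndarray],
        frequencies: np.ndarray,
        subject_id: str = "S01",
        day_index: int = 1,
        repeat_index: int = 1,
        condition: ConditionSpec | None = None,
    ) -> "SessionRecord":
        """Build a session from a pair->spectrum mapping in any key order."""
        frequencies = np.asarray(frequencies, dtype=float)
        channels = np.full((len(PAIRS), frequencies.size), np.nan)
        for (a, b), spec in pairs.items():
            channels[pair_index(a, b)] = np.asarray(spec, dtype=float)
        missing = [PAIRS[i] for i in range(len(PAIRS)) if np.isnan(channels[i]).any()]
        if missing:
            raise ValueError(f"missing electrode pairs: {missing}")
        return cls(subject_id, day_index, repeat_index, frequencies, channels,
                   condition=condition)

    def channel(self, a: int, b: int) -> np.ndarray:
        """Magnitude spectrum of the unordered pair ``{a, b}`` (ohms)."""
        return self.channels[pair_index(a, b)]


@dataclass
class StudyData:
    """A collection of sessions as a dense channel array plus metadata.

    Attributes
    ----------
    channels : ndarray, shape (n_sessions, 10, n_freq)
        Impedance magnitudes, pair axis in :data:`PAIRS` order.
    meta : DataFrame
        One row per session with columns ``subject_id``, ``day_index``,
        ``repeat_index``, ``hand_temp_c``, ``placement_label``.
    frequencies : ndarray
        The common measurement grid in Hz.
    """

    channels: np.ndarray
    meta: pd.DataFrame
    frequencies: np.ndarray = field(default_factory=lambda: DEFAULT_FREQUENCIES.copy())

    _REQUIRED_META = ("subject_id", "day_index", "repeat_index")

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[1] != len(PAIRS):
            raise ValueError(
                f"channels must have shape (n, 10, n_freq), got {self.channels.shape}"
            )
        if self.channels.shape[2] != self.frequencies.size:
            raise ValueError("channel frequency axis does not match the grid")
        if len(self.meta) != self.channels.shape[0]:
            raise ValueError("meta rows must match the number of sessions")
        for col in self._REQUIRED_META:
            if col not in self.meta.columns:
                raise ValueError(f"meta is missing required column {col!r}")
        for col, default in (("hand_temp_c", np.nan), ("placement_label", "")):
            if col not in self.meta.columns:
                self.meta[col] = default
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_sessions(self) -> int:
        return self.channels.shape[0]

    @property
    def subjects(self) -> np.ndarray:
        return self.meta["subject_id"].unique()

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.meta["day_index"].unique())

    def session(self, i: int) -> SessionRecord:
        row = self.meta.iloc[i]
        return SessionRecord(
            subject_id=row["subject_id"],
            day_index=int(row["day_index"]),
            repeat_index=int(row["repeat_index"]),
            frequencies=self.frequencies,
            channels=self.channels[i],
            placement_label=str(row.get("placement_label", "")),
        )

    def __iter__(self) -> Iterator[SessionRecord]:
        return (self.session(i) for i in range(self.n_sessions))

    def subset(self, mask: Sequence[bool] | np.ndarray) -> "StudyData":
        mask = np.asarray(mask, dtype=bool)
        return StudyData(
            channels=self.channels[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            frequencies=self.frequencies,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (session, electrode pair, frequency)."""
        n, npair, nf = self.channels.shape
        pair_a = np.array([p[0] for p in PAIRS])
        pair_b = np.array([p[1] for p in PAIRS])
        rows = {
            "subject_id": np.repeat(self.meta["subject_id"].to_numpy(), npair * nf),
            "day_index": np.repeat(self.meta["day_index"].to_numpy(), npair * nf),
            "repeat_index": np.repeat(self.meta["repeat_index"].to_numpy(), npair * nf),
            "electrode_a": np.tile(np.repeat(pair_a, nf), n),
            "electrode_b": np.tile(np.repeat(pair_b, nf), n),
            "frequency_hz": np.tile(self.frequencies, n * npair),
            "impedance_ohm": self.channels.reshape(-1),
            "hand_temp_c": np.repeat(self.meta["hand_temp_c"].to_numpy(), npair * nf),
            "placement_label": np.repeat(
                self.meta["placement_label"].astype(str).to_numpy(), npair * nf
            ),
        }
        return pd.DataFrame(rows)
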