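"""Feature families for impedance-based identity recognition.

Three families, all built from the 10-channel session spectra:

* **raw finger** — the six finger-pair channel spectra as measured;
  cheap but exposed to day-to-day drift, temperature and placement.
* **ratiometric** — six ratios of finger-pair channels at matched
  frequencies; invariant to any drift that scales all fingers by a
  common factor.
* **upper limb** — the pure limb spectrum recovered from each triple
  ``(e0, ei, ej)`` as ``[Z(0,i) + Z(0,j) - Z(i,j)] / 2``: the finger
  contributions enter the wrist channels and the finger channel
  identically and cancel, so the limb feature is exactly invariant to
  per-finger placement and temperature effects.

Combo orderings are fixed to a canonical listing order so that feature
vectors are reproducible across runs.  The flat layout concatenates the
six 25-point spectra per family into a 150-vector (300 when two
families are fused); the channels layout stacks them as ``(25, 1, C)``
for convolutional models.

The families are also exposed as sklearn transformers operating on a
``(n_sessions, 10, n_freq)`` channel array (or its 2-D flattening), so
they compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .records import FINGER_PAIRS, PAIRS, SessionRecord, StudyData, pair_index

__all__ = [
    "LIMB_TRIPLES",
    "RATIO_COMBOS",
    "FINGER_PAIRS",
    "FeatureSet",
    "channel",
    "upper_limb_impedance",
    "raw_finger_features",
    "ratiometric_features",
    "upper_limb_features",
    "build_vector",
    "extract_features",
    "RawFingerFeatures",
    "RatiometricFeatures",
    "UpperLimbFeatures",
    "FAMILIES",
]

#: The six wrist triples (e0, ei, ej), canonical listing order.
LIMB_TRIPLES: tuple[tuple[int, int, int], ...] = (
    (0, 1, 2), (0, 1, 3), (0, 1, 4), (0, 2, 3), (0, 2, 4), (0, 3, 4),
)

#: The six canonical ratio combinations (numerator pair, denominator
#: pair); each finger pair appears exactly once as a numerator and once
#: as a denominator.
RATIO_COMBOS: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
    ((1, 2), (3, 4)),
    ((1, 3), (1, 2)),
    ((1, 4), (1, 3)),
    ((2, 3), (1, 4)),
    ((2, 4), (2, 3)),
    ((3, 4), (2, 4)),
)

FAMILIES = ("raw_finger", "ratiometric", "upper_limb")

_FINGER_IDX = np.array([pair_index(a, b) for a, b in FINGER_PAIRS])
_TRIPLE_IDX = np.array(
    [
        (pair_index(0, i), pair_index(0, j), pair_index(i, j))
        for _, i, j in LIMB_TRIPLES
    ]
)
_RATIO_IDX = np.array(
    [(pair_index(*num), pair_index(*den)) for num, den in RATIO_COMBOS]
)


@dataclass
class FeatureSet:
    """Named per-combination spectra of one family for one session."""

    family: Literal["raw_finger", "ratiometric", "upper_limb"]
    combos: tuple[str, ...]
    values: np.ndarray  # shape (6, n_freq)
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.combos), self.frequencies.size):
            raise ValueError("values must be (n_combos, n_freq)")


def channel(session: SessionRecord, a: int, b: int) -> np.ndarray:
    """Spectrum of the unordered electrode pair ``{a, b}``."""
    return session.channel(a, b)


# ---------------------------------------------------------------------------
# array-level kernels, shared by per-session ops and transformers
# ---------------------------------------------------------------------------

def _raw_from_channels(ch: np.ndarray) -> np.ndarray:
    return ch[..., _FINGER_IDX, :]


def _limb_from_channels(ch: np.ndarray) -> np.ndarray:
    zi = ch[..., _TRIPLE_IDX[:, 0], :]
    zj = ch[..., _TRIPLE_IDX[:, 1], :]
    zij = ch[..., _TRIPLE_IDX[:, 2], :]
    return (zi + zj - zij) / 2.0


def _ratio_from_channels(ch: np.ndarray) -> np.ndarray:
    num = ch[..., _RATIO_IDX[:, 0], :]
    den = ch[..., _RATIO_IDX[:, 1], :]
    if np.any(den == 0.0):
        raise ZeroDivisionError("zero denominator channel in ratiometric feature")
    return num / den


def upper_limb_impedance(
    session: SessionRecord, triple: tuple[int, int, int]
) -> np.ndarray:
    """Pure limb spectrum from one wrist triple ``(0, i, j)``.

    ``[Z(0,i) + Z(0,j) - Z(i,j)] / 2`` elementwise; the two finger
    impedances on the paths cancel.  Heavy noise can push individual
    values to or below zero; those are kept (clipping would bias CV
    statistics downstream) with a warning.
    """
    e0, i, j = triple
    if e0 != 0 or not (1 <= i < j <= 4):
        raise ValueError(f"triple must be (0, i, j) with 1 <= i < j <= 4, got {triple}")
    limb = (session.channel(0, i) + session.channel(0, j) - session.channel(i, j)) / 2.0
    if np.any(limb <= 0.0):
        warnings.warn(
            "non-positive extracted limb impedance (noise artifact); values kept",
            RuntimeWarning,
            stacklevel=2,
        )
    return limb


def raw_finger_features(session: SessionRecord) -> FeatureSet:
    """The six finger-pair channel spectra in canonical order."""
    return FeatureSet(
        family="raw_finger",
        combos=tuple(f"(e{a},e{b})" for a, b in FINGER_PAIRS),
        values=_raw_from_channels(session.channels),
        frequencies=session.frequencies,
    )


def ratiometric_features(
    session: SessionRecord,
    combos: Sequence[tuple[tuple[int, int], tuple[int, int]]] = RATIO_COMBOS,
) -> FeatureSet:
    """Finger-pair ratios at matched frequencies, canonical combo order."""
    if tuple(combos) == RATIO_COMBOS:
        values = _ratio_from_channels(session.channels)
    else:
        values = []
        for num, den in combos:
            if tuple(num) == tuple(den):
                raise ValueError("numerator and denominator pair must differ")
            d = session.channel(*den)
            if np.any(d == 0.0):
                raise ZeroDivisionError("zero denominator channel in ratiometric feature")
            values.append(session.channel(*num) / d)
        values = np.stack(values)
    return FeatureSet(
        family="ratiometric",
        combos=tuple(
            f"(e{n[0]},e{n[1]})/(e{d[0]},e{d[1]})" for n, d in combos
        ),
        values=values,
        frequencies=session.frequencies,
    )


def upper_limb_features(session: SessionRecord) -> FeatureSet:
    """Pure limb spectra from all six wrist triples, canonical order."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = _limb_from_channels(session.channels)
    if np.any(values <= 0.0):
        warnings.warn(
            "non-positive extracted limb impedance (noise artifact); values kept",
            RuntimeWarning,
            stacklevel=2,
        )
    return FeatureSet(
        family="upper_limb",
        combos=tuple(f"(e0,e{i},e{j})" for _, i, j in LIMB_TRIPLES),
        values=values,
        frequencies=session.frequencies,
    )


def build_vector(
    sets: Sequence[FeatureSet], layout: Literal["flat", "channels"] = "flat"
) -> np.ndarray:
    """Fuse one or more feature sets into a classifier-ready vector.

    ``flat`` concatenates in (family, combo, frequency) order — one
    family on the default grid gives length 150, two give 300.
    ``channels`` stacks combos as ``(n_freq, 1, n_combos)`` for 1-D
    convolutional input.
    """
    if len(sets) == 0:
        raise ValueError("need at least one FeatureSet")
    grid = sets[0].frequencies
    for fs in sets[1:]:
        if fs.frequencies.shape != grid.shape or not np.array_equal(fs.frequencies, grid):
            raise ValueError("feature sets must share the frequency grid")
    stacked = np.concatenate([fs.values for fs in sets], axis=0)  # (C, n_freq)
    if layout == "flat":
        return stacked.reshape(-1)
    if layout == "channels":
        return stacked.T[:, np.newaxis, :]
    raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# sklearn transformer surface
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402


class _ChannelFamilyTransformer(TransformerMixin, BaseEstimator):
    """Base for family transformers over session channel arrays.

    Accepts ``X`` of shape ``(n, 10, n_freq)`` or its 2-D flattening
    ``(n, 10 * n_freq)`` and emits flat family vectors
    ``(n, 6 * n_freq)`` so downstream sklearn estimators see 2-D data.
    """

    def __init__(self, n_frequencies: int = 25):
        self.n_frequencies = n_frequencies

    def _as_channels(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        nf = self.n_frequencies
        if X.ndim == 3:
            if X.shape[1:] != (len(PAIRS), nf):
                raise ValueError(f"expected (n, 10, {nf}), got {X.shape}")
            return X
        if X.ndim == 2:
            if X.shape[1] != len(PAIRS) * nf:
                raise ValueError(f"expected (n, {len(PAIRS) * nf}), got {X.shape}")
            return X.reshape(X.shape[0], len(PAIRS), nf)
        raise ValueError("X must be 2-D or 3-D")

    def fit(self, X, y=None):
        self._as_channels(X)
        self.n_features_in_ = np.asarray(X).shape[1] if np.asarray(X).ndim == 2 else len(PAIRS)
        return self

    def transform(self, X) -> np.ndarray:
        ch = self._as_channels(X)
        out = self._kernel(ch)
        return out.reshape(out.shape[0], -1)

    def _kernel(self, ch: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class RawFingerFeatures(_ChannelFamilyTransformer):
    """Six finger-pair spectra per session, flattened to ``(n, 6*n_freq)``."""

    def _kernel(self, ch: np.ndarray) -> np.ndarray:
        return _raw_from_channels(ch)


class RatiometricFeatures(_ChannelFamilyTransformer):
    """Six canonical finger-pair ratios per session."""

    def _kernel(self, ch: np.ndarray) -> np.ndarray:
        return _ratio_from_channels(ch)


class UpperLimbFeatures(_ChannelFamilyTransformer):
    """Pure limb spectra from the six wrist triples per session."""

    def _kernel(self, ch: np.ndarray) -> np.ndarray:
        return _limb_from_channels(ch)


_SELECTIONS = {
    "finger": ("raw_finger",),
    "ratio": ("ratiometric",),
    "limb": ("upper_limb",),
    "ratio+limb": ("ratiometric", "upper_limb"),
}

_FAMILY_KERNELS = {
    "raw_finger": _raw_from_channels,
    "ratiometric": _ratio_from_channels,
    "upper_limb": _limb_from_channels,
}


def extract_features(
    data: StudyData,
    selection: str,
    layout: Literal["flat", "channels"] = "flat",
) -> np.ndarray:
    """Feature matrix for a whole study.

    Parameters
    ----------
    data : StudyData
        Sessions to featurize.
    selection : str
        ``finger``, ``ratio``, ``limb`` or ``ratio+limb`` (a family
        name like ``raw_finger`` is also accepted).
    layout : str
        ``flat`` -> ``(n, n_combos * n_freq)``;
        ``channels`` -> ``(n, n_freq, n_combos)`` for the convnet.
    """
    if selection in _SELECTIONS:
        families = _SELECTIONS[selection]
    elif selection in _FAMILY_KERNELS:
        families = (selection,)
    else:
        raise ValueError(
            f"unknown feature selection {selection!r}; "
            f"expected one of {sorted(_SELECTIONS)} or a family name"
        )
    blocks = [_FAMILY_KERNELS[fam](data.channels) for fam in families]
    stacked = np.concatenate(blocks, axis=1)  # (n, C, n_freq)
    if layout == "flat":
        return stacked.reshape(stacked.shape[0], -1)
    if layout == "channels":
        return np.swapaxes(stacked, 1, 2)
    raise ValueError(f"unknown layout {layout!r}")


def feature_names(selection: str, frequencies: np.ndarray) -> list[str]:
    """Column names matching ``extract_features(..., layout='flat')``."""
    families = _SELECTIONS.get(selection, (selection,))
    labels = {
        "raw_finger": [f"finger_e{a}e{b}" for a, b in FINGER_PAIRS],
        "ratiometric": [
            f"ratio_e{n[0]}e{n[1]}_e{d[0]}e{d[1]}" for n, d in RATIO_COMBOS
        ],
        "upper_limb": [f"limb_e0e{i}e{j}" for _, i, j in LIMB_TRIPLES],
    }
    names = []
    for fam in families:
        for combo in labels[fam]:
            for f in frequencies:
                names.append(f"{combo}_{int(f)}")
    return names
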