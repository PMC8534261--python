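"""Reproducibility analysis: CV profiles, temperature response, PCA.

Day-to-day reproducibility is summarized per feature family by the
coefficient of variation of daily means, computed per subject and
frequency and then aggregated across subjects (mean and sd).  The
temperature robustness analysis regresses band-averaged impedance on
hand temperature per subject and family.  PCA embeddings give the
cluster view used to compare the distinguishability of families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .features import _FAMILY_KERNELS, FAMILIES
from .records import StudyData

__all__ = [
    "coefficient_of_variation",
    "daily_cv_profile",
    "band_average",
    "temperature_response",
    "pca_embedding",
    "PcaEmbedding",
]


def coefficient_of_variation(values) -> float:
    """Sample CV: standard deviation (n-1 denominator) over the mean.

    Scale-free dispersion; requires at least two values and a nonzero
    mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0.0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def _family_values(data: StudyData, family: str) -> np.ndarray:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return _FAMILY_KERNELS[family](data.channels)  # (n, 6, n_freq)


def daily_cv_profile(data: StudyData, family: str) -> pd.DataFrame:
    """Across-day CV of a feature family, aggregated across subjects.

    Per subject, combo and frequency the repeats within each day are
    averaged and the CV is taken across the daily means; per-combo CVs
    are then averaged into a family-level value per subject, and the
    across-subject mean and sd are reported per frequency.

    Subjects with fewer than two distinct days are excluded with a
    warning.

    Returns
    -------
    DataFrame
        Columns ``family``, ``frequency_hz``, ``cv_mean``, ``cv_sd``,
        ``n_subjects``; one row per frequency.
    """
    values = _family_values(data, family)
    nf = data.frequencies.size
    per_subject: list[np.ndarray] = []
    for subject, idx in data.meta.groupby("subject_id").groups.items():
        sub_meta = data.meta.loc[idx]
        days = sub_meta["day_index"].unique()
        if len(days) < 2:
            warnings.warn(
                f"subject {subject!r} has a single measurement day; excluded from CV",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        daily = np.stack(
            [
                values[np.asarray(idx)[sub_meta["day_index"].to_numpy() == d]].mean(axis=0)
                for d in days
            ]
        )  # (n_days, 6, nf)
        cv = daily.std(axis=0, ddof=1) / daily.mean(axis=0)  # (6, nf)
        per_subject.append(cv.mean(axis=0))  # combo-averaged, (nf,)
    if not per_subject:
        raise ValueError("no subject has two or more measurement days")
    mat = np.stack(per_subject)  # (n_subjects, nf)
    return pd.DataFrame(
        {
            "family": family,
            "frequency_hz": data.frequencies,
            "cv_mean": mat.mean(axis=0),
            "cv_sd": mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(nf),
            "n_subjects": mat.shape[0],
        }
    )


def band_average(spectrum, frequencies: np.ndarray | None = None,
                 grid: np.ndarray | None = None) -> float:
    """Arithmetic mean of a spectrum over the full measurement band.

    If both ``frequencies`` (of the spectrum) and ``grid`` (the
    expected full grid) are given, the spectrum must cover the grid
    exactly (order-insensitively).
    """
    v = np.asarray(spectrum, dtype=float)
    if grid is not None:
        if frequencies is None:
            if v.size != np.asarray(grid).size:
                raise ValueError("spectrum does not cover the full frequency grid")
        else:
            f = np.asarray(frequencies, dtype=float)
            if not np.array_equal(np.sort(f), np.sort(np.asarray(grid, dtype=float))):
                raise ValueError("spectrum does not cover the full frequency grid")
    return float(v.mean())


def temperature_response(data: StudyData) -> pd.DataFrame:
    """OLS slope and Pearson r of band-averaged impedance vs hand temperature.

    Computed per subject for the raw finger and extracted limb
    families (band- and combo-averaged per session).  A negative
    finger slope with a flat limb slope is the expected signature of
    peripheral thermoregulation.

    Requires at least three distinct temperatures; raises on a
    constant temperature column.
    """
    temps = data.meta["hand_temp_c"].to_numpy(dtype=float)
    if np.unique(temps).size < 3:
        raise ValueError("temperature sweep must cover at least 3 distinct temperatures")
    rows = []
    for family in ("raw_finger", "upper_limb"):
        band = _family_values(data, family).mean(axis=(1, 2))  # (n_sessions,)
        for subject, idx in data.meta.groupby("subject_id").groups.items():
            idx = np.asarray(idx)
            t = temps[idx]
            if np.ptp(t) == 0.0:
                raise ValueError(f"subject {subject!r} measured at constant temperature")
            res = stats.linregress(t, band[idx])
            rows.append(
                {
                    "subject_id": subject,
                    "family": family,
                    "slope_ohm_per_degc": res.slope,
                    "pearson_r": res.rvalue,
                    "intercept_ohm": res.intercept,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PcaEmbedding:
    """Top-k principal-component scores with explained variance."""

    scores: np.ndarray  # (n_samples, k), column-centered
    explained_variance: np.ndarray  # (k,), non-increasing
    components: np.ndarray  # (k, n_features)


def pca_embedding(X: np.ndarray, k: int = 3) -> PcaEmbedding:
    """Principal-component embedding of a feature matrix.

    Columns are centered (no unit-variance scaling: spectra within a
    family share units) and projected onto the top-``k`` right singular
    directions.  Signs are fixed by making each component's
    largest-magnitude loading positive, so embeddings are deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} samples, got {X.shape[0]}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(k):
        j = np.argmax(np.abs(comps[c]))
        if comps[c, j] < 0:
            comps[c] = -comps[c]
            scores[:, c] = -scores[:, c]
    return PcaEmbedding(
        scores=scores,
        explained_variance=pca.explained_variance_,
        components=comps,
    )
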