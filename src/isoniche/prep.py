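"""Isotope pre-processing.

delta-notation arithmetic, lipid normalisation of delta13C from the C:N
ratio, within-group anomaly normalisation (removing baseline differences
between treatments) and the per-individual Euclidean distance to the group
centroid in delta13C-delta15N space,

    ED = sqrt(d13C_a**2 + d15N_a**2),

where the subscript *a* denotes the anomaly (individual value minus group
mean).  The mean ED of a group equals that group's distance-to-centroid
niche metric (CD) by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default C:N threshold above which delta13C is lipid-normalised
LIPID_CN_THRESHOLD = 3.6
#: aquatic-animal lipid normalisation constants: d13c - 3.32 + 0.99 * C:N
LIPID_INTERCEPT = -3.32
LIPID_SLOPE = 0.99


@dataclass(frozen=True)
class DeltaStandard:
    """An international isotope reference standard (heavy/light ratio)."""

    element: str
    name: str
    r_standard: float

    def __post_init__(self) -> None:
        if not (self.r_standard > 0):
            raise ValueError("R_standard must be > 0")


#: Vienna Pee Dee Belemnite, the carbon reference
VPDB = DeltaStandard("C", "VPDB", 0.0112372)
#: atmospheric N2, the nitrogen reference
AIR_N2 = DeltaStandard("N", "atmospheric N2", 0.0036765)


def delta_from_ratio(r_sample, standard: DeltaStandard):
    """delta (permil) = (R_sample / R_standard - 1) * 1000."""
    r = np.asarray(r_sample, dtype=float)
    if np.any(r <= 0):
        raise ValueError("isotope ratio must be > 0")
    out = (r / standard.r_standard - 1.0) * 1000.0
    return float(out) if np.isscalar(r_sample) else out


def ratio_from_delta(delta, standard: DeltaStandard):
    """Inverse of :func:`delta_from_ratio`."""
    d = np.asarray(delta, dtype=float)
    out = (d / 1000.0 + 1.0) * standard.r_standard
    return float(out) if np.isscalar(delta) else out


def lipid_normalize(
    d13c_raw,
    cn_ratio,
    threshold: float = LIPID_CN_THRESHOLD,
    intercept: float = LIPID_INTERCEPT,
    slope: float = LIPID_SLOPE,
):
    """Normalise delta13C for lipid content from the mass C:N ratio.

    Lipids are depleted in 13C relative to protein, so lipid-rich tissue
    biases bulk delta13C low; above the C:N threshold (default 3.6) the
    arithmetic correction ``d13c + intercept + slope * C:N`` is applied,
    below it the value passes through unchanged.
    """
    d = np.asarray(d13c_raw, dtype=float)
    cn = np.asarray(cn_ratio, dtype=float)
    if np.any(~(cn > 0)):
        raise ValueError("cn_ratio must be > 0")
    corrected = np.where(cn > threshold, d + intercept + slope * cn, d)
    n_below = int(np.sum(cn <= threshold))
    if n_below:
        logger.info(
            "lipid_normalize: %d value(s) at C:N <= %.3g left uncorrected",
            n_below,
            threshold,
        )
    if np.isscalar(d13c_raw) and np.isscalar(cn_ratio):
        return float(corrected)
    return corrected


def compute_anomalies(
    df: pd.DataFrame,
    group_col: str = "treatment",
    d13c_col: str = "d13c_corr",
    d15n_col: str = "d15n",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtract each group's mean per isotope axis.

    Returns the input frame with ``d13c_anom`` / ``d15n_anom`` columns added
    and a per-group table of the means used.  Anomalies sum to zero within
    each group by construction.
    """
    if df.empty:
        raise ValueError("cannot compute anomalies of an empty table")
    if df[group_col].isna().any():
        raise ValueError(f"missing {group_col} label")
    out = df.copy()
    means = out.groupby(group_col)[[d13c_col, d15n_col]].transform("mean")
    out["d13c_anom"] = out[d13c_col] - means[d13c_col]
    out["d15n_anom"] = out[d15n_col] - means[d15n_col]
    group_means = (
        out.groupby(group_col)[[d13c_col, d15n_col]]
        .mean()
        .rename(columns={d13c_col: "mean_d13c", d15n_col: "mean_d15n"})
        .reset_index()
    )
    return out, group_means


def euclidean_distance(d13c_anom, d15n_anom):
    """Euclidean distance to the group centroid (permil)."""
    out = np.hypot(np.asarray(d13c_anom, float), np.asarray(d15n_anom, float))
    if np.isscalar(d13c_anom) and np.isscalar(d15n_anom):
        return float(out)
    return out


def prepare_isotopes(
    df: pd.DataFrame,
    group_col: str = "treatment",
    cn_threshold: float = LIPID_CN_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pre-processing for a specimen table.

    Adds ``d13c_corr`` (lipid-normalised), ``d13c_anom``/``d15n_anom``
    (within *group_col*, computed on the corrected values) and ``ed``.
    Returns the augmented frame and the per-group mean table.
    """
    out = df.copy()
    out["d13c_corr"] = lipid_normalize(
        out["d13c_raw"].to_numpy(float),
        out["cn_ratio"].to_numpy(float),
        threshold=cn_threshold,
    )
    out, group_means = compute_anomalies(out, group_col=group_col)
    out["ed"] = euclidean_distance(
        out["d13c_anom"].to_numpy(), out["d15n_anom"].to_numpy()
    )
    return out, group_means


def zscore_within_group(values, groups) -> np.ndarray:
    """Standardise to zero mean and unit sample sd within each group.

    Raises for groups of size < 2 or zero spread (no finite z-score
    exists), naming the offending group.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for g in pd.unique(groups):
        mask = groups == g
        v = values[mask]
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {g!r} has zero spread")
        out[mask] = (v - v.mean()) / sd
    return out
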