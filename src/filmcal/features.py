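"""Dose-calibration features from paired pre/post pixel values.

Three families of scanner read-outs are in routine use for radiochromic
film calibration and all three are kept here as network inputs:

* **net optical density** ``NOD = log10(PV_pre / PV_post)`` — the classic
  background-subtracting quantity (red channel only, the most
  dose-sensitive at clinical dose levels);
* **raw pixel values** per channel, irradiated (IPV, postscan) and
  background (BPV, prescan) — the background values carry the film's
  shelf-age signature;
* **inverse transmittance** ``IT = (2^16 - 1) / PV`` per channel, computed
  from the postscan.

Together they form the ten-feature vector consumed by the hierarchical
network, organised in five input groups:
(1) R-NOD, (2) R-IPV/R-BPV, (3) G-IPV/G-BPV, (4) B-IPV/B-BPV,
(5) R-IT/G-IT/B-IT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FULL_SCALE = 65535.0

FEATURE_COLUMNS = [
    "r_nod",
    "r_ipv", "r_bpv",
    "g_ipv", "g_bpv",
    "b_ipv", "b_bpv",
    "r_it", "g_it", "b_it",
]

#: Column slices of FEATURE_COLUMNS defining the five network input groups.
FEATURE_GROUPS = [
    ["r_nod"],
    ["r_ipv", "r_bpv"],
    ["g_ipv", "g_bpv"],
    ["b_ipv", "b_bpv"],
    ["r_it", "g_it", "b_it"],
]

SAMPLE_TABLE_COLUMNS = [
    "lot_id", "calibration_index", "shelf_age_months", "position_mm",
    "R_bpv", "G_bpv", "B_bpv", "R_ipv", "G_ipv", "B_ipv", "dose_cGy",
]

__all__ = [
    "FeatureVector",
    "CalibrationSample",
    "net_optical_density",
    "inverse_transmittance",
    "build_feature_vector",
    "dose_at_position",
    "features_from_table",
    "FEATURE_COLUMNS",
    "FEATURE_GROUPS",
    "SAMPLE_TABLE_COLUMNS",
]


@dataclass(frozen=True)
class FeatureVector:
    """The ten calibration features for one midline sample."""

    r_nod: float
    r_ipv: float
    g_ipv: float
    b_ipv: float
    r_bpv: float
    g_bpv: float
    b_bpv: float
    r_it: float
    g_it: float
    b_it: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in FEATURE_COLUMNS])


@dataclass(frozen=True)
class CalibrationSample:
    """One (features, delivered dose) pair with its provenance."""

    features: FeatureVector
    dose: float  # cGy
    lot_id: str = ""
    calibration_index: int = 0
    shelf_age_months: float = 0.0

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


def net_optical_density(pv_pre, pv_post):
    """log10(pv_pre / pv_post): the channel's net optical density."""
    pv_pre = np.asarray(pv_pre, dtype=float)
    pv_post = np.asarray(pv_post, dtype=float)
    if np.any(pv_pre <= 0) or np.any(pv_post <= 0):
        raise ValueError("pixel values must be positive")
    return np.log10(pv_pre / pv_post)


def inverse_transmittance(pv):
    """(2^16 - 1) / pv: increases monotonically with absorbed dose."""
    pv = np.asarray(pv, dtype=float)
    if np.any(pv <= 0):
        raise ValueError("pixel values must be positive")
    return FULL_SCALE / pv


def build_feature_vector(pre_rgb, post_rgb) -> FeatureVector:
    """Assemble the ten features from one pre/post RGB pixel-value pair.

    Inverse transmittances are computed from the postscan (irradiated)
    values; the prescan supplies the background pixel values.
    """
    pre = np.asarray(pre_rgb, dtype=float)
    post = np.asarray(post_rgb, dtype=float)
    if pre.shape != (3,) or post.shape != (3,):
        raise ValueError("expected RGB triplets")
    it = inverse_transmittance(post)
    return FeatureVector(
        r_nod=float(net_optical_density(pre[0], post[0])),
        r_ipv=float(post[0]), g_ipv=float(post[1]), b_ipv=float(post[2]),
        r_bpv=float(pre[0]), g_bpv=float(pre[1]), b_bpv=float(pre[2]),
        r_it=float(it[0]), g_it=float(it[1]), b_it=float(it[2]),
    )


def dose_at_position(mu, pdd, position, cal_factor: float = 1.0):
    """Delivered dose at a midline position from MU and a PDD table.

    ``pdd`` is a table of (depth mm, percent) pairs — a DataFrame with
    columns ``depth_mm``/``pdd_percent``, or a 2-column array.  Depths are
    linearly interpolated; querying outside the tabulated range is an
    error.  ``cal_factor`` is the machine calibration in cGy/MU (1 under
    the reference-condition quick calibration).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if isinstance(pdd, pd.DataFrame):
        depths = pdd["depth_mm"].to_numpy(dtype=float)
        percents = pdd["pdd_percent"].to_numpy(dtype=float)
    else:
        arr = np.asarray(pdd, dtype=float)
        depths, percents = arr[:, 0], arr[:, 1]
    order = np.argsort(depths)
    depths, percents = depths[order], percents[order]
    position = np.asarray(position, dtype=float)
    if np.any(position < depths[0]) or np.any(position > depths[-1]):
        raise ValueError("position outside the PDD table's depth range")
    return mu * cal_factor * np.interp(position, depths, percents) / 100.0


def features_from_table(table: pd.DataFrame,
                        standardize: bool = False) -> pd.DataFrame:
    """Compute the ten feature columns for every row of a sample table.

    ``table`` uses the sample-table schema (``SAMPLE_TABLE_COLUMNS``);
    the result carries ``FEATURE_COLUMNS`` plus ``dose_cGy`` and the
    provenance columns.  Features are emitted on their natural scales
    (net OD ~0-1, pixel values ~10^4, inverse transmittance ~1-10);
    ``standardize`` optionally z-scores the ten feature columns.
    """
    out = pd.DataFrame(index=table.index)
    out["r_nod"] = net_optical_density(table["R_bpv"], table["R_ipv"])
    for ch in "RGB":
        out[f"{ch.lower()}_ipv"] = table[f"{ch}_ipv"].astype(float)
        out[f"{ch.lower()}_bpv"] = table[f"{ch}_bpv"].astype(float)
        out[f"{ch.lower()}_it"] = inverse_transmittance(table[f"{ch}_ipv"])
    out = out[FEATURE_COLUMNS]
    if standardize:
        std = out.std(ddof=0).replace(0.0, 1.0)
        out = (out - out.mean()) / std
    for col in ("dose_cGy", "lot_id", "calibration_index",
                "shelf_age_months", "position_mm"):
        if col in table:
            out[col] = table[col].to_numpy()
    return out
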