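"""Reading film scans and extracting midline depth profiles.

Radiochromic film is scanned on a flatbed scanner before irradiation
(*prescan*, the background) and again after (*postscan*).  In the
parallel-to-beam calibration geometry the film midline coincides with the
beam central axis, so a single film yields one pixel-value sample per depth
along its long axis.  This module reads the RGB TIFF scans and reduces them
to such midline profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

MM_PER_INCH = 25.4
FULL_SCALE = 65535

__all__ = [
    "ScanImage",
    "MidlineProfile",
    "read_scan",
    "extract_midline_profile",
    "pair_profiles",
]


@dataclass
class ScanImage:
    """One RGB film scan on the 16-bit-per-channel scale.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols, 3)
        Channel values in [0, 65535].  Rows run along the film's long axis
        (portrait convention: long axis = depth axis).
    dpi : float
        Scan resolution in dots per inch (127 dpi is typical for this
        workflow).
    orientation : {"portrait", "landscape"}
    scan_role : {"prescan", "postscan"}
    """

    pixels: np.ndarray
    dpi: float
    orientation: str = "portrait"
    scan_role: str = "prescan"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be a (rows, cols, 3) RGB array")
        if self.pixels.min() < 0 or self.pixels.max() > FULL_SCALE:
            raise ValueError("channel values must lie in [0, 65535]")
        if not self.dpi > 0:
            raise ValueError("dpi must be positive")
        if self.scan_role not in ("prescan", "postscan"):
            raise ValueError(f"unknown scan_role {self.scan_role!r}")


@dataclass
class MidlineProfile:
    """Mean RGB pixel values along the film midline.

    ``positions`` are distances in mm from the first sampled row (the
    beam-entry edge); ``pv`` holds one RGB triplet per position, each the
    mean over a lateral window of ``2*window_px + 1`` columns centred on
    the image's central column.
    """

    positions: np.ndarray
    pv: np.ndarray
    window_px: int
    step_px: int
    role: str = field(default="prescan")

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.pv = np.asarray(self.pv, dtype=float)
        if self.pv.shape != (self.positions.size, 3):
            raise ValueError("pv must hold one RGB triplet per position")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.pv.min() < 0 or self.pv.max() > FULL_SCALE:
            raise ValueError("pv channels must lie in [0, 65535]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_mm": self.positions,
                "R_pv": self.pv[:, 0],
                "G_pv": self.pv[:, 1],
                "B_pv": self.pv[:, 2],
                "role": self.role,
            }
        )


def read_scan(path, role: str, dpi: float | None = None,
              transpose: bool = False) -> ScanImage:
    """Read an RGB TIFF film scan, promoting 8-bit data to the 16-bit scale.

    8-bit channel values are multiplied by 257 so that full scale maps to
    full scale (255 * 257 = 65535).  ``dpi`` overrides the file's resolution
    metadata; if the file carries none and no override is given, an error is
    raised.  ``transpose`` swaps the axes for scans acquired with the short
    axis along the beam.
    """
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        file_dpi = _dpi_from_tags(page)
    if arr.ndim != 3 or arr.shape[-1] < 3:
        raise ValueError(f"{path}: not an RGB image (shape {arr.shape})")
    arr = arr[..., :3]
    if arr.dtype == np.uint8:
        arr = arr.astype(np.uint16) * 257
    elif arr.dtype != np.uint16:
        raise ValueError(f"{path}: expected 8- or 16-bit channels, got {arr.dtype}")
    if transpose:
        arr = np.swapaxes(arr, 0, 1)
    resolved_dpi = dpi if dpi is not None else file_dpi
    if resolved_dpi is None:
        raise ValueError(f"{path}: no resolution metadata; pass dpi explicitly")
    return ScanImage(pixels=arr, dpi=float(resolved_dpi), scan_role=role)


def _dpi_from_tags(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if den == 0:
        return None
    dpi = num / den
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    unit = getattr(unit, "value", unit)
    if unit == 1:  # RESUNIT NONE: no physical scale recorded
        return None
    if unit == 3:  # centimetres
        dpi *= 2.54
    return float(dpi) if dpi > 0 else None


def extract_midline_profile(img: ScanImage, window_px: int = 5,
                            step_px: int = 5) -> MidlineProfile:
    """Average pixel values over a lateral window around the central column.

    The midline is the central column (``floor(width/2)``).  Every
    ``step_px``-th row is sampled, averaging columns within ``±window_px``
    of the midline; row index converts to mm through the scan dpi.  The
    defaults (window 5, step 5) give ~1 mm sampling at 127 dpi and average
    11 columns to suppress scanner noise.
    """
    if window_px < 1 or step_px < 1:
        raise ValueError("window_px and step_px must be >= 1")
    rows, cols, _ = img.pixels.shape
    centre = cols // 2
    lo, hi = centre - window_px, centre + window_px + 1
    if lo < 0 or hi > cols:
        raise ValueError(
            f"lateral window ±{window_px}px around column {centre} exceeds "
            f"image width {cols}"
        )
    row_idx = np.arange(0, rows, step_px)
    band = img.pixels[row_idx, lo:hi, :].astype(float)
    pv = band.mean(axis=1)
    positions = row_idx * (MM_PER_INCH / img.dpi)
    return MidlineProfile(positions=positions, pv=pv, window_px=window_px,
                          step_px=step_px, role=img.scan_role)


def pair_profiles(pre: MidlineProfile, post: MidlineProfile,
                  atol: float = 1e-9) -> pd.DataFrame:
    """Match prescan/postscan profile samples by position.

    Returns a DataFrame with one row per common position holding the pre-
    and postscan RGB values.  Positions present in only one profile are
    dropped.
    """
    if pre.step_px != post.step_px or pre.window_px != post.window_px:
        raise ValueError("profiles must share window_px and step_px")
    rows = []
    j = 0
    for i, p in enumerate(pre.positions):
        while j < post.positions.size and post.positions[j] < p - atol:
            j += 1
        if j < post.positions.size and abs(post.positions[j] - p) <= atol:
            rows.append((p, *pre.pv[i], *post.pv[j]))
    if not rows:
        raise ValueError("no overlapping positions between profiles")
    return pd.DataFrame(
        rows,
        columns=["position_mm", "R_bpv", "G_bpv", "B_bpv",
                 "R_ipv", "G_ipv", "B_ipv"],
    )
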