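"""Synthetic EBT3-like calibration data.

Real calibration films are not deposited with the study design this
package implements, so a phenomenological simulator stands in for them.
It emulates the features of radiochromic film data that the calibration
pipeline must cope with:

* a saturating-plus-linear net-optical-density dose response per colour
  channel, with the red channel most sensitive at clinical dose levels;
* lot-to-lot sensitivity shifts (a multiplier on net OD);
* shelf-age drift of both sensitivity and the background pixel value;
* multiplicative scanner noise on every read-out;
* the parallel-to-beam midline geometry, in which one film irradiated at
  a single MU setting yields one (depth, dose) sample per millimetre
  through a percentage-depth-dose curve.

The response model is an explicit stand-in: net OD for channel W at dose
D (cGy) and shelf age t (months) is

    netOD = s_L * (1 + r_s*t) * (alpha_W * D / (D + beta_W) + gamma_W * D)

with the background pixel value decaying as ``basePV_W * (1 - r_b*t)``
and ``pv_post = pv_pre * 10**(-netOD)``; both pixel values then receive
independent multiplicative Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

from .features import SAMPLE_TABLE_COLUMNS

__all__ = [
    "ChannelResponse",
    "LotProfile",
    "SimConfig",
    "pdd_percent",
    "simulate_pv",
    "simulate_calibration_film",
    "generate_study",
    "write_synthetic_scans",
    "default_lot",
    "default_study_design",
]

CHANNELS = ("R", "G", "B")


@dataclass(frozen=True)
class ChannelResponse:
    """Saturating-plus-linear net-OD response of one colour channel.

    ``alpha`` is the saturating net-OD amplitude, ``beta`` the
    half-saturation dose (cGy), ``gamma`` the residual linear slope
    (OD per cGy).  Low-dose sensitivity is ``alpha/beta + gamma``.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if self.alpha < 0 or self.beta <= 0 or self.gamma < 0:
            raise ValueError("alpha, gamma must be >= 0 and beta > 0")

    def net_od(self, dose):
        dose = np.asarray(dose, dtype=float)
        return self.alpha * dose / (dose + self.beta) + self.gamma * dose


@dataclass(frozen=True)
class LotProfile:
    """Response parameters of one synthetic film lot.

    Defaults are EBT3-like: red net OD ~0.35 at 200 cGy, with the
    channel low-dose sensitivities ordered red > green > blue.
    ``sensitivity`` is the lot-to-lot multiplier on net OD;
    ``drift_sens`` and ``drift_bg`` are fractional per-month drift rates
    of the sensitivity (upward) and of the background pixel value
    (downward), emulating the shelf-aging effect.
    """

    lot_id: str = "C"
    channels: dict = field(default_factory=lambda: {
        "R": ChannelResponse(alpha=0.55, beta=300.0, gamma=2.0e-4),
        "G": ChannelResponse(alpha=0.50, beta=600.0, gamma=1.5e-4),
        "B": ChannelResponse(alpha=0.30, beta=800.0, gamma=1.0e-4),
    })
    sensitivity: float = 1.0
    drift_sens: float = 0.008    # +0.8 %/month
    drift_bg: float = 0.0015     # -0.15 %/month
    base_bpv: dict = field(default_factory=lambda: {
        "R": 44000.0, "G": 47000.0, "B": 42000.0,
    })

    def __post_init__(self):
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        for ch, pv in self.base_bpv.items():
            if not 0 < pv <= 65535:
                raise ValueError(f"{ch} background PV outside (0, 65535]")
        sens = [self.channels[c].alpha / self.channels[c].beta
                for c in CHANNELS]
        if not sens[0] > sens[1] > sens[2]:
            raise ValueError(
                "low-dose sensitivity must be ordered red > green > blue")


def default_lot(lot_id: str = "C", sensitivity: float = 1.0,
                bpv_shift: float = 0.0) -> LotProfile:
    """A lot with the default response, scaled sensitivity and a
    fractional shift of all background pixel values."""
    base = LotProfile()
    bpv = {ch: pv * (1.0 + bpv_shift) for ch, pv in base.base_bpv.items()}
    return replace(base, lot_id=lot_id, sensitivity=sensitivity, base_bpv=bpv)


@dataclass(frozen=True)
class SimConfig:
    """Irradiation geometry, dose range and noise of the simulator.

    The percentage-depth-dose model is a linear build-up to ``d_max_mm``
    followed by exponential attenuation ``exp(-mu_atten*(d - d_max))``,
    a 6 MV-like curve.  Depth sampling starts at ``d_max_mm`` by default:
    the build-up region is excluded, as is standard dosimetry practice
    (charged-particle disequilibrium makes the depth dose there
    unreliable).  ``noise_sigma`` is the relative standard deviation of
    the multiplicative scanner noise on each emitted pixel value.
    """

    dose_min: float = 20.0
    dose_max: float = 400.0
    d_max_mm: float = 15.0
    mu_atten: float = 0.0055       # per mm
    film_length_mm: float = 245.0
    step_mm: float = 1.0
    depth_start_mm: float | None = None   # None -> d_max_mm
    cal_factor: float = 1.0        # cGy per MU at d_max
    noise_sigma: float = 0.003
    seed: int = 435

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not 0 < self.dose_min < self.dose_max:
            raise ValueError("dose range must be positive and ordered")


def pdd_percent(depth_mm, config: SimConfig = SimConfig()):
    """Percentage depth dose of the synthetic 6 MV-like beam."""
    d = np.asarray(depth_mm, dtype=float)
    build_up = 100.0 * d / config.d_max_mm
    plateau = 100.0 * np.exp(-config.mu_atten * (d - config.d_max_mm))
    return np.where(d < config.d_max_mm, build_up, plateau)


def simulate_pv(dose, channel: str, lot: LotProfile,
                shelf_age_months: float, rng, noise_sigma: float = 0.0):
    """Pre/post pixel values for one channel at one dose and shelf age.

    Returns real-valued (pv_pre, pv_post); quantisation to 16-bit
    integers happens only when images are rendered.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    resp = lot.channels[channel]
    net_od = (lot.sensitivity * (1.0 + lot.drift_sens * shelf_age_months)
              * resp.net_od(dose))
    pv_pre = lot.base_bpv[channel] * (1.0 - lot.drift_bg * shelf_age_months)
    pv_pre = np.broadcast_to(np.asarray(pv_pre, dtype=float), dose.shape).copy()
    pv_post = pv_pre * np.power(10.0, -net_od)
    if noise_sigma > 0:
        pv_pre = pv_pre * rng.normal(1.0, noise_sigma, size=dose.shape)
        pv_post = pv_post * rng.normal(1.0, noise_sigma, size=dose.shape)
    return np.clip(pv_pre, 1.0, 65535.0), np.clip(pv_post, 1.0, 65535.0)


def simulate_calibration_film(mu: float, lot: LotProfile,
                              shelf_age_months: float,
                              config: SimConfig, rng,
                              calibration_index: int = 1) -> pd.DataFrame:
    """One parallel-to-beam film: a sample-table DataFrame.

    Depth positions run from ``depth_start_mm`` to ``film_length_mm`` at
    ``step_mm`` spacing; each yields the dose ``mu*cal_factor*PDD/100``
    and noisy pre/post pixel values for all three channels.  Positions
    whose dose falls outside [dose_min, dose_max] are dropped.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    start = config.depth_start_mm if config.depth_start_mm is not None \
        else config.d_max_mm
    depths = np.arange(start, config.film_length_mm + 1e-9, config.step_mm)
    doses = mu * config.cal_factor * pdd_percent(depths, config) / 100.0
    keep = (doses >= config.dose_min) & (doses <= config.dose_max)
    depths, doses = depths[keep], doses[keep]
    cols = {"lot_id": lot.lot_id,
            "calibration_index": calibration_index,
            "shelf_age_months": shelf_age_months,
            "position_mm": depths}
    for ch in CHANNELS:
        pre, post = simulate_pv(doses, ch, lot, shelf_age_months, rng,
                                noise_sigma=config.noise_sigma)
        cols[f"{ch}_bpv"] = pre
        cols[f"{ch}_ipv"] = post
    cols["dose_cGy"] = doses
    return pd.DataFrame(cols)[SAMPLE_TABLE_COLUMNS]


def generate_study(lots, calibrations_per_lot, config: SimConfig,
                   rng=None) -> pd.DataFrame:
    """Full multi-lot study: one film per (mu, shelf age) session.

    ``calibrations_per_lot`` maps each lot's position in ``lots`` to a
    list of (mu, shelf_age_months) sessions; sessions are numbered from 1
    in list order.  Returns one long sample table.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    frames = []
    for lot, sessions in zip(lots, calibrations_per_lot):
        for idx, (mu, age) in enumerate(sessions, start=1):
            mus = mu if np.iterable(mu) else (mu,)
            for m in mus:
                frames.append(simulate_calibration_film(
                    m, lot, age, config, rng, calibration_index=idx))
    return pd.concat(frames, ignore_index=True)


# MU settings cycled over the training lot's sessions; four bands cover
# ~28-400 cGy through the depth-dose fall-off while every individual
# film spans a factor ~3.5 in dose.
TRAINING_MU_CYCLE = (100.0, 200.0, 300.0, 400.0)

#: (mu, shelf_age_months) sessions emulating the study design: a training
#: lot exposed 17 times within 20 months (the 16th-to-17th gap is 4
#: months), plus two held-out lots calibrated while the training lot aged.
#: Held-out verification films use MU >= 250 so their doses stay above
#: ~70 cGy, the low end of the clinical verification range.  Each new
#: lot's first calibration session uses two films (250 and 400 MU) so the
#: lot-transfer refit covers the whole dose range it will correct.
LOT_A_MU = ((250.0, 400.0), 300.0, 350.0, 400.0, 250.0, 300.0, 350.0)
LOT_B_MU = ((250.0, 400.0), 300.0, 250.0)


def default_study_design() -> dict:
    """Session lists for the training lot C and held-out lots A and B."""
    ages_c = list(np.linspace(0.0, 16.0, 16)) + [20.0]
    mu_c = [TRAINING_MU_CYCLE[i % 4] for i in range(16)] + [400.0]
    return {
        "C": list(zip(mu_c, ages_c)),
        "A": list(zip(LOT_A_MU, np.linspace(2.0, 8.0, 7))),
        "B": list(zip(LOT_B_MU, (3.0, 5.0, 7.0))),
    }


def write_synthetic_scans(film: pd.DataFrame, dpi: float, out_dir,
                          width_px: int = 64, prefix: str = "film") -> tuple:
    """Render one film's pre/post sample PVs as 16-bit RGB TIFF pairs.

    The film's midline profile is interpolated onto the scanner's row
    grid and replicated across the width, so reading the images back
    through the scan pipeline reproduces the sample PVs up to 16-bit
    quantisation.  Returns (prescan_path, postscan_path).
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    positions = film["position_mm"].to_numpy(dtype=float)
    mm_per_px = 25.4 / dpi
    n_rows = int(np.floor(positions.max() / mm_per_px)) + 1
    row_mm = np.arange(n_rows) * mm_per_px
    paths = []
    for role, tag in (("prescan", "bpv"), ("postscan", "ipv")):
        planes = []
        for ch in CHANNELS:
            pv = film[f"{ch}_{tag}"].to_numpy(dtype=float)
            planes.append(np.interp(row_mm, positions, pv))
        img = np.stack(planes, axis=-1)[:, None, :]
        img = np.repeat(img, width_px, axis=1)
        img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
        path = out_dir / f"{prefix}_{role}.tif"
        tifffile.imwrite(path, img, photometric="rgb",
                         resolution=(dpi, dpi), resolutionunit="INCH")
        paths.append(path)
    return tuple(paths)
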