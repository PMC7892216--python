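"""Intralot cubic refit and the verification error statistics.

A network trained on one film lot systematically mis-doses films from
other lots, because lot sensitivity differs; the mapping from the network
estimate H to the true dose is, however, smooth and monotone.  A cubic
polynomial

    D_rfit = e*H^3 + f*H^2 + g*H + k

fitted on a single calibration film of the new lot corrects the remaining
sessions of that lot.  For the training lot itself no refit is applied
(D_rd = H), which is how the aging verification is run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conventional import percent_error

__all__ = [
    "RefitPoly",
    "CubicRefit",
    "ErrorReport",
    "fit_refit_poly",
    "apply_refit",
    "percent_error_hnn",
    "error_report",
    "run_aging_test",
    "run_intralot_test",
]


@dataclass
class RefitPoly:
    """Cubic lot-transfer polynomial (coefficients in descending powers)."""

    e: float
    f: float
    g: float
    k: float
    source_lot: str = ""
    h_min: float = -np.inf
    h_max: float = np.inf

    @property
    def coeffs(self) -> np.ndarray:
        return np.array([self.e, self.f, self.g, self.k])

    def predict(self, H):
        return apply_refit(self, H)

    def extrapolates(self, H) -> np.ndarray:
        """True where H lies outside the fitted range (cubics diverge)."""
        H = np.asarray(H, dtype=float)
        return (H < self.h_min) | (H > self.h_max)

    def to_dict(self) -> dict:
        return {"e": self.e, "f": self.f, "g": self.g, "k": self.k,
                "source_lot": self.source_lot,
                "h_min": self.h_min, "h_max": self.h_max}

    def summary(self) -> str:
        return (
            "Cubic intralot refit  D_rfit = e*H^3 + f*H^2 + g*H + k\n"
            f"  e = {self.e:+.6e}  f = {self.f:+.6e}\n"
            f"  g = {self.g:+.6e}  k = {self.k:+.6e}\n"
            f"  fitted over H in [{self.h_min:.1f}, {self.h_max:.1f}] cGy"
            + (f"  (lot {self.source_lot})" if self.source_lot else "")
        )


class CubicRefit:
    """Ordinary least-squares cubic of delivered dose on the estimate H."""

    def __init__(self, H, dose, source_lot: str = ""):
        self.H = np.asarray(H, dtype=float)
        self.dose = np.asarray(dose, dtype=float)
        self.source_lot = source_lot
        if self.H.size != self.dose.size:
            raise ValueError("H and dose must have equal length")
        if self.H.size < 4:
            raise ValueError("a cubic refit needs at least 4 samples")
        if np.ptp(self.H) == 0 or np.ptp(self.dose) == 0:
            raise ValueError("refit samples must span a nonzero range")

    def fit(self) -> RefitPoly:
        coeffs = np.polyfit(self.H, self.dose, deg=3)
        return RefitPoly(*(float(c) for c in coeffs),
                         source_lot=self.source_lot,
                         h_min=float(self.H.min()), h_max=float(self.H.max()))


def fit_refit_poly(H, dose, source_lot: str = "") -> RefitPoly:
    """Functional wrapper: ``CubicRefit(H, dose).fit()``."""
    return CubicRefit(H, dose, source_lot=source_lot).fit()


def apply_refit(poly: RefitPoly, H):
    """Evaluate the cubic; the result is the lot-corrected dose D_rd."""
    H = np.asarray(H, dtype=float)
    return np.polyval(poly.coeffs, H)


def percent_error_hnn(d_rd, d_d):
    """Signed percentage error (D_rd - D_d) / D_d * 100 of the network route."""
    return percent_error(d_rd, d_d)


@dataclass
class ErrorReport:
    """Per-sample and summary verification statistics.

    Percent errors are signed; MSE is in cGy^2 (its square root and the
    MAE in cGy).  ``extrapolated`` counts samples where a refit cubic was
    evaluated outside its fitted H range.
    """

    errors_percent: np.ndarray = field(repr=False)
    max_abs_percent: float
    mean_abs_percent: float
    mse: float
    rmse: float
    mae: float
    n: int
    extrapolated: int = 0

    def to_dict(self) -> dict:
        return {
            "max_abs_percent": self.max_abs_percent,
            "mean_abs_percent": self.mean_abs_percent,
            "mse_cGy2": self.mse,
            "rmse_cGy": self.rmse,
            "mae_cGy": self.mae,
            "n": self.n,
            "extrapolated": self.extrapolated,
        }

    def summary(self) -> str:
        lines = [
            f"Verification on n = {self.n} samples",
            f"  max |error| = {self.max_abs_percent:.3f} %   "
            f"mean |error| = {self.mean_abs_percent:.3f} %",
            f"  MSE = {self.mse:.3f} cGy^2   RMSE = {self.rmse:.3f} cGy   "
            f"MAE = {self.mae:.3f} cGy",
        ]
        if self.extrapolated:
            lines.append(f"  warning: {self.extrapolated} samples evaluated "
                         "outside the refit's fitted H range")
        return "\n".join(lines)


def error_report(predicted, delivered, extrapolated: int = 0) -> ErrorReport:
    """Summarise predicted-vs-delivered doses into an ErrorReport."""
    predicted = np.asarray(predicted, dtype=float)
    delivered = np.asarray(delivered, dtype=float)
    if predicted.size == 0:
        raise ValueError("empty test set")
    errs = percent_error_hnn(predicted, delivered)
    resid = predicted - delivered
    return ErrorReport(
        errors_percent=errs,
        max_abs_percent=float(np.max(np.abs(errs))),
        mean_abs_percent=float(np.mean(np.abs(errs))),
        mse=float(np.mean(resid ** 2)),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        mae=float(np.mean(np.abs(resid))),
        n=predicted.size,
        extrapolated=extrapolated,
    )


def _features_and_dose(samples):
    if isinstance(samples, pd.DataFrame):
        return samples, samples["dose_cGy"].to_numpy(dtype=float)
    samples = list(samples)
    if not samples:
        raise ValueError("empty test set")
    X = np.vstack([s.features.as_array() for s in samples])
    return X, np.array([s.dose for s in samples])


def run_aging_test(model, test) -> ErrorReport:
    """Aging verification: same lot, later shelf age, no refit (D_rd = H)."""
    feats, dose = _features_and_dose(test)
    H = model.predict(feats)
    return error_report(H, dose)


def run_intralot_test(model, refit_samples, test) -> tuple[ErrorReport, RefitPoly]:
    """New-lot verification: cubic refit on the lot's first calibration.

    Fits the transfer cubic on ``refit_samples``, applies it to ``test``
    and reports the error statistics together with the fitted polynomial.
    """
    rfeats, rdose = _features_and_dose(refit_samples)
    poly = fit_refit_poly(model.predict(rfeats), rdose)
    tfeats, tdose = _features_and_dose(test)
    H = model.predict(tfeats)
    d_rd = apply_refit(poly, H)
    n_extrap = int(poly.extrapolates(H).sum())
    return error_report(d_rd, tdose, extrapolated=n_extrap), poly


def per_sample_table(predicted, delivered, H=None) -> pd.DataFrame:
    """CSV-ready per-sample verification table."""
    predicted = np.asarray(predicted, dtype=float)
    delivered = np.asarray(delivered, dtype=float)
    return pd.DataFrame({
        "dose_cGy": delivered,
        "H_cGy": predicted if H is None else np.asarray(H, dtype=float),
        "D_rd_cGy": predicted,
        "percent_error": percent_error_hnn(predicted, delivered),
    })
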