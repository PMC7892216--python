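"""Conventional red-channel net-OD calibration.

The classical approach fits delivered dose against the red-channel net
optical density with the power function

    D_fit = a * NOD + b * NOD**c

in two stages: stage 1 leaves ``a`` and ``b`` free and bounds the exponent
``c`` in [1, 3]; the fitted exponent is then rounded to the nearest tenth
and stage 2 refits ``a`` and ``b`` with ``c`` held at the rounded value
(warm-started from the stage-1 parameters).  Rounding-then-fixing gives a
calibration whose exponent is a tidy, reportable constant while the linear
and power amplitudes absorb the residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PowerFit",
    "PowerCalibration",
    "fit_power_two_stage",
    "eval_power",
    "percent_error",
]


@dataclass
class PowerFit:
    """Fitted parameters of the two-stage power calibration.

    ``a`` is in cGy per unit NOD, ``b`` in cGy per NOD**c, ``c`` is
    dimensionless; ``residual`` is the RMS fit residual in cGy.
    """

    a: float
    b: float
    c: float
    residual: float
    stage: int = 2
    stage1_c: float | None = None
    n_samples: int = 0

    def predict(self, nod):
        return eval_power(self, nod)

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c,
            "stage1_c": self.stage1_c,
            "rms_residual_cGy": self.residual,
            "n_samples": self.n_samples,
        }

    def summary(self) -> str:
        lines = [
            "Conventional red-channel NOD power calibration",
            "  D_fit = a*NOD + b*NOD^c",
            f"  a = {self.a:12.4f} cGy/NOD",
            f"  b = {self.b:12.4f} cGy/NOD^c",
            f"  c = {self.c:12.4f}  (stage-1 estimate {self.stage1_c:.4f}, "
            "rounded to the nearest tenth and fixed)",
            f"  RMS residual = {self.residual:.4f} cGy on n = {self.n_samples}",
        ]
        return "\n".join(lines)


class PowerCalibration:
    """Two-stage constrained power-function calibration model.

    Parameters
    ----------
    nod : array-like
        Red-channel net optical densities (non-negative, not all equal).
    dose : array-like
        Delivered doses in cGy, same length.

    ``fit()`` returns a :class:`PowerFit` results object.
    """

    #: multi-start values for the exponent; the cost surface in c has
    #: local minima when a and b trade off against each other.
    C_STARTS = (1.5, 2.0, 2.5)

    def __init__(self, nod, dose):
        self.nod = np.asarray(nod, dtype=float)
        self.dose = np.asarray(dose, dtype=float)
        if self.nod.size != self.dose.size:
            raise ValueError("nod and dose must have equal length")
        if self.nod.size < 4:
            raise ValueError("need at least 4 samples")
        if np.any(self.nod < 0):
            raise ValueError("nod values must be non-negative")
        if np.ptp(self.nod) == 0:
            raise ValueError("degenerate data: all nod values equal")

    @classmethod
    def from_dataframe(cls, frame, nod_col="r_nod", dose_col="dose_cGy"):
        return cls(frame[nod_col], frame[dose_col])

    def _residual(self, params):
        a, b, c = params
        return a * self.nod + b * np.power(self.nod, c) - self.dose

    def fit(self) -> PowerFit:
        # linear pre-fit D ~ a*nod gives the scale for a; b starts small
        denom = float(self.nod @ self.nod)
        a0 = float(self.nod @ self.dose) / denom if denom > 0 else 1.0
        best = None
        for c0 in self.C_STARTS:
            try:
                sol = least_squares(
                    self._residual, x0=[a0, 1.0, c0],
                    bounds=([-np.inf, -np.inf, 1.0], [np.inf, np.inf, 3.0]),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError("stage-1 power fit failed to converge")
        a1, b1, c1 = best.x
        c_fixed = round(c1, 1)
        c_fixed = min(max(c_fixed, 1.0), 3.0)

        def resid_ab(params):
            a, b = params
            return a * self.nod + b * np.power(self.nod, c_fixed) - self.dose

        sol2 = least_squares(resid_ab, x0=[a1, b1],
                             xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if not sol2.success:
            raise RuntimeError("stage-2 power fit failed to converge")
        a2, b2 = sol2.x
        rms = float(np.sqrt(np.mean(resid_ab(sol2.x) ** 2)))
        return PowerFit(a=float(a2), b=float(b2), c=float(c_fixed),
                        residual=rms, stage=2, stage1_c=float(c1),
                        n_samples=self.nod.size)


def fit_power_two_stage(nod, dose) -> PowerFit:
    """Functional wrapper: ``PowerCalibration(nod, dose).fit()``."""
    return PowerCalibration(nod, dose).fit()


def eval_power(fit: PowerFit, nod):
    """Evaluate D = a*nod + b*nod^c; this is the conventional dose D_c."""
    nod = np.asarray(nod, dtype=float)
    if np.any(nod < 0):
        raise ValueError("nod must be non-negative")
    return fit.a * nod + fit.b * np.power(nod, fit.c)


def percent_error(calculated, delivered):
    """Signed percentage error (D_c - D_d) / D_d * 100."""
    calculated = np.asarray(calculated, dtype=float)
    delivered = np.asarray(delivered, dtype=float)
    if np.any(delivered <= 0):
        raise ValueError("delivered dose must be positive")
    return (calculated - delivered) / delivered * 100.0
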