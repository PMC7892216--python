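"""The end-to-end verification study on synthetic films.

This module wires the whole pipeline together in the shape of the film
study the calibration method is designed for:

* a training lot ("C") exposed 17 times within 20 months, the gap between
  the 16th and 17th calibration being 4 months;
* the first 11 sessions (portion I) train a network used for the
  *intralot* verification on two held-out lots: lot "A" (sensitivity
  +7%) with 7 calibrations and lot "B" (sensitivity -5%) with 3; the
  cubic lot-transfer refit is fitted on each new lot's first calibration
  and judged on the remaining sessions;
* the first 16 sessions (portion II) train a network used for the
  *aging* verification on the 17th session, with no refit;
* for context, the conventional power-law calibration is fitted on the
  16th session and evaluated on the 17th — the aging failure mode the
  network method is meant to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conventional import eval_power, fit_power_two_stage, percent_error
from .features import features_from_table
from .hnn import HNNCalibration, HNNResults, TrainConfig
from .refit_eval import (ErrorReport, RefitPoly, error_report,
                         run_aging_test, run_intralot_test)
from .synthetic_film import SimConfig, default_lot, default_study_design, \
    generate_study

__all__ = ["StudyResults", "run_verification_study", "generate_study_table"]

#: sensitivity multipliers of the held-out lots; the new lots differ from
#: the training lot in their net-OD sensitivity factor only (lot-to-lot
#: background-level shifts additionally confound the network's shelf-age
#: proxy and are studied separately — see the methods note)
HELD_OUT_LOTS = {"A": 1.07, "B": 0.95}


@dataclass
class StudyResults:
    """All verification outputs of one synthetic study."""

    aging: ErrorReport
    intralot: dict
    refits: dict
    conventional_aging: ErrorReport | None
    portion_one: HNNResults = field(repr=False, default=None)
    portion_two: HNNResults = field(repr=False, default=None)
    n_aging: int = 0
    n_intralot: int = 0

    @property
    def aging_max_percent(self) -> float:
        """Max |percent error| of the aging verification (network, no refit)."""
        return self.aging.max_abs_percent

    @property
    def intralot_max_percent(self) -> float:
        """Max |percent error| over all held-out-lot verification samples."""
        return max(r.max_abs_percent for r in self.intralot.values())

    @property
    def mean_verification_mse(self) -> float:
        """Per-test MSE (cGy^2) averaged over aging and intralot tests."""
        mses = [self.aging.mse] + [r.mse for r in self.intralot.values()]
        return float(np.mean(mses))

    def summary(self) -> str:
        lines = ["Synthetic verification study",
                 "", "Aging test (training lot, +4 months, D_rd = H):",
                 "  " + self.aging.summary().replace("\n", "\n  ")]
        for lot_id, rep in self.intralot.items():
            lines += [f"Intralot test, lot {lot_id} (refit on 1st calibration):",
                      "  " + rep.summary().replace("\n", "\n  ")]
        if self.conventional_aging is not None:
            lines += ["Conventional power-law calibration on the aged session:",
                      "  " + self.conventional_aging.summary().replace("\n",
                                                                       "\n  ")]
        lines.append(f"Averaged verification MSE: "
                     f"{self.mean_verification_mse:.2f} cGy^2")
        return "\n".join(lines)


def generate_study_table(seed: int = 435,
                         noise_sigma: float = 0.003) -> pd.DataFrame:
    """The full three-lot synthetic sample table (features not yet built)."""
    config = SimConfig(seed=seed, noise_sigma=noise_sigma)
    design = default_study_design()
    lots = [default_lot("C")]
    sessions = [design["C"]]
    for lot_id, sens in HELD_OUT_LOTS.items():
        lots.append(default_lot(lot_id, sensitivity=sens))
        sessions.append(design[lot_id])
    return generate_study(lots, sessions, config)


def run_verification_study(seed: int = 435, noise_sigma: float = 0.003,
                           include_conventional: bool = True,
                           epochs: int = 500) -> StudyResults:
    """Generate the synthetic study, train both networks, run all tests.

    ``seed`` drives every source of randomness: the film simulator and
    both training runs.
    """
    feats = features_from_table(generate_study_table(seed, noise_sigma))
    lot_c = feats[feats.lot_id == "C"]
    config = TrainConfig(seed=seed, epochs=epochs)

    # aging verification: portion II (sessions 1-16) -> session 17
    portion_two = HNNCalibration(
        lot_c[lot_c.calibration_index <= 16]).fit(config)
    session17 = lot_c[lot_c.calibration_index == 17]
    aging = run_aging_test(portion_two, session17)

    # intralot verification: portion I (sessions 1-11) -> lots A and B
    portion_one = HNNCalibration(
        lot_c[lot_c.calibration_index <= 11]).fit(config)
    intralot, refits = {}, {}
    n_intra = 0
    for lot_id in HELD_OUT_LOTS:
        lot = feats[feats.lot_id == lot_id]
        first = lot[lot.calibration_index == 1]
        rest = lot[lot.calibration_index > 1]
        report, poly = run_intralot_test(portion_one, first, rest)
        intralot[lot_id], refits[lot_id] = report, poly
        n_intra += report.n

    conventional = None
    if include_conventional:
        s16 = lot_c[lot_c.calibration_index == 16]
        power = fit_power_two_stage(s16["r_nod"], s16["dose_cGy"])
        d_c = eval_power(power, session17["r_nod"])
        conventional = error_report(d_c, session17["dose_cGy"].to_numpy())

    return StudyResults(aging=aging, intralot=intralot, refits=refits,
                        conventional_aging=conventional,
                        portion_one=portion_one, portion_two=portion_two,
                        n_aging=aging.n, n_intralot=n_intra)
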