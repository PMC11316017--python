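"""Published reference values from the original rat thermal-neutron study.

The package ships the fitted calibration constants, correlation
diagnostics, per-marker RAR equivalent doses (RARED) and RAR factors
(RARF), and the seven-group irradiation design of the whole-body rat
study it implements.  These serve three roles:

* defaults for the synthetic-study generator, so a simulated study
  "looks like" the real one;
* fixtures for the built-in cross-check (``rardose reproduce-table7``)
  that re-derives every RARF cell and the aggregate rows from the
  published RARED values;
* worked-example inputs in the documentation.

All doses are equivalent doses in mSv; the acute calibration groups span
0-50 mSv at a dose rate of 1.5 mSv/h.
"""

from __future__ import annotations

from .core import DoseCondition

__all__ = [
    "CALIBRATION_CONSTANTS",
    "RAR_MARKERS",
    "MARKER_UNITS",
    "REFERENCE_RARED",
    "REFERENCE_RARF",
    "REFERENCE_AGGREGATES",
    "CONDITIONS",
    "ACUTE_DOSES",
    "DEFAULT_DESIGN_ROWS",
    "KNOWN_INCONSISTENCIES",
]

#: acute single-dose groups used to fit every calibration curve (mSv)
ACUTE_DOSES = (0.0, 5.0, 10.0, 50.0)

#: the two priming+challenge conditions, keyed by their report label
CONDITIONS: dict[str, DoseCondition] = {
    "5+50": DoseCondition(priming_dose=5.0, challenge_dose=50.0),
    "10+50": DoseCondition(priming_dose=10.0, challenge_dose=50.0),
}

#: published dose-response fits over the acute groups.  ``r_value`` is the
#: signed dose-response correlation for linear fits and the observed-vs-
#: fitted correlation for nonlinear fits; ``p_value`` is present only
#: where a correlation p was published.
CALIBRATION_CONSTANTS: dict[str, dict] = {
    "GSH": {
        "family": "exponential",
        "constants": {"A": 88.43, "R0": -0.085, "y0": 14.8},
        "r_value": 0.962,
    },
    "CAT": {
        "family": "exponential",
        "constants": {"A": 6.05e-3, "R0": -0.054, "y0": 88.8e-3},
        "r_value": 0.995,
    },
    "SOD": {
        "family": "linear",
        "constants": {"a": -22e-4, "b": 0.6365},
        "r_value": -0.994,
        "p_value": 0.006,
    },
    "MDA": {
        "family": "quadratic",
        "constants": {"intercept": 31.93, "B1": 8.15, "B2": -0.103},
        "r_value": 0.9331,
        "p_value": 0.258,
    },
    "EPR": {
        "family": "linear",
        "constants": {"a": 0.153, "b": 45.0},
        "r_value": 0.9996,
        "p_value": 4.03e-4,
    },
    "CA%": {
        "family": "exponential",
        "constants": {"A": -14.04, "R0": -0.112, "y0": 21.18},
        "r_value": 0.9996,
    },
    "TM": {
        "family": "exponential",
        "constants": {"A": -1.342, "R0": -0.067, "y0": 2.506},
        "r_value": 0.9999,
    },
    "DNA%": {
        "family": "linear",
        "constants": {"a": 149e-3, "b": 9.852},
        "r_value": 0.991,
        "p_value": 8.9e-4,
    },
    "TL": {
        "family": "quadratic",
        "constants": {"intercept": 6.136, "B1": 0.1886, "B2": -19e-4},
        "r_value": 0.9992,
        "p_value": 0.0402,
    },
    "OTM": {
        "family": "exponential",
        "constants": {"A": -1.211, "R0": -0.0214, "y0": 1.741},
        "r_value": 0.993,
    },
    "Hb": {
        "family": "linear",
        "constants": {"a": -115e-4, "b": 14.78},
        "r_value": -0.979,
        "p_value": 0.011,
    },
    "MCV": {
        "family": "exponential",
        "constants": {"A": -9.73, "R0": -0.095, "y0": 101.4},
        "r_value": 0.997,
    },
    "RDWs": {
        "family": "linear",
        "constants": {"a": 141e-3, "b": 28.43},
        "r_value": 0.9931,
        "p_value": 0.007,
    },
}

#: the 11 markers carried through the RAR table, in report column order
RAR_MARKERS = (
    "GSH", "CAT", "SOD", "MDA", "EPR", "TM", "DNA%", "TL", "OTM", "Hb", "RDWs",
)

#: nominal units per marker (synthetic defaults; units travel with readings)
MARKER_UNITS: dict[str, str] = {
    "GSH": "mg/dL",
    "CAT": "U/mL",
    "SOD": "U/mL",
    "MDA": "nmol/mL",
    "EPR": "a.u.",
    "CA%": "%",
    "TM": "um",
    "DNA%": "%",
    "TL": "um",
    "OTM": "um",
    "Hb": "g/dL",
    "MCV": "fL",
    "RDWs": "%",
    "HCT": "%",
    "MCHC": "g/dL",
}

#: published per-marker RAR equivalent doses (mSv), by condition label
REFERENCE_RARED: dict[str, dict[str, float]] = {
    "5+50": {
        "GSH": 9.7, "CAT": 5.6, "SOD": 7.4, "MDA": 6.1, "EPR": 19.4,
        "TM": 9.4, "DNA%": 9.6, "TL": 9.6, "OTM": 13.1, "Hb": 16.6,
        "RDWs": 14.6,
    },
    "10+50": {
        "GSH": 19.9, "CAT": 16.5, "SOD": 23.6, "MDA": 16.6, "EPR": 32.6,
        "TM": 18.8, "DNA%": 22.8, "TL": 17.9, "OTM": 23.8, "Hb": 40.9,
        "RDWs": 20.6,
    },
}

#: published per-marker RAR factors, by condition label
REFERENCE_RARF: dict[str, dict[str, float]] = {
    "5+50": {
        "GSH": 0.91, "CAT": 0.99, "SOD": 0.96, "MDA": 0.98, "EPR": 0.92,
        "TM": 0.92, "DNA%": 0.92, "TL": 0.92, "OTM": 0.85, "Hb": 0.79,
        "RDWs": 0.83,
    },
    "10+50": {
        "GSH": 0.84, "CAT": 0.89, "SOD": 0.77, "MDA": 0.89, "EPR": 0.62,
        "TM": 0.85, "DNA%": 0.79, "TL": 0.87, "OTM": 0.77, "Hb": 0.49,
        "RDWs": 0.82,
    },
}

#: published row aggregates (mean, n-1 SD) of the RAR table
REFERENCE_AGGREGATES = {
    "5+50": {"rared_mean": 10.1, "rared_sd": 3.4, "rarf_mean": 0.91, "rarf_sd": 0.06},
    "10+50": {"rared_mean": 23.1, "rared_sd": 7.5, "rarf_mean": 0.78, "rarf_sd": 0.12},
}

#: internal inconsistencies of the published table, surfaced (never "fixed"):
#: the EPR 5+50 RARED of 19.4 mSv yields a factor of 0.74 under the defining
#: formula, not the printed 0.92; a RARED of 9.4 mSv would reproduce both the
#: printed factor and the printed 5+50 average 10.1 +/- 3.4.
KNOWN_INCONSISTENCIES = (
    {
        "condition": "5+50",
        "marker": "EPR",
        "published_rared": 19.4,
        "published_rarf": 0.92,
        "note": (
            "published RARED 19.4 mSv implies RARF 0.74; RARED 9.4 mSv would "
            "reproduce the published RARF 0.92 and the published row average "
            "10.1 +/- 3.4 (suspected transcription slip)"
        ),
    },
)

#: the seven-group irradiation plan (doses mSv, interval days, readout hours)
DEFAULT_DESIGN_ROWS = (
    {"group_id": "G1", "role": "control", "priming_dose_mSv": 0.0,
     "challenge_dose_mSv": 0.0, "interval_days": None, "readout_hr": 24, "n_animals": 5},
    {"group_id": "G2", "role": "acute", "priming_dose_mSv": 5.0,
     "challenge_dose_mSv": 0.0, "interval_days": 14, "readout_hr": 24, "n_animals": 5},
    {"group_id": "G3", "role": "acute", "priming_dose_mSv": 10.0,
     "challenge_dose_mSv": 0.0, "interval_days": 14, "readout_hr": 24, "n_animals": 5},
    {"group_id": "G4", "role": "acute", "priming_dose_mSv": 50.0,
     "challenge_dose_mSv": 0.0, "interval_days": 14, "readout_hr": 24, "n_animals": 5},
    {"group_id": "G5", "role": "rar_control", "priming_dose_mSv": 0.0,
     "challenge_dose_mSv": 50.0, "interval_days": None, "readout_hr": 24, "n_animals": 5},
    {"group_id": "G6", "role": "combined", "priming_dose_mSv": 5.0,
     "challenge_dose_mSv": 50.0, "interval_days": 14, "readout_hr": 24, "n_animals": 5},
    {"group_id": "G7", "role": "combined", "priming_dose_mSv": 10.0,
     "challenge_dose_mSv": 50.0, "interval_days": 14, "readout_hr": 24, "n_animals": 5},
)
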