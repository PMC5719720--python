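"""Published reference calibration rows and the RPD printing-identity check.

The bundled ``data/reference_calibration_rows.csv`` holds published
calibration-table rows (N, Terms, derivative code, scatter method, range,
mean, SD, SEC, R², SECV, R²cv, RPD) for a transgenic rice straw population.
Every statistic is printed to two decimals, so the identity RPD = SD/SECV
can only be checked up to rounding: a printed RPD is *consistent* when the
interval of ratios attainable from SD and SECV values that round to the
printed ones overlaps the interval of values that round to the printed RPD.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from nirscal.modelstats import rpd


def load_reference_rows() -> pd.DataFrame:
    """The bundled published calibration-table rows."""
    with resources.files("nirscal.data").joinpath("reference_calibration_rows.csv").open() as fh:
        return pd.read_csv(fh)


def rpd_identity_check(rows: pd.DataFrame | None = None, decimals: int = 2) -> pd.DataFrame:
    """Recompute SD/SECV for each printed row and test rounding consistency.

    Adds columns ``rpd_recomputed`` (point ratio of the printed SD and
    SECV), ``rpd_lo``/``rpd_hi`` (the ratio interval over all unrounded
    values compatible with the printed SD/SECV) and ``consistent`` (True
    when that interval overlaps the half-unit interval around the printed
    RPD).
    """
    rows = load_reference_rows() if rows is None else rows.copy()
    half = 0.5 * 10.0**-decimals
    out = rows.copy()
    out["rpd_recomputed"] = [rpd(r.sd, r.secv) for r in rows.itertuples()]
    out["rpd_lo"] = (rows["sd"] - half) / (rows["secv"] + half)
    out["rpd_hi"] = (rows["sd"] + half) / (rows["secv"] - half)
    out["consistent"] = (out["rpd_lo"] < rows["rpd"] + half) & (
        out["rpd_hi"] > rows["rpd"] - half
    )
    return out
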