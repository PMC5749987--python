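"""Semi-empirical propagation of shallow-water detonation sound.

Similitude relations for the peak pressure and sound exposure level (SEL)
of an underwater charge at range r (metres):

    p_peak = 52.16e6 * (W^(1/3) / r)^1.13          [Pa]
    SEL    = 6.14 log10(W) - 13.26 log10(r) + A    [dB re 1 uPa^2 s]

The additive SEL constant ``A`` is calibrated once, by least squares,
against a published eight-cell reference table of SEL values (two charge
weights x four ranges), which insulates the module against transcription
differences in the source constant.

Weight convention: the reference table is reproduced by plugging the
numeric charge weight exactly as tabulated (nominal pounds of C4) into
the similitude formulas, even though those formulas are written for kg of
TNT; back-solving the table is inconsistent with any standard conversion
factor.  The functions therefore treat ``weight`` as the as-printed
number by default.  ``c4_lb_to_tnt_kg`` is provided for physically
explicit use.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE_SCENARIOS",
    "peak_pressure",
    "sel",
    "calibrate_sel_offset",
    "scenario_table",
    "c4_lb_to_tnt_kg",
]

PEAK_COEFF = 52.16e6   # Pa
PEAK_EXPONENT = 1.13
SEL_WEIGHT_SLOPE = 6.14
SEL_RANGE_SLOPE = -13.26

#: Reference SEL / peak-pressure cells: two charge weights at four ranges.
REFERENCE_SCENARIOS = pd.DataFrame(
    {
        "range_m": [1000, 1000, 3000, 3000, 6000, 6000, 12000, 12000],
        "weight": [5, 20, 5, 20, 5, 20, 5, 20],
        "sel_db": [183, 187, 177, 181, 173, 177, 169, 173],
        "peak_pa": [39139, 65976, 11310, 19065, 5168, 8711, 2361, 3980],
    }
)


def _validate(weight, range_m) -> tuple[np.ndarray, np.ndarray]:
    w = np.asarray(weight, dtype=float)
    r = np.asarray(range_m, dtype=float)
    if np.any(w <= 0) or np.any(r <= 0):
        raise ValueError("weight and range must be > 0")
    return w, r


def peak_pressure(weight, range_m) -> float | np.ndarray:
    """Peak pressure (Pa) of a charge of given weight at range ``range_m`` (m)."""
    w, r = _validate(weight, range_m)
    out = PEAK_COEFF * (np.cbrt(w) / r) ** PEAK_EXPONENT
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=1)
def calibrate_sel_offset() -> float:
    """Least-squares additive constant A from the eight reference SEL cells.

    With the slopes fixed, the least-squares A is the mean over cells of
    ``sel - 6.14 log10 W + 13.26 log10 r``.
    """
    t = REFERENCE_SCENARIOS
    a = (
        t["sel_db"]
        - SEL_WEIGHT_SLOPE * np.log10(t["weight"])
        - SEL_RANGE_SLOPE * np.log10(t["range_m"])
    )
    return float(a.mean())


def sel(weight, range_m, offset: float | None = None) -> float | np.ndarray:
    """Sound exposure level (dB re 1 uPa^2 s) at range ``range_m`` (m).

    Uses the calibrated additive constant unless ``offset`` is given.
    Unrounded; round to the nearest dB for reporting.
    """
    w, r = _validate(weight, range_m)
    a = calibrate_sel_offset() if offset is None else offset
    out = SEL_WEIGHT_SLOPE * np.log10(w) + SEL_RANGE_SLOPE * np.log10(r) + a
    return float(out) if out.ndim == 0 else out


def scenario_table(weights=(5, 20), ranges_m=(1000, 3000, 6000, 12000)) -> pd.DataFrame:
    """Predicted SEL (rounded to nearest dB) and peak pressure over a grid."""
    rows = []
    for r in ranges_m:
        for w in weights:
            rows.append(
                {
                    "range_m": r,
                    "weight": w,
                    "sel_db": int(round(sel(w, r))),
                    "peak_pa": peak_pressure(w, r),
                }
            )
    return pd.DataFrame(rows)


def c4_lb_to_tnt_kg(pounds: float, equivalence: float = 1.34) -> float:
    """Convert nominal pounds of C4 to kg of TNT equivalent.

    ``equivalence`` is the TNT equivalence factor of C4 (about 1.34 on an
    energy basis).  Provided for physically explicit use of the similitude
    formulas; note the reference table itself is reproduced by the
    as-printed weights, not by converted ones.
    """
    if pounds <= 0:
        raise ValueError("pounds must be > 0")
    return pounds * 0.45359237 * equivalence
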