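"""Bundled reference sample: 20 wild western chimpanzee (*Pan troglodytes
verus*) immature femora — 18 from the Taï Forest skeletal collection and 2
from Sierra Leone.

For each specimen the table carries sex (blank when unrecorded), age at
death in years, side, maximum intermetaphyseal femur length in mm, micro-CT
voxel size in mm, locomotor stage, and how the age was established:

* ``documented`` — birth/death records or dental histology;
* ``year_only`` — birth year known to the year only (age within +/- 0.5 y);
* ``length_estimated`` — age itself estimated from femur length via the
  growth curve, so these rows must be excluded when *calibrating* that curve.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

KNOWN_AGE_SOURCES = ("documented", "year_only")


def load_reference_femora() -> pd.DataFrame:
    """The bundled 20-specimen chimpanzee femur table."""
    with resources.files("bonecsg.data").joinpath("chimp_femora.csv").open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    df["sex"] = df["sex"].replace("", None)
    return df


def calibration_pairs(
    df: pd.DataFrame | None = None,
    sources=KNOWN_AGE_SOURCES,
) -> pd.DataFrame:
    """(age, femur length) rows usable for growth-curve calibration.

    Defaults to every known-age specimen (documented plus year-only birth
    records, 16 of the 20); pass ``sources=("documented",)`` to restrict to
    the strictly documented subset.
    """
    if df is None:
        df = load_reference_femora()
    out = df[df["age_source"].isin(sources)]
    return out[["specimen_id", "age_years", "femur_length_mm"]].reset_index(drop=True)
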