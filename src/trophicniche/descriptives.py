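"""Descriptive statistics of the capture/tagging metadata table.

The packaged ``capture_records.csv`` lists, per captured individual, the
body measurements, tracking window, and whisker sampling details used by
the isotope and telemetry analyses.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_capture_records", "capture_summary"]


def load_capture_records(path=None) -> pd.DataFrame:
    if path is None:
        source = resources.files("trophicniche.data").joinpath("capture_records.csv")
        with source.open() as fh:
            return pd.read_csv(fh, parse_dates=["capture_date"])
    return pd.read_csv(path, parse_dates=["capture_date"])


def capture_summary(records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-species means (and SDs) of whisker length, body mass, body
    length, and tracking duration. Individuals with a missing tracking
    duration (tag malfunction) are excluded from that column only."""
    df = load_capture_records() if records is None else records
    rows = []
    for species, block in df.groupby("species", sort=True):
        rows.append(
            {
                "species": species,
                "n": len(block),
                "whisker_length_mean_mm": block["whisker_length_mm"].mean(),
                "whisker_length_sd_mm": block["whisker_length_mm"].std(ddof=1),
                "body_mass_mean_kg": block["body_mass_kg"].mean(),
                "body_mass_sd_kg": block["body_mass_kg"].std(ddof=1),
                "tracking_mean_days": block["tracking_days"].mean(),
                "tracking_sd_days": block["tracking_days"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows).set_index("species")
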