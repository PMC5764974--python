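"""Packaged reference datasets transcribed from the printed study tables.

These are fixtures for the screening and quantification rules (what the
published scores and calibration parameters were), not regression targets
for the models in this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "reference_library_table",
    "reference_screening_scores",
    "reference_calibration",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("hecm.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def reference_library_table() -> pd.DataFrame:
    """The 40-compound annotation library (verbatim transcription)."""
    return _read("reference_library.tsv")


def reference_screening_scores() -> pd.DataFrame:
    """Published per-peak VIP and MIV scores of the ten common peaks."""
    return _read("reference_screening_scores.tsv")


def reference_calibration() -> pd.DataFrame:
    """Published calibration parameters, LOD/LOQ and marker contents (%)."""
    return _read("reference_calibration.tsv")
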