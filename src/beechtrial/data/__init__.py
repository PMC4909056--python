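"""Published summary tables of the ten-provenance beech common-garden trial.

These small reference CSVs carry the trial's printed per-provenance climate
normals and result summaries (variance decomposition, climate-model fits,
provenance growth means).  They serve as fixtures and worked-example inputs;
the raw tree-level field data are unpublished, so pipeline-scale runs use the
:mod:`beechtrial.simulate` generators instead.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_origin_climate",
    "load_reference_varcomp",
    "load_reference_climate_model",
    "load_growth_means",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, **kwargs)


def load_origin_climate() -> pd.DataFrame:
    """Per-provenance climate of origin: MAT, MAP, MSP, EQ, GAI, FAI."""
    return _read("table1_climate.csv")


def load_reference_varcomp() -> pd.DataFrame:
    """Per-trait CVs, variance-component percentages and corrected LRTs.

    The ``p`` column is kept as printed (strings such as ``"<0.001"``).
    """
    return _read("reference_varcomp.csv", dtype={"p": str})


def load_reference_climate_model() -> pd.DataFrame:
    """Per-trait FAI climate-model estimates and ML likelihood-ratio tests."""
    return _read("reference_climate_model.csv")


def load_growth_means() -> pd.DataFrame:
    """Published provenance-mean ABI and BAI (only the printed extremes)."""
    return _read("provenance_growth_means.csv")
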