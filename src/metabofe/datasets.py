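"""Packaged reference tables for gate replay and worked examples.

Three small CSVs ship with the package: the published per-ion-mode genetic
parameter tables (heritability, genetic and phenotypic correlations with FCR
and RFI, estimate +/- SE, with "-" marking animal-model fits that did not
converge) and the line-mean concentration table of the selected biomarkers.
They let the four-criterion gate be replayed end to end without any
simulation or download.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_positive_mode_parameters",
    "load_negative_mode_parameters",
    "load_genetic_parameter_tables",
    "load_biomarker_line_means",
]

_NUMERIC = [
    "h2",
    "se_h2",
    "rg_fcr",
    "se_rg_fcr",
    "rg_rfi",
    "se_rg_rfi",
    "rp_fcr",
    "se_rp_fcr",
    "rp_rfi",
    "se_rp_rfi",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("metabofe.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, na_values=["-"])
    for col in df.columns:
        if col in _NUMERIC:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    return df


def load_positive_mode_parameters() -> pd.DataFrame:
    """Genetic parameters of the positive-ion-mode differential metabolites."""
    df = _read("genetic_parameters_positive.csv")
    df.insert(2, "ion_mode", "positive")
    return df


def load_negative_mode_parameters() -> pd.DataFrame:
    """Genetic parameters of the negative-ion-mode differential metabolites."""
    df = _read("genetic_parameters_negative.csv")
    df.insert(2, "ion_mode", "negative")
    return df


def load_genetic_parameter_tables() -> pd.DataFrame:
    """Both ion modes stacked (non-converged cells are NaN)."""
    return pd.concat(
        [load_positive_mode_parameters(), load_negative_mode_parameters()],
        ignore_index=True,
    )


def load_biomarker_line_means() -> pd.DataFrame:
    """Fat/lean line mean concentrations of the selected biomarkers."""
    df = _read("biomarker_line_means.csv")
    for col in ("mean_fat", "mean_lean"):
        df[col] = df[col].astype(float)
    return df
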