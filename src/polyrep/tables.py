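"""Loaders for the published per-hybridoma V(D)J annotation tables.

The package bundles the two printed annotation tables of the source study's
polyreactive antibodies — IgM and IgG hybridomas from the autoimmune-prone
strain at three ages — as tidy TSVs: gene segment calls (IGHV/IGHD/IGHJ,
IGkV/IGkJ), CDR3 amino-acid strings and their printed lengths.  Cells the
publication marks as not sequenced are ``"NS"``; an absent D call is ``"-"``.

These tables are real inputs, not fixtures: they drive the clone-grouping
and CDR3-length analyses that do not require raw sequence data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from polyrep.annotate import NS

_COLUMNS = ["id", "age_weeks", "isotype", "subclass", "heavy_v", "heavy_d",
            "heavy_j", "heavy_cdr3", "heavy_cdr3_length", "kappa_v", "kappa_j",
            "kappa_cdr3", "kappa_cdr3_length"]


def _load(name: str) -> pd.DataFrame:
    path = resources.files("polyrep").joinpath(f"data/tables/{name}")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    assert list(df.columns) == _COLUMNS
    df["age_weeks"] = df["age_weeks"].astype(int)
    for col in ("heavy_cdr3_length", "kappa_cdr3_length"):
        df[col] = pd.to_numeric(df[col].replace(NS, pd.NA), errors="raise").astype("Int64")
    return df


def load_igm_annotations() -> pd.DataFrame:
    """IgM hybridoma annotations (autoimmune-prone strain; 28/47/66 weeks)."""
    return _load("igm_annotations.tsv")


def load_igg_annotations() -> pd.DataFrame:
    """IgG hybridoma annotations with subclasses (same strain and ages)."""
    return _load("igg_annotations.tsv")


def load_all_annotations() -> pd.DataFrame:
    """Both tables concatenated, with an isotype column distinguishing them."""
    return pd.concat([load_igm_annotations(), load_igg_annotations()],
                     ignore_index=True)
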