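"""Accessors for the small packaged fixtures.

* ``load_published_calls`` — the published per-gene Z-scores of the top
  differentially expressed genes (25 up, 31 down), with calls re-derived
  from the Z values by the standard thresholds.
* ``load_literature_db`` — a partly synthetic reconstruction of the curated
  cisplatin literature label table (see the file header for which rows are
  reported vs synthetic-fill).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import LiteratureDB, read_literature_table
from .zscore import DEThresholds, apply_thresholds


def _data_path(name: str):
    return resources.files("toxarray.data").joinpath(name)


def load_published_zscores() -> pd.DataFrame:
    """Published Z-scores of the top up/downregulated genes (columns gene, z)."""
    with resources.as_file(_data_path("published_zscores.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_published_calls(thresholds: DEThresholds | None = None) -> pd.DataFrame:
    """The published Z table with UP/DOWN/STABLE/NONE calls applied."""
    df = load_published_zscores()
    df["call"] = apply_thresholds(df["z"], thresholds or DEThresholds())
    return df


def load_literature_db() -> LiteratureDB:
    """The packaged (partly synthetic) literature label fixture."""
    with resources.as_file(_data_path("literature_db_synthetic.tsv")) as p:
        return read_literature_table(p)
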