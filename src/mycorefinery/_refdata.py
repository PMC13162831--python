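"""Loader for the embedded pure-ester reference constant table."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd


@lru_cache(maxsize=1)
def reference_table() -> pd.DataFrame:
    """Pure-FAME fuel constants indexed by (carbons, double_bonds)."""
    with resources.files("mycorefinery.data").joinpath("fame_reference.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return df.set_index(["carbons", "double_bonds"])


def data_path(name: str):
    """Traversable handle to a packaged data file."""
    return resources.files("mycorefinery.data").joinpath(name)
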