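"""Bundled reference tables: published repeat statistics for land plants.

Two small compiled tables ship with the package:

* ``nuclear_repeat_content`` — nuclear repeat size, genome size and reported
  repeat/genome percentage for 22 land plants.
* ``mito_repeat_tiers`` — mitochondrial repeat size (kb) and repeat counts at
  the > 1 kb and > 100 bp tiers for 22 land plants.

Both serve as worked inputs for the ratio-table and tier-invariant analyses
and as realistic group structure (spermatophytes vs bryophytes) for the
comparative tests.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("igtscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_nuclear_repeat_table() -> pd.DataFrame:
    """Nuclear repeat/genome sizes (Mb) and reported percentages, 22 species."""
    return _load("nuclear_repeat_content.tsv")


def load_mito_repeat_tiers() -> pd.DataFrame:
    """Mitochondrial repeat size and two-tier repeat counts, 22 species."""
    return _load("mito_repeat_tiers.tsv")
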