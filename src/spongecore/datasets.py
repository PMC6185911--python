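"""Bundled reference data.

``survey_summary`` loads the per-species summary of a published field survey
of the 19 most abundant sponge species of Nha Trang Bay (Vietnam) plus
seawater, analysed with the same restrictive workflow this package
implements (ZOTU table rarefied to 41 000 reads, 100 %-occurrence cores).
Columns: replicate number, mean richness ± sd, core size, mean core share of
reads ± sd, species-specific ZOTU count and % of core, seawater-core-shared
ZOTU count and % of core, HMA/LMA class.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["survey_summary"]


def survey_summary() -> pd.DataFrame:
    """The 19-species survey summary table, indexed by species name."""
    ref = resources.files("spongecore").joinpath("data/sponge_survey_summary.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df.set_index("species")
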