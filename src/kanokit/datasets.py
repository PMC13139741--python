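"""Bundled example datasets.

``load_nurse_demand`` returns the aggregated Kano frequency table from a
published cross-sectional survey of 1,571 hospital nurses rating 26
candidate features of a digital mental-health support tool.  Each row
gives the per-item counts of the six Kano categories; every row sums to
the 1,571 valid respondents.  The table is the canonical worked example
for the whole pipeline: attribute assignment, SI/DSI, and the
importance-satisfaction matrix can all be recomputed from it.
"""

from __future__ import annotations

from importlib import resources

from .aggregate import ItemFrequencies
from .io import read_frequency_table

NURSE_DEMAND_N_RESPONDENTS = 1571


def load_nurse_demand() -> list[ItemFrequencies]:
    """Per-item Kano frequencies for the 26-item nurse-demand survey."""
    path = resources.files("kanokit") / "data" / "nurse_demand_frequencies.tsv"
    with resources.as_file(path) as p:
        return read_frequency_table(p)
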