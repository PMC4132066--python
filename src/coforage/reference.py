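"""Bundled reference tables from a published little-penguin field study.

Three small machine-readable tables back the validation/acceptance suite:

``day_counts``
    22 deployment days with the number of simultaneously instrumented
    individuals, how many of them associated for at least one
    minimum-duration unit, the resulting percentage and the estimated
    number of adults foraging from the colony that day.
``sync_pairs``
    20 dyads that dived synchronously: total association duration,
    number of synchronised dives and median [range] dive statistics.
    Range cells that were not legible in the source are left empty.
``track_counts``
    Headline track counts (84 tracks total; how many fell in each
    association category).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FILES = {
    "day_counts": "reference_day_counts.csv",
    "sync_pairs": "reference_sync_pairs.csv",
    "track_counts": "reference_track_counts.csv",
}


def fixture_tables() -> dict[str, pd.DataFrame]:
    """Load the packaged reference tables as DataFrames."""
    out = {}
    for name, fname in _FILES.items():
        with resources.files("coforage").joinpath("data", fname).open("rb") as fh:
            out[name] = pd.read_csv(fh)
    return out
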