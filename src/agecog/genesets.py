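"""Packaged gene lists used in the worked analyses.

Three small plain-text fixtures ship with the package:

* ``transcription_regulation_46`` — the 46 transcription-regulation
  genes whose expression rises with impaired set-shift behavior; the
  composite index score is built over this set.
* ``ai_up_16`` — the 16 immediate-early/activity-related genes
  significantly increased in aged-impaired vs aged-unimpaired animals,
  with their published AI/AU and age fold changes.
* ``dlpfc_aging_concordant_60`` — the 60 genes whose rat mPFC aging
  direction agreed (and reached directed significance) with human
  dorsolateral-PFC aging, as an up/down direction list.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datatypes import DirectionSet

__all__ = [
    "transcription_regulation_genes",
    "ai_up_genes",
    "dlpfc_aging_direction_set",
]


def _data_path(name: str):
    return resources.files("agecog.data").joinpath(name)


def transcription_regulation_genes() -> list[str]:
    """The 46 transcription-regulation genes of the composite index."""
    text = _data_path("transcription_regulation_46.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def ai_up_genes() -> pd.DataFrame:
    """16 genes up in aged-impaired animals, with published fold changes."""
    with resources.as_file(_data_path("ai_up_16.csv")) as path:
        return pd.read_csv(path)


def dlpfc_aging_direction_set() -> DirectionSet:
    """Directional list of 60 cross-species concordant aging genes."""
    with resources.as_file(_data_path("dlpfc_aging_concordant_60.csv")) as path:
        table = pd.read_csv(path)
    pairs = [
        (row.symbol, +1 if row.direction == "up" else -1)
        for row in table.itertuples()
    ]
    return DirectionSet.from_pairs("dlpfc_aging_concordant_60", pairs)
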