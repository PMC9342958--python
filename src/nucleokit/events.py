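"""Event-table container shared by the cytometry generator and the analysis.

An :class:`EventTable` wraps a :class:`pandas.DataFrame` with one row per
cell and columns ``donor``, ``acceptor``, ``fret`` (detector intensities in
arbitrary units) plus optional ``reporter``, ``truth_assembled`` and
``concentration`` columns.  ``truth_assembled`` and ``concentration`` exist
only for synthetic tables, where the generator knows the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("donor", "acceptor", "fret")
OPTIONAL_COLUMNS = ("reporter", "truth_assembled", "concentration")


@dataclass
class EventTable:
    """One flow sample: per-cell channel intensities plus provenance metadata."""

    data: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table is missing required columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def donor(self) -> np.ndarray:
        return self.data["donor"].to_numpy(dtype=float)

    @property
    def acceptor(self) -> np.ndarray:
        return self.data["acceptor"].to_numpy(dtype=float)

    @property
    def fret(self) -> np.ndarray:
        return self.data["fret"].to_numpy(dtype=float)

    @property
    def has_truth(self) -> bool:
        return "truth_assembled" in self.data.columns

    @property
    def truth_assembled(self) -> np.ndarray:
        if not self.has_truth:
            raise AttributeError("table has no truth_assembled column")
        return self.data["truth_assembled"].to_numpy(dtype=bool)

    def subset(self, mask: np.ndarray, **extra_meta: Any) -> "EventTable":
        meta = dict(self.metadata)
        meta.update(extra_meta)
        return EventTable(self.data.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True), meta)

    def copy(self) -> "EventTable":
        return EventTable(self.data.copy(), dict(self.metadata))
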