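"""Three-matrix exposure dataset container.

Concentrations of each panel congener measured in maternal blood,
umbilical cord blood and umbilical cord tissue for the same subjects,
together with above-LOD detect flags.  All downstream stages (censoring
substitution, detection filtering, clustering, marker selection) operate
on this container.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import pandas as pd

from .panel import MATRICES, CongenerPanel

#: Unit flags.
UNITS_RAW = "pg/g-fat"
UNITS_TEQ = "pg-TEQ/g-fat"


@dataclass
class ExposureDataset:
    """Subjects x congeners concentration tables, one per biological matrix.

    ``matrices`` maps matrix name -> DataFrame (index: subject ids,
    columns: congener ids); ``detected`` holds same-shape boolean tables
    (True = measured above the LOD).  Subject and congener ordering is
    identical across matrices.
    """

    matrices: dict[str, pd.DataFrame] = field(repr=False)
    detected: dict[str, pd.DataFrame] = field(repr=False)
    panel: CongenerPanel
    units: str = UNITS_TEQ
    imputed: bool = False

    def __post_init__(self) -> None:
        names = list(self.matrices)
        unknown = [m for m in names if m not in MATRICES]
        if unknown:
            raise ValueError(f"unknown matrix names: {unknown}")
        if set(self.detected) != set(names):
            raise ValueError("matrices and detected must cover the same matrices")
        first = self.matrices[names[0]]
        for m in names:
            x, d = self.matrices[m], self.detected[m]
            if not (x.index.equals(first.index) and x.columns.equals(first.columns)):
                raise ValueError(f"matrix {m!r} has inconsistent subjects/congeners")
            if not (d.index.equals(x.index) and d.columns.equals(x.columns)):
                raise ValueError(f"detect flags for {m!r} misaligned")
            if (x.to_numpy() <= 0).any():
                raise ValueError(f"non-positive concentration in {m!r}")
        missing = [c for c in first.columns if c not in self.panel]
        if missing:
            raise KeyError(f"congeners absent from panel: {missing}")

    @property
    def subject_ids(self) -> list:
        first = next(iter(self.matrices.values()))
        return list(first.index)

    @property
    def congeners(self) -> list[str]:
        first = next(iter(self.matrices.values()))
        return list(first.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def detect_fraction(self) -> pd.DataFrame:
        """Fraction of subjects above the LOD, congeners x matrices."""
        return pd.DataFrame(
            {m: self.detected[m].mean(axis=0) for m in self.matrices}
        )

    def subset_congeners(self, congener_ids: list[str]) -> "ExposureDataset":
        missing = [c for c in congener_ids if c not in self.congeners]
        if missing:
            raise KeyError(f"congeners not in dataset: {missing}")
        return ExposureDataset(
            matrices={m: x[congener_ids].copy() for m, x in self.matrices.items()},
            detected={m: d[congener_ids].copy() for m, d in self.detected.items()},
            panel=self.panel.subset(congener_ids),
            units=self.units,
            imputed=self.imputed,
        )

    def copy(self) -> "ExposureDataset":
        return ExposureDataset(
            matrices={m: x.copy() for m, x in self.matrices.items()},
            detected={m: d.copy() for m, d in self.detected.items()},
            panel=copy.deepcopy(self.panel),
            units=self.units,
            imputed=self.imputed,
        )
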