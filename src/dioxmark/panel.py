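"""Congener panel metadata.

The panel covers the 29 congeners routinely reported for human
biomonitoring of dioxin-like toxicity: 7 polychlorinated dibenzo-p-dioxins
(PCDD), 10 dibenzofurans (PCDF) and 12 dioxin-like PCBs, each carrying a
WHO-2005 toxic equivalency factor (TEF) and a per-matrix limit of
detection (LOD).  TEFs are shipped as an editable CSV rather than being
hard-coded: they belong to the WHO consensus scheme, not to this package,
and users may swap in a revised scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

#: The three biological matrices, in canonical order.
MATRICES: tuple[str, str, str] = ("maternal_blood", "cord_blood", "cord_tissue")

#: Allowed compound classes.
CLASSES: tuple[str, str, str] = ("PCDD", "PCDF", "dlPCB")

LOD_COLUMNS = tuple(f"lod_{m}" for m in MATRICES)


class PanelConfigError(ValueError):
    """Raised when a panel metadata table violates its contract."""


@dataclass
class CongenerPanel:
    """Metadata for a congener panel.

    ``table`` is indexed by ``congener_id`` and has columns
    ``compound_class``, ``n_chlorines``, ``tef`` and one ``lod_<matrix>``
    column per biological matrix.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["compound_class", "n_chlorines", "tef", *LOD_COLUMNS]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise PanelConfigError(f"panel table missing columns: {missing}")
        if t.index.duplicated().any():
            dups = sorted(t.index[t.index.duplicated()])
            raise PanelConfigError(f"duplicate congener ids: {dups}")
        bad_class = t.loc[~t["compound_class"].isin(CLASSES)]
        if len(bad_class):
            raise PanelConfigError(
                f"unknown compound_class for {list(bad_class.index)}"
            )
        if (t["tef"] < 0).any():
            bad = list(t.index[t["tef"] < 0])
            raise PanelConfigError(f"negative TEF for {bad}")
        for c in LOD_COLUMNS:
            if (t[c] <= 0).any():
                bad = list(t.index[t[c] <= 0])
                raise PanelConfigError(f"non-positive LOD in {c} for {bad}")

    @property
    def congeners(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, congener_id: str) -> bool:
        return congener_id in self.table.index

    def compound_class(self, congener_id: str) -> str:
        return self.table.at[congener_id, "compound_class"]

    def by_class(self, compound_class: str) -> list[str]:
        t = self.table
        return list(t.index[t["compound_class"] == compound_class])

    def tef(self, congener_id: str) -> float:
        return float(self.table.at[congener_id, "tef"])

    def lod(self, congener_id: str, matrix: str) -> float:
        return float(self.table.at[congener_id, f"lod_{matrix}"])

    def with_lods(self, lods: pd.DataFrame) -> "CongenerPanel":
        """Return a copy whose LOD columns are replaced.

        ``lods`` is indexed by congener id with one column per matrix name.
        """
        t = self.table.copy()
        for m in MATRICES:
            t.loc[lods.index, f"lod_{m}"] = lods[m]
        return CongenerPanel(t)

    def subset(self, congener_ids: list[str]) -> "CongenerPanel":
        missing = [c for c in congener_ids if c not in self.table.index]
        if missing:
            raise KeyError(f"congeners not in panel: {missing}")
        return CongenerPanel(self.table.loc[congener_ids].copy())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="congener_id")

    @classmethod
    def from_csv(cls, path) -> "CongenerPanel":
        t = pd.read_csv(path, index_col="congener_id")
        return cls(t)


def _load_bundled(name: str) -> pd.DataFrame:
    ref = resources.files("dioxmark.data").joinpath(name)
    with resources.as_file(ref) as p:
        return pd.read_csv(p)


def load_tef_table() -> pd.DataFrame:
    """The bundled WHO-2005 TEF scheme (congener_id, class, Cl count, TEF)."""
    t = _load_bundled("who2005_tef.csv")
    for i, row in t.iterrows():
        if row["tef"] < 0 or row["compound_class"] not in CLASSES:
            raise PanelConfigError(
                f"malformed TEF config row {i}: {row.to_dict()}"
            )
    return t


def load_cohort_summary() -> pd.DataFrame:
    """Published summary of the reference 41-pair birth cohort.

    One row per congener and matrix: median, quartiles (pg-TEQ/g fat) and
    the number of samples above the LOD out of 41.  Congeners that were
    never detected in a matrix carry small placeholder location/scale
    values so that a fully censored congener can still be simulated.
    """
    return _load_bundled("cohort_summary.csv")


def default_panel(lod_placeholder: float = 1e-3) -> CongenerPanel:
    """The 29-congener dioxin/furan/dl-PCB panel with WHO-2005 TEFs.

    LODs are placeholders; simulation and file readers replace them with
    the values that apply to the data at hand.
    """
    t = load_tef_table().set_index("congener_id")
    for c in LOD_COLUMNS:
        t[c] = lod_placeholder
    return CongenerPanel(t)
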