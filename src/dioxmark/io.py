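"""Reading and writing exposure datasets as plain CSV.

One wide CSV per biological matrix (``subject_id`` column plus one
column per congener), an optional companion ``*_detected.csv`` boolean
table per matrix, and a panel metadata CSV (congener id, class,
chlorine count, TEF, one LOD column per matrix).  When detect-flag
files are absent, flags are inferred as value strictly above the LOD
(a value exactly at the LOD counts as non-detected).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .dataset import ExposureDataset
from .panel import MATRICES, CongenerPanel


def write_exposure_dataset(dataset: ExposureDataset, outdir) -> dict[str, Path]:
    """Write matrix CSVs, detect-flag CSVs and the panel CSV to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for m, x in dataset.matrices.items():
        p = outdir / f"{m}.csv"
        x.to_csv(p, index_label="subject_id")
        written[m] = p
        pf = outdir / f"{m}_detected.csv"
        dataset.detected[m].to_csv(pf, index_label="subject_id")
        written[f"{m}_detected"] = pf
    panel_path = outdir / "panel.csv"
    dataset.panel.to_csv(panel_path)
    written["panel"] = panel_path
    return written


def _read_numeric_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    bad = df.columns[df.dtypes == object]
    for c in bad:
        nonnum = pd.to_numeric(df[c], errors="coerce").isna()
        row = df.index[nonnum][0] if nonnum.any() else None
        raise ValueError(
            f"non-numeric value in {path} (column {c!r}, subject {row!r})"
        )
    return df


def read_exposure_csv(
    matrix_paths: dict[str, str],
    panel_path,
    detected_paths: Optional[dict[str, str]] = None,
    units: str = "pg-TEQ/g-fat",
    imputed: bool = False,
) -> ExposureDataset:
    """Assemble an :class:`ExposureDataset` from wide CSV files.

    ``matrix_paths`` maps matrix names to concentration CSVs.  Congeners
    are matched to the panel by id, and re-ordered to the panel's
    ordering, so permuted input columns give an identical dataset.
    """
    for m in matrix_paths:
        if m not in MATRICES:
            raise ValueError(f"unknown matrix name {m!r}")
        if not Path(matrix_paths[m]).exists():
            raise FileNotFoundError(f"matrix file not found: {matrix_paths[m]}")
    if not Path(panel_path).exists():
        raise FileNotFoundError(f"panel file not found: {panel_path}")
    panel = CongenerPanel.from_csv(panel_path)

    matrices: dict[str, pd.DataFrame] = {}
    detected: dict[str, pd.DataFrame] = {}
    for m, path in matrix_paths.items():
        x = _read_numeric_table(path)
        unknown = [c for c in x.columns if c not in panel]
        if unknown:
            raise KeyError(f"congeners in {path} absent from panel: {unknown}")
        order = [c for c in panel.congeners if c in x.columns]
        x = x[order]
        matrices[m] = x
        if detected_paths and m in detected_paths:
            d = pd.read_csv(detected_paths[m], index_col="subject_id")[order]
            detected[m] = d.astype(bool)
        else:
            lods = pd.Series({c: panel.lod(c, m) for c in order})
            detected[m] = x.gt(lods, axis=1)  # strictly above the LOD

    used = sorted(
        {c for x in matrices.values() for c in x.columns},
        key=panel.congeners.index,
    )
    return ExposureDataset(
        matrices=matrices,
        detected=detected,
        panel=panel.subset(used),
        units=units,
        imputed=imputed,
    )
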