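"""Data preparation for congener panels with left-censored values.

Three rules are applied before any multivariate analysis:

* values below the limit of detection are substituted by LOD/2;
* only congeners detected in at least half of the samples (default) in
  *every* biological matrix are retained;
* raw concentrations may be converted to toxic equivalents (TEQ) by
  multiplying each congener with its WHO-2005 TEF, after which congener
  TEQs are additive and group sums (e.g. total PCDD/F) are meaningful.

The detection filter looks only at detect flags, and the LOD/2 rule only
at flagged cells, so the two steps commute.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataset import UNITS_RAW, UNITS_TEQ, ExposureDataset


@dataclass
class FilterReport:
    """Outcome of the all-matrix detection-fraction filter.

    ``dropped`` lists, per removed congener, the matrix with the lowest
    detection fraction and that fraction.
    """

    retained: list[str]
    dropped: list[tuple[str, str, float]]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"congener_id": c, "status": "retained"} for c in self.retained]
        rows += [
            {
                "congener_id": c,
                "status": "dropped",
                "worst_matrix": m,
                "worst_detect_fraction": f,
            }
            for c, m, f in self.dropped
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def impute_lod(dataset: ExposureDataset) -> ExposureDataset:
    """Substitute LOD/2 for every value flagged as below the LOD.

    Detected cells are untouched; the result is flagged ``imputed`` so
    repeated application is a no-op by construction.
    """
    import math
    import warnings

    out = dataset.copy()
    for m, x in out.matrices.items():
        det = out.detected[m]
        for c in x.columns:
            lod = dataset.panel.lod(c, m)
            if not math.isfinite(lod):
                warnings.warn(
                    f"LOD for {c!r} in {m!r} is not finite; censored values "
                    "left as-is (drop the congener via filter_detect)",
                    stacklevel=2,
                )
                continue
            x.loc[~det[c], c] = lod / 2.0
    out.imputed = True
    return out


def filter_detect(
    dataset: ExposureDataset, threshold: float = 0.5
) -> tuple[ExposureDataset, FilterReport]:
    """Keep congeners detected in >= ``threshold`` of samples in all matrices.

    The comparison is inclusive (a congener exactly at the threshold is
    retained) and the denominator is the number of subjects per matrix.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    frac = dataset.detect_fraction()  # congeners x matrices
    keep = (frac >= threshold).all(axis=1)
    retained = [c for c in dataset.congeners if keep[c]]
    dropped = []
    for c in dataset.congeners:
        if not keep[c]:
            worst = frac.loc[c].idxmin()
            dropped.append((c, worst, float(frac.at[c, worst])))
    if not retained:
        raise ValueError(
            f"no congener passes the {threshold:.0%} detection filter in all "
            "matrices; review the threshold"
        )
    return dataset.subset_congeners(retained), FilterReport(
        retained=retained, dropped=dropped, threshold=threshold
    )


def to_teq(dataset: ExposureDataset) -> ExposureDataset:
    """Convert raw pg/g-fat concentrations to pg-TEQ/g-fat.

    Each congener column is multiplied by its TEF.  Applying the
    conversion to data already in TEQ units is an error.
    """
    if dataset.units == UNITS_TEQ:
        raise ValueError("dataset is already in TEQ units")
    if dataset.units != UNITS_RAW:
        raise ValueError(f"unrecognised units {dataset.units!r}")
    out = dataset.copy()
    for c in out.congeners:
        tef = out.panel.tef(c)
        if pd.isna(tef):
            raise ValueError(f"missing TEF for congener {c!r}")
        for m in out.matrices:
            out.matrices[m][c] *= tef
    # LODs live on the same scale as the concentrations
    table = out.panel.table
    for m in out.matrices:
        table[f"lod_{m}"] = table[f"lod_{m}"] * table["tef"]
    out.units = UNITS_TEQ
    return out


def sum_groups(
    dataset: ExposureDataset, groups: dict[str, list[str]]
) -> dict[str, pd.DataFrame]:
    """Per-subject arithmetic sums of congener groups, per matrix.

    Returns matrix name -> DataFrame (subjects x group names).  TEQ
    values are additive, so these are the usual summary exposures such
    as total PCDD/F or a representative-PCB sum.
    """
    present = set(dataset.congeners)
    for name, members in groups.items():
        unknown = sorted(set(members) - present)
        if unknown:
            raise KeyError(f"group {name!r} references unknown congeners {unknown}")
    out: dict[str, pd.DataFrame] = {}
    for m, x in dataset.matrices.items():
        out[m] = pd.DataFrame(
            {name: x[list(members)].sum(axis=1) for name, members in groups.items()},
            index=x.index,
        )
    return out
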