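"""Select representative marker congeners inside each stable cluster.

For every stable cluster with more than two members: MGV-transform the
member concentrations, summarise the cluster by its first principal
component, and delete spline terms backwards until R-squared would drop
below 0.95.  Two-member stable clusters are reported as-is.  Writes a
per-cluster marker table (variance share of PC1, final R-squared,
retained markers) to results/markers.csv.
"""

import pandas as pd
from pathlib import Path

from dioxmark.io import read_exposure_csv
from dioxmark.markers import MarkerSelectionResult, pc1_score, select_markers
from dioxmark.mgv import mgv
from dioxmark.panel import MATRICES

ROOT = Path(__file__).resolve().parents[1] / "results"


def stable_sets(matrix: str) -> list[list[str]]:
    table = pd.read_csv(ROOT / "clustering" / f"stability_{matrix}.csv")
    return [
        sorted(row["members"].split(";"))
        for _, row in table[table["stable"]].iterrows()
    ]


def main():
    prepared = ROOT / "prepared"
    ds = read_exposure_csv(
        {m: prepared / f"{m}.csv" for m in MATRICES},
        prepared / "panel.csv",
        detected_paths={m: prepared / f"{m}_detected.csv" for m in MATRICES},
    )
    rows = []
    for m in MATRICES:
        x = ds.matrices[m]
        for members in stable_sets(m):
            if len(members) > 2:
                tm = mgv(x[members])
                scores, pc1_var = pc1_score(tm.scores)
                sel = select_markers(x[members], scores, r2_target=0.95)
                sel.pc1_var = pc1_var
            else:
                sel = MarkerSelectionResult(
                    cluster=members, pc1_var=float("nan"),
                    markers=members, final_r2=float("nan"),
                )
            rows.append(
                {"matrix": m, "cluster": ";".join(members), **sel.to_row()}
            )
            label = "+".join(sel.markers)
            print(
                f"{m}: cluster of {len(members)} -> markers [{label}]  "
                f"(PC1 var share {sel.pc1_var:.2f}, R2 {sel.final_r2:.2f})"
                if len(members) > 2
                else f"{m}: two-member stable cluster [{label}] kept as-is"
            )
    out = ROOT / "markers.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
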