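"""Apply LOD/2 substitution and the all-matrix 50% detection filter.

Reads the cohort written by 01_simulate_cohort.py, drops congeners not
detected in at least half of the samples in every matrix, substitutes
LOD/2 for the remaining censored values, and writes the analysis-ready
tables plus the filter report under results/prepared/.
"""

from pathlib import Path

from dioxmark.io import read_exposure_csv, write_exposure_dataset
from dioxmark.panel import MATRICES
from dioxmark.preprocess import filter_detect, impute_lod

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    data = ROOT / "data"
    ds = read_exposure_csv(
        {m: data / f"{m}.csv" for m in MATRICES},
        data / "panel.csv",
        detected_paths={m: data / f"{m}_detected.csv" for m in MATRICES},
    )
    filtered, report = filter_detect(ds, threshold=0.5)
    prepared = impute_lod(filtered)

    out = ROOT / "prepared"
    write_exposure_dataset(prepared, out)
    report.to_csv(out / "filter_report.csv")

    print(f"{len(report.retained)} of {len(ds.congeners)} congeners pass the "
          "50% detection rule in all three matrices")
    by_class = prepared.panel.table["compound_class"].value_counts().to_dict()
    print("retained by class:", by_class)
    for c, m, f in report.dropped:
        print(f"  dropped {c:<15s} (worst: {f:.0%} detected in {m})")


if __name__ == "__main__":
    main()
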