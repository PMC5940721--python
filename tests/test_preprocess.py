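import numpy as np
import pandas as pd
import pytest

from dioxmark.dataset import UNITS_RAW, ExposureDataset
from dioxmark.panel import MATRICES, default_panel, load_cohort_summary
from dioxmark.preprocess import filter_detect, impute_lod, sum_groups, to_teq

from .conftest import make_blockspec, quiet_generate

#: Congeners that survive the >=50%-detected-in-all-matrices rule applied
#: to the reference cohort detection counts (hand count of the printed
#: table: >=21 of 41 in every matrix).
EXPECTED_RETAINED = {
    "12378-PeCDD", "123678-HxCDD", "123789-HxCDD", "1234678-HpCDD", "OCDD",
    "23478-PeCDF", "123478-HxCDF", "123678-HxCDF", "1234678-HpCDF",
    "PCB77", "PCB105", "PCB114", "PCB118", "PCB123", "PCB126",
    "PCB156", "PCB157", "PCB167", "PCB169", "PCB189",
}


def small_dataset(detect_target=0.6, seed=5, n=20):
    spec = make_blockspec(
        {"a": ["PCB105", "PCB118"], "b": ["PCB126"]}, detect_target=detect_target
    )
    return quiet_generate(
        default_panel().subset(spec.congeners), n, spec, seed,
        lod_placement="empirical",
    )


class TestImputeLod:
    def test_censored_cells_get_half_lod(self):
        ds = small_dataset()
        out = impute_lod(ds)
        for m in MATRICES:
            det = ds.detected[m]
            for c in ds.congeners:
                half = ds.panel.lod(c, m) / 2.0
                assert (out.matrices[m].loc[~det[c], c] == half).all()

    def test_detected_cells_unchanged(self):
        ds = small_dataset()
        out = impute_lod(ds)
        for m in MATRICES:
            det = ds.detected[m].to_numpy()
            assert np.array_equal(
                out.matrices[m].to_numpy()[det], ds.matrices[m].to_numpy()[det]
            )

    def test_identity_when_all_detected(self):
        ds = small_dataset(detect_target=1.0)
        out = impute_lod(ds)
        for m in MATRICES:
            pd.testing.assert_frame_equal(out.matrices[m], ds.matrices[m])

    def test_idempotent_and_below_lod(self):
        ds = small_dataset()
        once = impute_lod(ds)
        twice = impute_lod(once)
        for m in MATRICES:
            pd.testing.assert_frame_equal(once.matrices[m], twice.matrices[m])
            censored = ~ds.detected[m]
            for c in ds.congeners:
                vals = once.matrices[m].loc[censored[c], c]
                assert (vals < ds.panel.lod(c, m)).all()


class TestFilterDetect:
    def test_reference_cohort_pattern_retains_20(self, study_dataset):
        """The printed detection counts leave 9 PCDD/F + 11 dl-PCBs."""
        filtered, report = filter_detect(study_dataset, threshold=0.5)
        assert set(report.retained) == EXPECTED_RETAINED
        classes = filtered.panel.table["compound_class"].value_counts()
        assert classes.get("dlPCB") == 11
        assert classes.get("PCDD", 0) + classes.get("PCDF", 0) == 9
        assert "PCB81" not in report.retained

    def test_zero_detect_congener_dropped(self, study_dataset):
        _, report = filter_detect(study_dataset)
        dropped = {c for c, _, _ in report.dropped}
        assert "123789-HxCDF" in dropped
        assert "1234789-HpCDF" in dropped

    def test_threshold_zero_retains_all(self, study_dataset):
        _, report = filter_detect(study_dataset, threshold=0.0)
        assert set(report.retained) == set(study_dataset.congeners)

    def test_monotone_in_threshold_and_idempotent(self, study_dataset):
        prev = None
        for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
            try:
                filtered, report = filter_detect(study_dataset, thr)
            except ValueError:
                break
            kept = set(report.retained)
            if prev is not None:
                assert kept <= prev
            prev = kept
            again, rep2 = filter_detect(filtered, thr)
            assert rep2.retained == report.retained

    def test_partition_invariant(self, study_dataset):
        _, report = filter_detect(study_dataset)
        dropped = {c for c, _, _ in report.dropped}
        assert dropped | set(report.retained) == set(study_dataset.congeners)
        assert not dropped & set(report.retained)

    def test_all_dropped_is_error(self):
        ds = small_dataset(detect_target=0.1)
        with pytest.raises(ValueError, match="threshold"):
            filter_detect(ds, threshold=0.9)


class TestToTeq:
    def _raw(self):
        ds = small_dataset(detect_target=1.0)
        return ExposureDataset(
            matrices={m: x.copy() for m, x in ds.matrices.items()},
            detected={m: d.copy() for m, d in ds.detected.items()},
            panel=ds.panel,
            units=UNITS_RAW,
        )

    def test_multiplies_by_tef(self):
        raw = self._raw()
        out = to_teq(raw)
        for c in raw.congeners:
            tef = raw.panel.tef(c)
            assert np.allclose(
                out.matrices["cord_blood"][c],
                raw.matrices["cord_blood"][c] * tef,
            )

    def test_applying_twice_is_error(self):
        out = to_teq(self._raw())
        with pytest.raises(ValueError, match="already"):
            to_teq(out)


class TestSumGroups:
    def test_single_congener_group(self, study_dataset):
        ds = impute_lod(filter_detect(study_dataset)[0])
        sums = sum_groups(ds, {"solo": ["PCB118"]})
        for m in MATRICES:
            assert np.allclose(sums[m]["solo"], ds.matrices[m]["PCB118"])

    def test_disjoint_additivity(self, study_dataset):
        ds = impute_lod(filter_detect(study_dataset)[0])
        a = ["PCB105", "PCB118"]
        b = ["PCB126", "PCB156"]
        sums = sum_groups(ds, {"a": a, "b": b, "ab": a + b})
        for m in MATRICES:
            assert np.allclose(sums[m]["ab"], sums[m]["a"] + sums[m]["b"])

    def test_unknown_congener_is_error(self, study_dataset):
        with pytest.raises(KeyError, match="nope"):
            sum_groups(study_dataset, {"g": ["nope"]})

    def test_pcddf_group_from_filter(self, study_dataset):
        """The retained PCDD/F set is exactly the 9 expected congeners."""
        filtered, report = filter_detect(study_dataset)
        pcddf = [
            c
            for c in report.retained
            if filtered.panel.compound_class(c) in ("PCDD", "PCDF")
        ]
        assert set(pcddf) == {
            c for c in EXPECTED_RETAINED if not c.startswith("PCB")
        }
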