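"""VoxelGrid invariants and volumetric / DICOM / cohort-table I/O."""

from __future__ import annotations

import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

import pvvkit as pk
from pvvkit.io import VolumeFormatError, read_dicom_series, read_volume, write_volume


class TestVoxelGrid:
    def test_rejects_bad_shapes_and_spacing(self):
        with pytest.raises(ValueError):
            pk.VoxelGrid(np.zeros((4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            pk.VoxelGrid(np.zeros((4, 4, 4)), (1, 0, 1))
        with pytest.raises(ValueError):
            pk.VoxelGrid(np.zeros((4, 4, 4)), (1, -1, 1))

    def test_anisotropic_voxel_volume(self):
        # 0.418 x 0.418 x 3.0 mm voxels, the clinical acquisition regime
        g = pk.VoxelGrid(np.ones((2, 2, 2)), (0.418, 0.418, 3.0))
        assert g.voxel_volume == pytest.approx(0.524, abs=5e-4)

    def test_binary_validation(self):
        g = pk.VoxelGrid(np.array([[[0, 2]]]), (1, 1, 1))
        assert not g.is_binary
        with pytest.raises(ValueError):
            g.as_bool()

    def test_mask_volume_invariant_under_axis_permutation(self):
        rng = np.random.default_rng(0)
        data = rng.random((6, 7, 8)) > 0.5
        g = pk.VoxelGrid(data, (0.5, 0.7, 3.0))
        gT = pk.VoxelGrid(data.transpose(2, 0, 1), (3.0, 0.5, 0.7))
        assert g.mask_volume_ml() == pytest.approx(gT.mask_volume_ml())


class TestVolumeIO:
    @pytest.mark.parametrize("suffix", [".nii", ".nii.gz", ".mha", ".nrrd"])
    def test_bitlevel_roundtrip(self, tmp_path, suffix):
        rng = np.random.default_rng(1)
        g = pk.VoxelGrid((rng.random((10, 10, 5)) > 0.5), (0.5, 0.5, 3.0), (1, 2, 3))
        p = write_volume(g, tmp_path / f"m{suffix}")
        r = read_volume(p)
        assert np.array_equal(r.data.astype(bool), g.data)
        assert np.allclose(r.spacing, g.spacing, atol=1e-6)
        assert np.allclose(r.origin, g.origin, atol=1e-6)

    def test_unknown_suffix_rejected(self, tmp_path):
        (tmp_path / "x.foo").write_text("junk")
        with pytest.raises(VolumeFormatError):
            read_volume(tmp_path / "x.foo")

    def test_corrupt_file_rejected(self, tmp_path):
        (tmp_path / "x.nrrd").write_text("not a volume")
        with pytest.raises(VolumeFormatError):
            read_volume(tmp_path / "x.nrrd")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "absent.nii")


def _write_slice(path, z, uid, value=0, rows=8, pixel_spacing=(0.7, 0.7)):
    ds = Dataset()
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = generate_uid()
    ds.SeriesInstanceUID = uid
    ds.Modality = "CT"
    ds.Rows = ds.Columns = rows
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelSpacing = list(pixel_spacing)
    ds.ImagePositionPatient = [0, 0, z]
    ds.PixelData = (np.full((rows, rows), value, np.uint16)).tobytes()
    meta = FileMetaDataset()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    fds = FileDataset(str(path), ds, file_meta=meta, preamble=b"\x00" * 128)
    fds.save_as(str(path), enforce_file_format=True)


class TestDicomSeries:
    def test_spacing_from_tags_and_slice_sorting(self, tmp_path):
        uid = generate_uid()
        # files written shuffled on purpose
        for i, z in enumerate([6.0, 0.0, 3.0]):
            _write_slice(tmp_path / f"s{i}.dcm", z, uid, value=int(z))
        v = read_dicom_series(tmp_path)
        assert v.spacing == (0.7, 0.7, 3.0)
        assert list(v.data[0, 0, :]) == [0, 3, 6]  # sorted by position

    def test_mixed_series_rejected(self, tmp_path):
        u1, u2 = generate_uid(), generate_uid()
        _write_slice(tmp_path / "a.dcm", 0.0, u1)
        _write_slice(tmp_path / "b.dcm", 3.0, u1)
        _write_slice(tmp_path / "c.dcm", 6.0, u2)
        with pytest.raises(VolumeFormatError, match="series"):
            read_dicom_series(tmp_path)

    def test_nonuniform_gaps_rejected(self, tmp_path):
        uid = generate_uid()
        for i, z in enumerate([0.0, 3.0, 7.5]):
            _write_slice(tmp_path / f"s{i}.dcm", z, uid)
        with pytest.raises(VolumeFormatError, match="spacing"):
            read_dicom_series(tmp_path)


class TestCohortTable:
    @staticmethod
    def _write_table(path, n_control=3, n_ipf=2, break_row=False):
        lines = ["participant_id,cohort,visit,method,pvv_total,pvv5,pvv10,pvv10plus,fibrosis_pct"]
        for i in range(n_control):
            lines.append(f"C{i},control,1,graph,22.0,0.7,2.5,18.8,1.5")
        for i in range(n_ipf):
            for v in (1, 2):
                lines.append(f"P{i},IPF,{v},graph,52.2,1.2,6.2,44.8,20.5")
        if break_row:
            lines.append("B0,control,1,graph,50.0,1.0,2.0,10.0,5.0")  # parts != total
        path.write_text("\n".join(lines))
        return path

    def test_load_typed_records(self, tmp_path):
        p = self._write_table(tmp_path / "t.csv")
        recs, report = pk.load_cohort_table(p)
        assert report.n_accepted == len(recs) == 7
        assert {r.cohort for r in recs} == {"control", "IPF"}
        assert all(r.pvv5 + r.pvv10 + r.pvv10plus == pytest.approx(r.pvv_total)
                   for r in recs)

    def test_partition_violation_rejected_with_row_number(self, tmp_path):
        p = self._write_table(tmp_path / "t.csv", break_row=True)
        recs, report = pk.load_cohort_table(p)
        assert len(report.rejected) == 1
        rownum, reason = report.rejected[0]
        assert "pvv" in reason
        assert rownum == 9  # 1-based with header

    def test_group_sizes_preserved(self, tmp_path):
        # the study's group structure: 59 single-visit controls and 43
        # patient scans pooled over 21 participants' visits (21+21+1)
        p = self._write_table(tmp_path / "t.csv", n_control=59, n_ipf=0)
        lines = p.read_text().splitlines()
        ipf_rows = []
        for pid in range(21):
            visits = 3 if pid == 0 else 2
            for v in range(1, visits + 1):
                ipf_rows.append(f"P{pid},IPF,{v},graph,52.2,1.2,6.2,44.8,20.5")
        assert len(ipf_rows) == 43
        p.write_text("\n".join(lines + ipf_rows))
        recs, _ = pk.load_cohort_table(p)
        df = pk.records_to_frame(recs)
        assert (df.cohort == "control").sum() == 59
        assert (df.cohort == "IPF").sum() == 43

    def test_missing_required_column(self, tmp_path):
        (tmp_path / "t.csv").write_text("participant_id,cohort\nA,control")
        from pvvkit.cohort import CohortSchemaError

        with pytest.raises(CohortSchemaError):
            pk.load_cohort_table(tmp_path / "t.csv")

    def test_blank_pft_allowed_blank_pvv_rejected(self, tmp_path):
        (tmp_path / "t.csv").write_text(
            "participant_id,cohort,visit,method,pvv_total,pvv5,pvv10,pvv10plus,fvc_pct\n"
            "A,control,1,graph,10.0,1.0,2.0,7.0,\n"
            "B,control,1,graph,,1.0,2.0,7.0,95\n"
        )
        recs, report = pk.load_cohort_table(tmp_path / "t.csv")
        assert len(recs) == 1 and recs[0].participant_id == "A"
        assert recs[0].fvc_pct is None
        assert len(report.rejected) == 1
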