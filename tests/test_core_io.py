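"""Datacube data model, container round trips, tables and ion images."""

import numpy as np
import pandas as pd
import pytest

from msiregio import (MsiDataset, MzAxis, read_msi, read_peptide_ids,
                      render_ion_image, write_msi)
from msiregio.core_io import FormatError, write_msi_batch
from msiregio.synth import make_layout, make_peak_panel, simulate_section


def tiny_dataset(mode="centroid"):
    return MsiDataset(
        pixels=[(0, 0), (1, 0), (0, 1), (1, 1)],
        axis=MzAxis([900.0, 1200.5, 2500.25], mode=mode),
        intensities=np.arange(12, dtype=float).reshape(4, 3),
        section_id="tiny", group="control",
    )


class TestDataModel:
    def test_duplicate_pixels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MsiDataset(pixels=[(0, 0), (0, 0)],
                       axis=MzAxis([1000.0]),
                       intensities=np.ones((2, 1)))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            MsiDataset(pixels=[(0, 0)], axis=MzAxis([1000.0]),
                       intensities=np.array([[-1.0]]))

    def test_axis_must_be_increasing_and_positive(self):
        with pytest.raises(ValueError):
            MzAxis([1000.0, 999.0])
        with pytest.raises(ValueError):
            MzAxis([-5.0, 1000.0])
        with pytest.raises(ValueError):
            MzAxis([1000.0], mode="weird")

    def test_spectrum_count_must_match_pixels(self):
        with pytest.raises(ValueError, match="shape"):
            MsiDataset(pixels=[(0, 0), (1, 0)], axis=MzAxis([1000.0]),
                       intensities=np.ones((3, 1)))


class TestInternalFormat:
    def test_round_trip_identity(self, tmp_path):
        ds = tiny_dataset()
        path = write_msi(ds, tmp_path / "tiny.msi.json")
        back = read_msi(path)
        assert np.array_equal(back.pixels, ds.pixels)
        assert np.array_equal(back.axis.values, ds.axis.values)
        assert np.array_equal(back.intensities, ds.intensities)
        assert (back.section_id, back.group) == ("tiny", "control")

    def test_synthetic_cube_round_trip(self, tmp_path):
        layout = make_layout(40, 40, 0.25, seed=3)
        panel = make_peak_panel(n_peaks=12, n_region_markers=2,
                                n_treatment_markers=2, seed=3)
        ds, _ = simulate_section(layout, panel, group="control", seed=3)
        back = read_msi(write_msi(ds, tmp_path / "cube.msi.json"))
        # float32 container encoding: equal within single-precision tolerance
        np.testing.assert_allclose(back.intensities, ds.intensities,
                                   rtol=1e-6, atol=1e-4)
        assert np.array_equal(back.pixels, ds.pixels)

    def test_malformed_sidecar_names_problem(self, tmp_path):
        p = tmp_path / "bad.msi.json"
        p.write_text('{"format": "msiregio-internal", "mode": "centroid"}')
        with pytest.raises(FormatError, match="mz"):
            read_msi(p)

    def test_batch_manifest_lists_all_sections(self, tmp_path):
        sets = []
        for i in range(3):
            ds = tiny_dataset()
            ds.section_id = f"s{i}"
            sets.append(ds)
        manifest = write_msi_batch(sets, tmp_path / "batch")
        import json
        entries = json.loads(manifest.read_text())["sections"]
        assert [e["section_id"] for e in entries] == ["s0", "s1", "s2"]
        for e in entries:
            assert (tmp_path / "batch" / e["path"]).exists()


class TestImzml:
    def test_round_trip(self, tmp_path):
        ds = tiny_dataset()
        path = write_msi(ds, tmp_path / "tiny.imzML")
        back = read_msi(path)
        assert np.array_equal(back.pixels, ds.pixels)
        np.testing.assert_allclose(back.intensities, ds.intensities,
                                   rtol=1e-6)
        assert back.group == "control"

    def test_file_is_parseable_by_independent_xml_reader(self, tmp_path):
        lxml = pytest.importorskip("lxml.etree")
        ds = MsiDataset(pixels=[(0, 0)], axis=MzAxis([1000.0]),
                        intensities=np.array([[7.0]]), section_id="one")
        path = write_msi(ds, tmp_path / "one.imzML")
        tree = lxml.parse(str(path))
        ns = {"m": "http://psi.hupo.org/ms/mzml"}
        spectra = tree.findall(".//m:spectrum", ns)
        assert len(spectra) == 1


class TestPeptideTable:
    HEADER = ("protein_accession,gene_name,description,sequence,"
              "experimental_neutral_mass,score\n")

    def test_reference_row_parses(self, tmp_path):
        p = tmp_path / "ids.csv"
        p.write_text(self.HEADER +
                     "P12345,Tnc,Tenascin-C,EGDPATINAATEIDAPR,1739.83,60.4\n")
        table = read_peptide_ids(p)
        assert len(table.rows) == 1
        assert len(table.rows["sequence"].iloc[0]) == 17

    def test_invalid_residue_rejected_with_reason(self, tmp_path):
        p = tmp_path / "ids.csv"
        p.write_text(self.HEADER +
                     "P1,Tnc,Tenascin-C,EGDPATINAATEIDAPZ,1739.83,60.4\n"
                     "P2,Flnc,Filamin C,LGSFGSITR,936.50,42.0\n")
        table = read_peptide_ids(p)
        assert len(table.rows) == 1
        assert table.rejected["reason"].iloc[0] == "invalid residue Z"

    def test_header_only_file_gives_empty_table(self, tmp_path, caplog):
        p = tmp_path / "ids.csv"
        p.write_text(self.HEADER)
        with caplog.at_level("WARNING"):
            table = read_peptide_ids(p)
        assert table.rows.empty
        assert "empty" in caplog.text

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "ids.csv"
        p.write_text("protein_accession,sequence\nP1,LGSFGSITR\n")
        with pytest.raises(FormatError, match="missing"):
            read_peptide_ids(p)


class TestIonImage:
    def test_constant_dataset_gives_constant_image(self):
        ds = tiny_dataset()
        ds.intensities[:] = 1.0
        img = render_ion_image(ds, 1200.5, 0.156)
        assert img.shape == (2, 2)
        assert np.all(img == 1.0)

    def test_off_grid_positions_are_missing_not_zero(self):
        ds = MsiDataset(pixels=[(0, 0), (2, 2)],
                        axis=MzAxis([1000.0]),
                        intensities=np.array([[1.0], [2.0]]))
        img = render_ion_image(ds, 1000.0, 0.1)
        assert img[0, 0] == 1.0 and img[2, 2] == 2.0
        assert np.isnan(img[1, 1])

    def test_mz_outside_axis_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            render_ion_image(tiny_dataset(), 5000.0, 0.156)

    def test_interval_spanning_two_centroids_sums_them(self):
        # three centroid peaks; a +-0.156 window around 1000.05 catches two
        ds = MsiDataset(pixels=[(0, 0)],
                        axis=MzAxis([1000.0, 1000.1, 1000.4]),
                        intensities=np.array([[2.0, 3.0, 10.0]]))
        img = render_ion_image(ds, 1000.05, 0.156)
        assert img[0, 0] == 5.0

    def test_permutation_invariance(self, rng):
        ds = tiny_dataset()
        perm = rng.permutation(ds.n_pixels)
        shuffled = MsiDataset(pixels=ds.pixels[perm], axis=ds.axis,
                              intensities=ds.intensities[perm],
                              section_id=ds.section_id, group=ds.group)
        a = render_ion_image(ds, 1200.5, 0.156)
        b = render_ion_image(shuffled, 1200.5, 0.156)
        np.testing.assert_array_equal(a, b)

    def test_planted_marker_brighter_in_tam(self):
        layout = make_layout(40, 40, 0.25, seed=5)
        panel = make_peak_panel(n_peaks=10, n_region_markers=2,
                                n_treatment_markers=1, seed=5)
        ds, truth = simulate_section(layout, panel, group="MSC-TX", seed=5)
        marker = truth.treatment_marker_mzs()[0]
        img = render_ion_image(ds, marker, 0.156)
        tam_mean = np.nanmean(np.where(layout.tam_mask, img, np.nan))
        tm_mean = np.nanmean(np.where(layout.tm_mask, img, np.nan))
        assert tam_mean > tm_mean
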