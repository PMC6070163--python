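"""Colormap file formats, bundled fixtures, synthetic generator."""

import hashlib
from importlib import resources

import numpy as np
import pytest

import cvdcmap as cm
from cvdcmap import colorspace as cs
from cvdcmap.cmap_io import ColormapFormatError


class TestTables:
    def test_float01_round_trip(self, tmp_path, viridis):
        p = tmp_path / "map.csv"
        cm.write_table(viridis, p, dialect="float01")
        back = cm.read_table(p, dialect="float01")
        assert np.abs(back.colors - viridis.colors).max() < 1e-8

    def test_int255_values_divided(self, tmp_path):
        p = tmp_path / "map.txt"
        p.write_text("255 0 0\n0 128 255\n")
        back = cm.read_table(p, dialect="int255")
        assert back.colors == pytest.approx(
            np.array([[1, 0, 0], [0, 128 / 255, 1]])
        )

    def test_two_column_file_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("0.1,0.2\n0.3,0.4\n")
        with pytest.raises(ColormapFormatError, match="3 columns"):
            cm.read_table(p)

    def test_out_of_range_reports_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("0.1,0.2,0.3\n1.5,0.2,0.3\n")
        with pytest.raises(ColormapFormatError, match="row 2"):
            cm.read_table(p, dialect="float01")

    def test_json_round_trip(self, tmp_path, jet):
        p = tmp_path / "jet.json"
        cm.write_json(jet, p)
        back = cm.read_json(p)
        assert back.name == "jet"
        assert np.array_equal(back.colors, jet.colors)


class TestImageJLut:
    def test_round_trip_within_quantization(self, tmp_path, viridis):
        p = tmp_path / "v.lut"
        cm.write_imagej_lut(viridis, p)
        assert p.stat().st_size == 768
        back = cm.read_imagej_lut(p)
        assert np.abs(back.colors - viridis.colors).max() <= 1 / 255

    def test_all_black_writes_zero_bytes(self, tmp_path):
        black = cm.RGBColormap(np.zeros((256, 3)))
        p = tmp_path / "b.lut"
        cm.write_imagej_lut(black, p)
        assert p.read_bytes() == bytes(768)

    def test_truncated_file_rejected(self, tmp_path):
        p = tmp_path / "short.lut"
        p.write_bytes(bytes(767))
        with pytest.raises(ColormapFormatError, match="768"):
            cm.read_imagej_lut(p)

    def test_wrong_length_map_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="256"):
            cm.write_imagej_lut(
                cm.fixture("two_point_degenerate"), tmp_path / "x.lut"
            )


class TestFixtures:
    def test_names(self):
        assert set(cm.fixture_names()) == {
            "viridis", "jet", "gray", "two_point_degenerate",
        }

    def test_viridis_first_entry(self, viridis):
        assert viridis.colors[0] == pytest.approx(
            [0.267004, 0.004874, 0.329415], abs=1e-6
        )
        assert len(viridis) == 256

    def test_jet_in_gamut(self, jet):
        assert len(jet) == 256
        assert cs.in_gamut(jet.colors).all()

    def test_gray_is_achromatic_and_lightness_linear(self, gray):
        c = gray.colors
        assert np.array_equal(c[:, 0], c[:, 1])
        assert np.array_equal(c[:, 0], c[:, 2])
        assert c[0] == pytest.approx([0, 0, 0])
        assert c[-1] == pytest.approx([1, 1, 1])
        jp = cs.srgb_to_ucs(c)[:, 0]
        assert jp == pytest.approx(np.linspace(0, 100, 256), abs=0.05)

    def test_bundled_tables_hash_pinned(self):
        digests = {}
        for name in ("viridis", "jet"):
            ref = resources.files("cvdcmap.data").joinpath(f"{name}.csv")
            digests[name] = hashlib.sha256(ref.read_bytes()).hexdigest()[:16]
        assert digests == {
            "viridis": "d35c01891ff4f3dc",
            "jet": "6793af75e2ee7790",
        }


class TestSynthTrajectory:
    def test_deterministic_for_fixed_seed(self):
        a = cm.synth_trajectory(seed=42)
        b = cm.synth_trajectory(seed=42)
        assert np.array_equal(a.colors, b.colors)

    def test_zero_chroma_gives_gray_ramp(self):
        m = cm.synth_trajectory(seed=1, chroma_radius=0.0)
        c = m.colors
        assert np.abs(c - c.mean(axis=1, keepdims=True)).max() < 2e-2
        assert np.all(np.diff(c.mean(axis=1)) > 0)

    @pytest.mark.parametrize("seed", range(0, 50, 7))
    def test_generated_maps_satisfy_invariants(self, seed):
        m = cm.synth_trajectory(seed=seed)
        assert len(m) == 256
        assert cs.in_gamut(m.colors).all()
        assert np.all(np.isfinite(m.colors))

    def test_impossible_geometry_signals_failure(self):
        with pytest.raises(RuntimeError, match="gamut"):
            cm.synth_trajectory(seed=0, chroma_radius=80.0)
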