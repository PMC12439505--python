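"""The periodized DWT core: depths, windows, energies, reconstruction."""

import numpy as np
import pytest

from pergdwt import dwt
from pergdwt._fejer_korovkin import scaling_filter


# Published Fejér-Korovkin length-4 scaling filter (Nielsen 2001 / standard
# filter tables); fk6 reference digits are coarser.
FK4_REFERENCE = [0.6539275373531193, 0.7532724928394872,
                 0.05317922877905981, -0.04616571481521770]
FK6_REFERENCE = [0.4279916, 0.8129197, 0.3563696,
                 -0.1464386, -0.0771566, 0.0406258]


class TestFejerKorovkinFilters:
    def test_fk4_matches_published_coefficients(self):
        assert np.allclose(scaling_filter(4), FK4_REFERENCE, atol=5e-8)

    def test_fk6_matches_published_coefficients(self):
        assert np.allclose(scaling_filter(6), FK6_REFERENCE, atol=2e-4)

    @pytest.mark.parametrize("length", [4, 6, 8])
    def test_orthonormality_to_machine_precision(self, length):
        h = np.asarray(scaling_filter(length))
        assert h.sum() == pytest.approx(np.sqrt(2), abs=1e-12)
        assert h @ h == pytest.approx(1.0, abs=1e-12)
        for shift in range(1, length // 2):
            assert abs(h[: length - 2 * shift] @ h[2 * shift:]) < 1e-12


class TestMaxLevel:
    @pytest.mark.parametrize(
        "name,expected",
        [("haar", 7), ("sym4", 5), ("coif2", 4), ("sym2", 6), ("db8", 4), ("fk4", 6)],
    )
    def test_admissible_depth(self, name, expected):
        assert dwt.max_level(name, 256) == expected

    def test_unknown_wavelet_lists_supported_names(self):
        with pytest.raises(ValueError, match="haar"):
            dwt.max_level("morl", 256)


class TestIndexWindow:
    @pytest.mark.parametrize(
        "band,level,position,t_lo,t_hi,f_lo,f_hi",
        [
            ("D", 6, 2, 38, 75, 13, 27),
            ("D", 5, 3, 38, 56, 27, 53),
            ("D", 6, 3, 75, 112, 13, 27),
            ("D", 7, 1, 0, 75, 7, 13),
            ("D", 7, 2, 75, 150, 7, 13),
            ("A", 6, 3, 75, 112, 0, 13),
        ],
    )
    def test_printed_windows(self, band, level, position, t_lo, t_hi, f_lo, f_hi):
        w = dwt.index_window(band, level, position)
        assert (w.t_lo_ms, w.t_hi_ms) == (t_lo, t_hi)
        assert (w.f_lo_hz, w.f_hi_hz) == (f_lo, f_hi)

    @pytest.mark.parametrize("level", [1, 2, 3, 4, 5, 6, 7])
    def test_time_cells_tile_the_window_exactly(self, level):
        n_cells = 256 // 2**level
        edges = [dwt.index_window("D", level, k + 1) for k in range(n_cells)]
        assert edges[0].t_lo == 0.0
        assert edges[-1].t_hi == pytest.approx(150.0)
        for prev, nxt in zip(edges, edges[1:]):
            assert prev.t_hi == pytest.approx(nxt.t_lo)

    def test_position_out_of_range(self):
        with pytest.raises(ValueError, match="position"):
            dwt.index_window("D", 6, 5)

    def test_center_is_midpoint_of_unrounded_band(self):
        w = dwt.index_window("D", 6, 2)
        assert w.t_center == pytest.approx((37.5 + 75.0) / 2)
        assert w.f_center == pytest.approx((1700 / 128 + 1700 / 64) / 2)


class TestDecompose:
    def test_constant_trace_haar_lives_in_approximation(self):
        d = dwt.decompose(np.full(256, 3.0), "haar")
        for arr in d.details.values():
            assert np.allclose(arr, 0.0, atol=1e-12)
        assert np.sum(d.approximation**2) == pytest.approx(256 * 9.0)

    def test_unit_impulse_parseval(self):
        x = np.zeros(256)
        x[100] = 1.0
        d = dwt.decompose(x, "sym2")
        total = sum(np.sum(v**2) for v in d.details.values()) + np.sum(
            d.approximation**2
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_20hz_sinusoid_concentrates_in_d6(self):
        # D6 spans 13.3-26.6 Hz at fs=1700
        t = np.arange(256) / dwt.FS_HZ
        x = np.sin(2 * np.pi * 20.0 * t)
        d = dwt.decompose(x, "sym2")
        energies = {f"D{l}": float(np.sum(v**2)) for l, v in d.details.items()}
        energies["A"] = float(np.sum(d.approximation**2))
        assert max(energies, key=energies.get) == "D6"

    def test_coefficient_counts_are_dyadic_for_every_wavelet(self):
        x = np.random.default_rng(0).normal(size=256)
        for name in dwt.SUPPORTED_WAVELETS:
            d = dwt.decompose(x, name)
            for level, arr in d.details.items():
                assert len(arr) == 256 // 2**level
            assert len(d.approximation) == 256 // 2**d.level
            assert sum(len(a) for a in d.details.values()) + len(d.approximation) == 256

    def test_non_finite_input_rejected(self):
        x = np.zeros(256)
        x[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            dwt.decompose(x, "haar")

    def test_non_dyadic_length_rejected(self):
        with pytest.raises(ValueError, match="power of two"):
            dwt.decompose(np.zeros(250), "haar")


class TestEnergyMap:
    def test_one_index_per_coefficient(self, rng):
        d = dwt.decompose(rng.normal(size=256), "sym2")
        emap = dwt.energy_map(d)
        assert len(emap) == 256
        assert sum(1 for e in emap if e.band == "D" and e.level == 6) == 4
        assert sum(1 for e in emap if e.band == "A") == 4

    def test_total_energy_is_parseval(self, rng):
        x = rng.normal(size=256)
        emap = dwt.energy_map(dwt.decompose(x, "coif1"))
        assert sum(e.energy for e in emap) == pytest.approx(np.sum(x**2))

    def test_zero_trace_zero_energies(self):
        emap = dwt.energy_map(dwt.decompose(np.zeros(256), "db4"))
        assert all(e.energy == 0.0 for e in emap)


class TestReconstructSubset:
    def test_full_set_is_identity(self, rng):
        x = rng.normal(size=256)
        d = dwt.decompose(x, "sym2")
        assert np.allclose(dwt.reconstruct_subset(d, d.addresses()), x, atol=1e-10)

    def test_empty_set_is_zero(self, rng):
        d = dwt.decompose(rng.normal(size=256), "sym2")
        assert np.allclose(dwt.reconstruct_subset(d, []), 0.0)

    def test_single_index_reconstructions_sum_to_trace(self, rng):
        x = rng.normal(size=256)
        d = dwt.decompose(x, "fk4")
        total = np.zeros(256)
        for addr in d.addresses():
            total += dwt.reconstruct_subset(d, [addr])
        assert np.allclose(total, x, atol=1e-6)

    def test_invalid_address_rejected(self, rng):
        d = dwt.decompose(rng.normal(size=256), "sym2")
        with pytest.raises(ValueError):
            dwt.reconstruct_subset(d, [("D", 6, 99)])
        with pytest.raises(ValueError):
            dwt.reconstruct_subset(d, [("A", 3, 1)])

    def test_single_index_signal_roundtrip(self):
        atom = dwt.single_index_signal("sym2", ("D", 6, 2), value=2.5)
        d = dwt.decompose(atom, "sym2")
        assert d.coefficient(("D", 6, 2)) == pytest.approx(2.5, abs=1e-9)
        others = [a for a in d.addresses() if a != ("D", 6, 2)]
        assert max(abs(d.coefficient(a)) for a in others) < 1e-9


def test_address_formatting_roundtrip():
    assert dwt.parse_address("D6-2") == ("D", 6, 2)
    assert dwt.format_address(("A", 6, 3)) == "A6-3"
    with pytest.raises(ValueError):
        dwt.parse_address("X6-2")
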