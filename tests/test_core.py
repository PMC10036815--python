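"""Data model, I/O, averaging, splitting and the four evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nirwood.core import (
    SpectraDataset,
    average_replicates,
    compute_metrics,
    describe_density,
    make_wavelength_grid,
    random_split,
    read_spectra_table,
    to_absorbance,
    to_reflectance,
    write_spectra_table,
)


def _tiny_dataset(n=6, p=16, seed=0, reps=1):
    rng = np.random.default_rng(seed)
    wl = make_wavelength_grid(1000, 1000 + p - 1, 1)
    n_rows = n * reps
    return SpectraDataset(
        wavelengths=wl,
        spectra=rng.uniform(0.2, 0.9, size=(n_rows, p)),
        density=np.repeat(rng.uniform(0.6, 1.1, size=n), reps),
        sample_id=np.repeat([f"s{i}" for i in range(n)], reps),
        species=np.array(["oak"] * n_rows, dtype=object),
        location=np.array(["north"] * n_rows, dtype=object),
        replicate=np.tile(np.arange(1, reps + 1), n),
    )


class TestGridAndIO:
    def test_grid_counts(self):
        assert make_wavelength_grid(350, 2397, 1).size == 2048
        assert make_wavelength_grid(350, 2500, 1).size == 2151

    def test_round_trip(self, tmp_path):
        ds = _tiny_dataset(5, 32)
        path = tmp_path / "t.csv"
        write_spectra_table(ds, path)
        back = read_spectra_table(path)
        np.testing.assert_allclose(back.spectra, ds.spectra, atol=1e-12)
        np.testing.assert_allclose(back.density, ds.density, atol=1e-12)
        assert list(back.sample_id) == list(ds.sample_id)

    def test_malformed_cell_names_row(self, tmp_path):
        ds = _tiny_dataset(3, 4)
        path = tmp_path / "t.csv"
        write_spectra_table(ds, path)
        lines = path.read_text().splitlines()
        parts = lines[2].split(",")
        parts[7] = "oops"
        lines[2] = ",".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="row 1"):
            read_spectra_table(path)

    def test_duplicate_and_nonmonotone_rejected(self, tmp_path):
        ds = _tiny_dataset(3, 4)
        ds.sample_id[1] = ds.sample_id[0]  # same id, same replicate index
        path = tmp_path / "t.csv"
        write_spectra_table(ds, path)
        with pytest.raises(ValueError, match="duplicate"):
            read_spectra_table(path)
        header_swapped = path.read_text().splitlines()
        cols = header_swapped[0].split(",")
        cols[5], cols[6] = cols[6], cols[5]
        header_swapped[0] = ",".join(cols)
        path.write_text("\n".join(header_swapped) + "\n")
        with pytest.raises(ValueError, match="increasing"):
            read_spectra_table(path)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            SpectraDataset(
                wavelengths=[3, 2, 1],
                spectra=np.full((1, 3), 0.5),
                density=[1.0],
                sample_id=["a"],
                species=["x"],
                location=["y"],
            )
        with pytest.raises(ValueError, match="reflectance"):
            SpectraDataset(
                wavelengths=[1, 2],
                spectra=np.array([[0.5, 1.5]]),
                density=[1.0],
                sample_id=["a"],
                species=["x"],
                location=["y"],
            )


class TestAveragingAndAbsorbance:
    def test_replicate_mean_and_count(self):
        ds = _tiny_dataset(4, 8, reps=3)
        ds.spectra[0:3, 0] = [0.2, 0.4, 0.6]
        out = average_replicates(ds, 3)
        assert out.n_samples == 4
        assert out.spectra[0, 0] == pytest.approx(0.4)

    def test_identical_replicates_idempotent(self):
        ds = _tiny_dataset(3, 8, reps=3)
        for i in range(3):
            ds.spectra[3 * i : 3 * i + 3] = ds.spectra[3 * i]
        out = average_replicates(ds, 3)
        np.testing.assert_allclose(out.spectra, ds.spectra[::3])

    def test_unequal_replicates_error_lists_ids(self):
        ds = _tiny_dataset(3, 8, reps=3)
        bad = ds.subset(np.arange(ds.n_samples) != 0)
        with pytest.raises(ValueError, match="s0"):
            average_replicates(bad, 3)

    def test_absorbance_identities(self):
        ds = _tiny_dataset(2, 4)
        ds.spectra[:] = 0.1
        ab = to_absorbance(ds)
        np.testing.assert_allclose(ab.spectra, 1.0)
        ds.spectra[:] = 1.0
        np.testing.assert_allclose(to_absorbance(ds).spectra, 0.0)

    def test_absorbance_round_trip(self):
        ds = _tiny_dataset(4, 16, seed=3)
        back = to_reflectance(to_absorbance(ds))
        np.testing.assert_allclose(back.spectra, ds.spectra, atol=1e-12)

    def test_average_then_convert_does_not_commute(self):
        """mean(log x) != log(mean x): the order (average reflectance first,
        then convert) is part of the contract."""
        ds = _tiny_dataset(2, 4, reps=3, seed=5)
        a = to_absorbance(average_replicates(ds, 3)).spectra
        b_all = to_absorbance(ds)
        b = average_replicates(
            SpectraDataset(
                wavelengths=ds.wavelengths,
                spectra=b_all.spectra,
                density=ds.density,
                sample_id=ds.sample_id,
                species=ds.species,
                location=ds.location,
                replicate=ds.replicate,
                mode="absorbance",
            ),
            3,
        ).spectra
        assert np.max(np.abs(a - b)) > 1e-6


class TestSplit:
    def test_split_counts_and_determinism(self):
        ds = _tiny_dataset(30, 8, seed=1)
        s1 = random_split(ds, 0.7, seed=4)
        s2 = random_split(ds, 0.7, seed=4)
        assert (s1.set_label == "calibration").sum() == 21
        assert list(s1.set_label) == list(s2.set_label)
        # partition: every sample in exactly one set
        assert set(s1.set_label) <= {"calibration", "prediction"}

    def test_small_species_error(self):
        ds = _tiny_dataset(3, 4)
        ds.species[0] = "rare"
        with pytest.raises(ValueError, match="rare"):
            random_split(ds, 0.7, seed=0)

    def test_containment_warning(self):
        ds = _tiny_dataset(10, 4, seed=2)
        ds.density[:] = np.linspace(0.6, 1.1, 10)
        # force the extreme-density sample into the prediction set: scan seeds
        for seed in range(200):
            s = random_split.__wrapped__ if hasattr(random_split, "__wrapped__") else random_split
            import warnings

            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                out = s(ds, 0.7, seed=seed)
            pred = out.density[out.set_label == "prediction"]
            cal = out.density[out.set_label == "calibration"]
            if pred.min() < cal.min() or pred.max() > cal.max():
                assert any("extrapolation" in str(w.message) for w in caught)
                return
        pytest.skip("no seed produced an uncontained split on this data")


class TestMetrics:
    def test_printed_rpd_pairs(self):
        """Construct data with a given R2; the population-SD RPD must match
        the tabulated value to 3 decimals."""
        for r2, rpd in [(0.812, 2.306), (0.823, 2.377), (0.901, 3.178), (0.755, 2.02)]:
            y = np.linspace(0.9, 1.2, 40)
            ss_tot = np.sum((y - y.mean()) ** 2)
            resid = np.sin(np.arange(40))  # arbitrary shape
            resid *= np.sqrt((1 - r2) * ss_tot / np.sum(resid**2))
            m = compute_metrics(y, y - resid)
            assert round(m.rpd, 3) == pytest.approx(rpd, abs=5e-4)

    def test_rsd_worked_example(self):
        """RMSE 0.020 at mean density 1.047 g/cm3 gives RSD 1.910 %."""
        n = 50
        y = np.full(n, 1.047) + np.linspace(-0.1, 0.1, n)
        resid = np.cos(np.arange(n))
        resid *= 0.020 * np.sqrt(n) / np.linalg.norm(resid)
        m = compute_metrics(y, y - resid)
        assert m.rmse == pytest.approx(0.020, abs=1e-12)
        assert round(m.rsd, 3) == pytest.approx(1.910, abs=5e-4)

    def test_perfect_prediction(self):
        y = np.array([0.6, 0.8, 1.0])
        m = compute_metrics(y, y)
        assert m.r2 == 1.0 and m.rmse == 0.0 and np.isinf(m.rpd)

    def test_errors(self):
        with pytest.raises(ValueError, match="constant"):
            compute_metrics(np.ones(5), np.zeros(5))
        with pytest.raises(ValueError, match="two"):
            compute_metrics([1.0], [1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_rpd_r2_identity_property(self, seed):
        """|RPD - (1 - R2)^(-1/2)| < 1e-9 and RSD * mean == 100 * RMSE."""
        rng = np.random.default_rng(seed)
        y = rng.uniform(0.5, 1.2, size=20)
        yhat = y + rng.normal(0, 0.05, size=20)
        m = compute_metrics(y, yhat)
        if m.r2 < 1:
            assert abs(m.rpd - (1 - m.r2) ** -0.5) < 1e-9
        assert m.rsd * np.mean(y) == pytest.approx(100 * m.rmse, rel=1e-12)


def test_describe_density_shapes():
    ds = _tiny_dataset(12, 4, seed=6)
    ds.species[6:] = "pine"
    out = random_split(ds, 0.7, seed=1)
    table = describe_density(out)
    assert set(table["set"]) == {"calibration", "prediction"}
    assert len(table) == 4  # two sets x two species
    const = _tiny_dataset(4, 4)
    const.density[:] = 0.8
    const.set_label[:] = "calibration"
    assert describe_density(const)["sd"].iloc[0] == 0.0
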