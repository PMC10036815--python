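"""Data model, I/O and evaluation metrics for Vis-NIR wood-density work.

A :class:`SpectraDataset` holds a wavelength grid (nm, 1 nm spacing in the
standard configuration: 350-2397 nm, 2048 variables), a samples x wavelengths
matrix of reflectance or absorbance values, per-sample wood density (g/cm3)
and species/location/replicate labels.  Model quality is summarized by four
standard chemometric indicators:

    R^2  = 1 - SS_res / SS_tot
    RMSE = sqrt(mean((y - yhat)^2))            [g/cm3]
    RPD  = SD(y) / RMSE                        (population SD, so that
                                                RPD = (1 - R^2)^(-1/2) exactly)
    RSD  = 100 * RMSE / mean(y)                [%]
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectraDataset",
    "ModelMetrics",
    "make_wavelength_grid",
    "read_spectra_table",
    "write_spectra_table",
    "average_replicates",
    "to_absorbance",
    "to_reflectance",
    "random_split",
    "compute_metrics",
    "describe_density",
]

_META_COLUMNS = ["sample_id", "species", "location", "replicate", "density"]


def make_wavelength_grid(start: float = 350.0, stop: float = 2397.0, step: float = 1.0) -> np.ndarray:
    """Inclusive wavelength grid in nm (350-2397 at 1 nm -> 2048 points)."""
    if stop <= start:
        raise ValueError("stop must exceed start")
    if step <= 0:
        raise ValueError("step must be positive")
    return np.arange(start, stop + step / 2, step, dtype=float)


@dataclass
class SpectraDataset:
    """Replicate- or sample-level spectra with density and labels."""

    wavelengths: np.ndarray
    spectra: np.ndarray
    density: np.ndarray
    sample_id: np.ndarray
    species: np.ndarray
    location: np.ndarray
    replicate: np.ndarray | None = None
    mode: str = "reflectance"
    set_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.density = np.asarray(self.density, dtype=float)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.species = np.asarray(self.species, dtype=object)
        self.location = np.asarray(self.location, dtype=object)
        n = self.spectra.shape[0]
        if self.replicate is None:
            self.replicate = np.ones(n, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate, dtype=int)
        if self.set_label is None:
            self.set_label = np.array(["unassigned"] * n, dtype=object)
        else:
            self.set_label = np.asarray(self.set_label, dtype=object)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.spectra.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"spectra have {self.spectra.shape[1]} columns but the grid "
                f"has {self.wavelengths.size} wavelengths"
            )
        for name, arr in (
            ("density", self.density),
            ("sample_id", self.sample_id),
            ("species", self.species),
            ("location", self.location),
            ("replicate", self.replicate),
            ("set_label", self.set_label),
        ):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows, spectra have {n}")
        if self.mode not in ("reflectance", "absorbance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "reflectance" and self.spectra.size:
            if np.any(self.spectra <= 0) or np.any(self.spectra > 1):
                raise ValueError("reflectance values must lie in (0, 1]")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def subset(self, mask: np.ndarray) -> "SpectraDataset":
        mask = np.asarray(mask)
        return replace(
            self,
            spectra=self.spectra[mask],
            density=self.density[mask],
            sample_id=self.sample_id[mask],
            species=self.species[mask],
            location=self.location[mask],
            replicate=self.replicate[mask],
            set_label=self.set_label[mask],
        )

    def calibration(self) -> "SpectraDataset":
        return self.subset(self.set_label == "calibration")

    def prediction(self) -> "SpectraDataset":
        return self.subset(self.set_label == "prediction")

    def with_spectra(self, spectra: np.ndarray, mode: str | None = None) -> "SpectraDataset":
        return replace(self, spectra=np.asarray(spectra, dtype=float), mode=mode or self.mode)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


def write_spectra_table(dataset: SpectraDataset, path, sep: str = ",") -> None:
    """Write the replicate-level table: header ``sample_id,species,location,
    replicate,density,<wavelengths...>``, UTF-8, full float precision."""
    frame = pd.DataFrame(
        {
            "sample_id": dataset.sample_id,
            "species": dataset.species,
            "location": dataset.location,
            "replicate": dataset.replicate,
            "density": dataset.density,
        }
    )
    spec = pd.DataFrame(
        dataset.spectra, columns=[format(w, ".10g") for w in dataset.wavelengths]
    )
    pd.concat([frame, spec], axis=1).to_csv(
        path, sep=sep, index=False, float_format="%.17g", encoding="utf-8"
    )


def read_spectra_table(path, sep: str = ",", mode: str = "reflectance") -> SpectraDataset:
    """Read a delimited spectra table written by :func:`write_spectra_table`.

    Malformed spectral cells and duplicate (sample_id, replicate) pairs are
    rejected with the offending row index.
    """
    table = pd.read_csv(path, sep=sep, dtype={"sample_id": str}, encoding="utf-8")
    missing = [c for c in _META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing metadata columns: {missing}")
    wl_cols = [c for c in table.columns if c not in _META_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header: {exc}") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelength header is not strictly increasing")
    spectra = np.empty((len(table), len(wl_cols)))
    for j, col in enumerate(wl_cols):
        values = pd.to_numeric(table[col], errors="coerce").to_numpy()
        if np.any(np.isnan(values)):
            row = int(np.argmax(np.isnan(values)))
            raise ValueError(
                f"non-numeric spectral value in column {col!r} at data row {row}"
            )
        spectra[:, j] = values
    keys = list(zip(table["sample_id"], table["replicate"]))
    seen: dict = {}
    for i, key in enumerate(keys):
        if key in seen:
            raise ValueError(
                f"duplicate sample_id/replicate pair {key} at data rows "
                f"{seen[key]} and {i}"
            )
        seen[key] = i
    return SpectraDataset(
        wavelengths=wavelengths,
        spectra=spectra,
        density=table["density"].to_numpy(dtype=float),
        sample_id=table["sample_id"].to_numpy(dtype=object),
        species=table["species"].to_numpy(dtype=object),
        location=table["location"].to_numpy(dtype=object),
        replicate=table["replicate"].to_numpy(dtype=int),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Replicate averaging, absorbance conversion, splitting
# ---------------------------------------------------------------------------


def average_replicates(dataset: SpectraDataset, replicates_per_sample: int = 3) -> SpectraDataset:
    """Average the replicate scans of each sample into one raw spectrum.

    Every sample_id must contribute exactly ``replicates_per_sample`` rows;
    density and labels must be constant within a sample and are carried
    through.  Averaging happens in the dataset's current mode (reflectance
    first, then convert — the two operations do not commute).
    """
    ids, first_idx, counts = np.unique(
        dataset.sample_id, return_index=True, return_counts=True
    )
    offenders = [str(i) for i, c in zip(ids, counts) if c != replicates_per_sample]
    if offenders:
        raise ValueError(
            f"samples without exactly {replicates_per_sample} replicates: "
            + ", ".join(offenders)
        )
    order = np.argsort(first_idx)  # preserve first-appearance order
    ids = ids[order]
    spectra = np.empty((ids.size, dataset.n_wavelengths))
    density = np.empty(ids.size)
    species = np.empty(ids.size, dtype=object)
    location = np.empty(ids.size, dtype=object)
    for k, sid in enumerate(ids):
        mask = dataset.sample_id == sid
        spectra[k] = dataset.spectra[mask].mean(axis=0)
        dens = dataset.density[mask]
        if np.ptp(dens) > 0:
            raise ValueError(f"sample {sid!r} has inconsistent density values")
        density[k] = dens[0]
        species[k] = dataset.species[mask][0]
        location[k] = dataset.location[mask][0]
    return SpectraDataset(
        wavelengths=dataset.wavelengths,
        spectra=spectra,
        density=density,
        sample_id=ids,
        species=species,
        location=location,
        replicate=np.ones(ids.size, dtype=int),
        mode=dataset.mode,
    )


def to_absorbance(dataset: SpectraDataset) -> SpectraDataset:
    """Convert reflectance to absorbance, A = log10(1/R)."""
    if dataset.mode != "reflectance":
        raise ValueError("dataset is not in reflectance mode")
    if np.any(dataset.spectra <= 0):
        raise ValueError("reflectance must be positive to take log10(1/R)")
    return dataset.with_spectra(np.log10(1.0 / dataset.spectra), mode="absorbance")


def to_reflectance(dataset: SpectraDataset) -> SpectraDataset:
    """Inverse of :func:`to_absorbance`, R = 10**(-A)."""
    if dataset.mode != "absorbance":
        raise ValueError("dataset is not in absorbance mode")
    return dataset.with_spectra(10.0 ** (-dataset.spectra), mode="reflectance")


def random_split(
    dataset: SpectraDataset, fraction_calibration: float = 0.7, seed: int = 0
) -> SpectraDataset:
    """Random calibration/prediction split, stratified by species.

    Per species, floor(n * fraction) samples go to calibration with at least
    one sample left for prediction.  A warning is emitted if the prediction
    density range is not contained in the calibration range.
    """
    if not 0 < fraction_calibration < 1:
        raise ValueError("fraction_calibration must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.array(["prediction"] * dataset.n_samples, dtype=object)
    for sp in np.unique(dataset.species.astype(str)):
        idx = np.flatnonzero(dataset.species.astype(str) == sp)
        if idx.size < 2:
            raise ValueError(
                f"species {sp!r} has {idx.size} sample(s); need >= 2 to split"
            )
        n_cal = min(int(np.floor(idx.size * fraction_calibration)), idx.size - 1)
        n_cal = max(n_cal, 1)
        chosen = rng.choice(idx, size=n_cal, replace=False)
        labels[chosen] = "calibration"
    out = replace(dataset, set_label=labels)
    cal_d = out.density[labels == "calibration"]
    pred_d = out.density[labels == "prediction"]
    if pred_d.size and (pred_d.min() < cal_d.min() or pred_d.max() > cal_d.max()):
        warnings.warn(
            "prediction-set density range exceeds the calibration-set range; "
            "predictions there are extrapolations",
            UserWarning,
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelMetrics:
    """R2, RMSE (g/cm3), RPD and RSD (%) for one reference/prediction pair."""

    r2: float
    rmse: float
    rpd: float
    rsd: float
    n: int = 0

    def __str__(self) -> str:  # table formatting: 3 decimals, RSD with %
        rpd = "inf" if np.isinf(self.rpd) else f"{self.rpd:.3f}"
        return (
            f"R2={self.r2:.3f} RMSE={self.rmse:.3f} RPD={rpd} RSD={self.rsd:.3f}%"
        )

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "rpd": self.rpd,
            "rsd": self.rsd,
            "n": self.n,
        }


def compute_metrics(reference: np.ndarray, predicted: np.ndarray) -> ModelMetrics:
    """Evaluate predictions against reference densities.

    The RPD uses the population standard deviation (denominator n), which
    makes RPD = (1 - R2)**(-1/2) an exact identity whenever R2 < 1.
    """
    y = np.asarray(reference, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("reference and prediction lengths differ")
    if y.size < 2:
        raise ValueError("need at least two samples to compute metrics")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("reference values are constant; metrics undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / y.size))
    sd = float(np.sqrt(ss_tot / y.size))
    rpd = np.inf if rmse == 0.0 else sd / rmse
    rsd = 100.0 * rmse / float(np.mean(y))
    return ModelMetrics(r2=r2, rmse=rmse, rpd=rpd, rsd=rsd, n=y.size)


def describe_density(dataset: SpectraDataset) -> pd.DataFrame:
    """Five-number descriptive table (min, max, mean, sd, n) of density per
    set label and species."""
    rows = []
    for label in ("calibration", "prediction", "unassigned"):
        mask = dataset.set_label == label
        if not mask.any():
            continue
        for sp in np.unique(dataset.species[mask].astype(str)):
            d = dataset.density[mask & (dataset.species.astype(str) == sp)]
            sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
            rows.append(
                {
                    "set": label,
                    "species": sp,
                    "min": float(d.min()),
                    "max": float(d.max()),
                    "mean": float(d.mean()),
                    "sd": sd,
                    "n": int(d.size),
                }
            )
    if not rows:
        warnings.warn("no rows with set labels; empty description", UserWarning)
    return pd.DataFrame(rows)
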