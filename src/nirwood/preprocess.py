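"""Spectral denoising and scatter correction.

Wavelet denoising (lifting or classical filter bank) uses soft or hard
thresholding of detail coefficients with the universal threshold

    lambda_j = scale * sigma_hat * sqrt(2 ln n_j),
    sigma_hat = median(|d_1|) / 0.6745,

where d_1 is the finest detail level; coefficients are taken in the
orthonormal (normalized) convention so a single noise estimate applies at
every level.  The wavelet function / order / decomposition level are chosen
by a three-stage greedy search scored with cross-validated PLS, mirroring
common chemometric practice: fix (order, level) = (3, 8) and pick the best
function among haar, db3, sym3 and bior1.3; then scan the order 2..8 for the
winning family; then scan the level 1..8.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import pywt

from . import calibrate
from .core import ModelMetrics, SpectraDataset, compute_metrics
from .lifting import lwt_forward, lwt_inverse, _pad_symmetric

__all__ = [
    "WaveletSpec",
    "lwt_denoise",
    "dwt_denoise",
    "msc",
    "snv",
    "select_wavelet_params",
    "pls_cv_scorer",
]

_FAMILIES = ("haar", "db", "sym", "bior")
_BIOR_ORDERS = (1, 3, 5)  # registered bior1.x reconstruction orders


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet function, order, decomposition level and threshold rule.

    For db/sym the order is the number of vanishing moments; for bior it is
    the reconstruction order Nd of bior1.Nd (only 1, 3, 5 are registered);
    haar takes no order.
    """

    family: str = "db"
    order: int = 3
    level: int = 8
    threshold_rule: str = "soft"
    threshold_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.level < 1:
            raise ValueError("decomposition level must be >= 1")
        if self.threshold_rule not in ("soft", "hard"):
            raise ValueError("threshold_rule must be 'soft' or 'hard'")
        if self.family == "bior" and self.order not in _BIOR_ORDERS:
            raise ValueError(f"bior1.{self.order} is not registered")
        if self.family in ("db", "sym") and not 1 <= self.order <= 20:
            raise ValueError("db/sym order out of range")

    @property
    def name(self) -> str:
        if self.family == "haar":
            return "haar"
        if self.family == "bior":
            return f"bior1.{self.order}"
        return f"{self.family}{self.order}"


def _thresholds(details: list[np.ndarray], rule: str, scale: float) -> list[np.ndarray]:
    sigma = float(np.median(np.abs(details[0]))) / 0.6745
    out = []
    for d in details:
        lam = scale * sigma * np.sqrt(2.0 * np.log(max(d.size, 2)))
        out.append(pywt.threshold(d, lam, mode=rule) if lam > 0 else d.copy())
    return out


def lwt_denoise(dataset: SpectraDataset, spec: WaveletSpec) -> SpectraDataset:
    """Denoise every spectrum with the lifting wavelet transform.

    Forward transform to level k, threshold all detail levels, inverse
    transform; shape and wavelength grid are unchanged.
    """
    out = np.empty_like(dataset.spectra)
    for i, row in enumerate(dataset.spectra):
        pyr = lwt_forward(row, spec.name, spec.level, normalize=True)
        pyr.details = _thresholds(pyr.details, spec.threshold_rule, spec.threshold_scale)
        out[i] = lwt_inverse(pyr)
    if dataset.mode == "reflectance":
        out = np.clip(out, 1e-6, 1.0)
    return dataset.with_spectra(out)


def dwt_denoise(dataset: SpectraDataset, spec: WaveletSpec) -> SpectraDataset:
    """Classical (filter-bank) wavelet denoising with the same threshold
    rule; uses periodized convolution after symmetric padding, matching the
    lifting transform's boundary treatment."""
    out = np.empty_like(dataset.spectra)
    block = 2**spec.level
    for i, row in enumerate(dataset.spectra):
        padded, left = _pad_symmetric(row, block)
        coeffs = pywt.wavedec(padded, spec.name, mode="periodization", level=spec.level)
        details = list(coeffs[1:])  # coarsest..finest
        details_fine_first = details[::-1]
        details_fine_first = _thresholds(
            details_fine_first, spec.threshold_rule, spec.threshold_scale
        )
        coeffs = [coeffs[0]] + details_fine_first[::-1]
        rec = pywt.waverec(coeffs, spec.name, mode="periodization")
        out[i] = rec[left : left + row.size]
    if dataset.mode == "reflectance":
        out = np.clip(out, 1e-6, 1.0)
    return dataset.with_spectra(out)


def msc(
    dataset: SpectraDataset, reference: np.ndarray | None = None
) -> tuple[SpectraDataset, np.ndarray]:
    """Multiplicative scatter correction.

    Each spectrum x is regressed on the reference, x ~ a + b * ref, and
    corrected to (x - a) / b.  The reference defaults to the calibration-set
    mean spectrum (overall mean if no split is assigned) and is returned so
    prediction-set spectra can be corrected against the same reference.
    """
    if reference is None:
        cal = dataset.set_label == "calibration"
        pool = dataset.spectra[cal] if cal.any() else dataset.spectra
        if pool.shape[0] < 2:
            raise ValueError("MSC needs >= 2 spectra to form a mean reference")
        reference = pool.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0.0:
        raise ValueError("MSC reference is constant")
    out = np.empty_like(dataset.spectra)
    for i, x in enumerate(dataset.spectra):
        b = float(ref_c @ (x - x.mean())) / denom
        if abs(b) < 1e-12:
            raise ValueError(f"spectrum {i} has no multiplicative component (b ~ 0)")
        a = float(x.mean() - b * reference.mean())
        out[i] = (x - a) / b
    return dataset.with_spectra(out), reference


def snv(dataset: SpectraDataset) -> SpectraDataset:
    """Standard normal variate: per spectrum, subtract the mean and divide
    by the standard deviation (denominator n-1)."""
    mu = dataset.spectra.mean(axis=1, keepdims=True)
    sd = dataset.spectra.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for constant spectra")
    return dataset.with_spectra((dataset.spectra - mu) / sd)


# ---------------------------------------------------------------------------
# Sequential wavelet-parameter search
# ---------------------------------------------------------------------------


def pls_cv_scorer(
    n_latent: int | None = None,
    n_folds: int = 5,
    seed: int = 0,
    max_latent: int = 15,
):
    """Build a scorer: denoised dataset -> cross-validated PLS ModelMetrics.

    Scores on the calibration subset when a split is assigned, otherwise on
    the full dataset.  The latent count is chosen by inner CV unless fixed.
    """

    def scorer(dataset: SpectraDataset) -> ModelMetrics:
        cal = dataset.set_label == "calibration"
        data = dataset.subset(cal) if cal.any() else dataset
        X, y = data.spectra, data.density
        k = n_latent or calibrate.select_n_latent(
            X, y, max_latent=max_latent, n_folds=n_folds, seed=seed
        )
        folds = calibrate._fold_assignment(y.size, n_folds, seed)
        pred = np.empty_like(y)
        for f in range(n_folds):
            test = folds == f
            kf = min(k, int((~test).sum()) - 1)
            model = calibrate.pls_fit(X[~test], y[~test], kf)
            pred[test] = model.predict(X[test])
        return compute_metrics(y, pred)

    return scorer


def select_wavelet_params(
    dataset: SpectraDataset,
    scorer=None,
    candidate_functions: tuple[str, ...] = ("haar", "db3", "sym3", "bior1.3"),
    order_range=range(2, 9),
    level_range=range(1, 9),
    threshold_rule: str = "soft",
    threshold_scale: float = 1.0,
) -> tuple[WaveletSpec, pd.DataFrame]:
    """Greedy three-stage search for (function, order, level).

    Stage 1 fixes order=3, level=8 and compares the candidate functions;
    stage 2 scans the order for the winning family (skipped for haar;
    restricted to registered members for bior); stage 3 scans the level.
    Each candidate is scored by cross-validated PLS; lower RMSE wins and
    ties keep the earlier candidate.  Returns the winning spec and the full
    score table.
    """
    if not candidate_functions:
        raise ValueError("candidate_functions must not be empty")
    if scorer is None:
        scorer = pls_cv_scorer()

    def parse(name: str) -> WaveletSpec:
        if name == "haar":
            return WaveletSpec("haar", 1, 8, threshold_rule, threshold_scale)
        if name.startswith("bior1."):
            return WaveletSpec("bior", int(name.split(".")[1]), 8, threshold_rule, threshold_scale)
        for fam in ("db", "sym"):
            if name.startswith(fam):
                return WaveletSpec(fam, int(name[len(fam):]), 8, threshold_rule, threshold_scale)
        raise ValueError(f"unsupported candidate wavelet {name!r}")

    rows = []

    def score(spec: WaveletSpec, stage: str) -> float:
        metrics = scorer(lwt_denoise(dataset, spec))
        rows.append(
            {
                "stage": stage,
                "wavelet": spec.name,
                "order": spec.order,
                "level": spec.level,
                "cv_r2": metrics.r2,
                "cv_rmse": metrics.rmse,
                "cv_rpd": metrics.rpd,
                "cv_rsd": metrics.rsd,
            }
        )
        return metrics.rmse

    # stage 1: wavelet function at (order, level) = (3, 8)
    best_spec, best_rmse = None, np.inf
    for name in candidate_functions:
        spec = parse(name)
        rmse = score(spec, "function")
        if rmse < best_rmse - 1e-15:
            best_spec, best_rmse = spec, rmse

    # stage 2: order scan for the winning family
    if best_spec.family != "haar":
        stage1_order = best_spec.order
        orders = [
            o
            for o in order_range
            if best_spec.family != "bior" or o in _BIOR_ORDERS
        ]
        for o in orders:
            if o == stage1_order:
                continue  # already scored in stage 1
            spec = replace(best_spec, order=o)
            rmse = score(spec, "order")
            if rmse < best_rmse - 1e-15:
                best_spec, best_rmse = spec, rmse

    # stage 3: decomposition level scan
    stage2_level = best_spec.level
    for lev in level_range:
        if lev == stage2_level:
            continue
        spec = replace(best_spec, level=lev)
        rmse = score(spec, "level")
        if rmse < best_rmse - 1e-15:
            best_spec, best_rmse = spec, rmse

    return best_spec, pd.DataFrame(rows)
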