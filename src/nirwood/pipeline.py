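"""End-to-end workflow: denoising search, wavelength selection comparison,
linear and hybrid nonlinear calibration, and signal-vs-combined modeling.

``run_single_species`` reproduces, per species, the full chemometric chain:

    replicate averaging -> log(1/R) -> calibration/prediction split ->
    greedy wavelet-parameter search -> LWT denoising ->
    {Full, LWT, SPA, UVE, CARS, IRIV} x PLS comparison ->
    FOA-GRNN and RSM-PSO-SVM on the winning wavelength subset ->
    metrics on the prediction set, both raw and LWT-denoised.

``run_combined`` contrasts "signal" models (one species) against "combined"
models (pooled species/locations) for PLS and PCR on raw spectra.

Selector hyperparameters default to desk-scale settings (Monte-Carlo runs,
binary-sampling rows) so a full run on a 60-sample, few-hundred-wavelength
dataset stays in the minutes range; all are exposed on :class:`RunConfig`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibrate, optimize, preprocess, varselect
from .core import (
    SpectraDataset,
    average_replicates,
    compute_metrics,
    describe_density,
    random_split,
    to_absorbance,
)
from .optimize import FOAConfig, PSOConfig, BBDesign
from .preprocess import WaveletSpec
from .synthgen import SynthConfig, generate_dataset

logger = logging.getLogger("nirwood")

__all__ = ["RunConfig", "run_single_species", "run_combined", "simulate_groups"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: str | None = None
    synth: SynthConfig | None = None
    replicates_per_sample: int = 3
    fraction_calibration: float = 0.7
    seed: int = 0
    preprocessing: str = "lwt"  # raw | lwt | wt | msc | snv
    wavelet: WaveletSpec | None = None  # None -> sequential search
    selection_methods: tuple[str, ...] = ("spa", "uve", "cars", "iriv")
    models: tuple[str, ...] = ("pls", "pcr", "foa_grnn", "rsm_pso_svm")
    output_dir: str | None = None
    # selector scale knobs
    cars_runs: int = 50
    iriv_rows: int = 100
    iriv_downsample: int = 4
    spa_range: tuple[int, int] = (5, 40)
    # optimizer settings
    foa: FOAConfig = field(default_factory=FOAConfig)
    pso: PSOConfig = field(default_factory=lambda: PSOConfig(population=10, max_generation=15, n_cv=5))
    rsm_design: BBDesign | None = None
    n_folds: int = 5

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model must be requested")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)


def simulate_groups(groups: dict[tuple[str, str], SynthConfig]) -> SpectraDataset:
    """Concatenate synthetic datasets for several (species, location) groups."""
    parts = []
    for (species, location), cfg in groups.items():
        ds, _ = generate_dataset(cfg)
        ds.species[:] = species
        ds.location[:] = location
        ds.sample_id = np.array(
            [f"{species}-{location}-{sid}" for sid in ds.sample_id], dtype=object
        )
        parts.append(ds)
    first = parts[0]
    for other in parts[1:]:
        if not np.array_equal(other.wavelengths, first.wavelengths):
            raise ValueError("all groups must share a wavelength grid")
    return SpectraDataset(
        wavelengths=first.wavelengths,
        spectra=np.vstack([p.spectra for p in parts]),
        density=np.concatenate([p.density for p in parts]),
        sample_id=np.concatenate([p.sample_id for p in parts]),
        species=np.concatenate([p.species for p in parts]),
        location=np.concatenate([p.location for p in parts]),
        replicate=np.concatenate([p.replicate for p in parts]),
        mode="reflectance",
    )


def _load(config: RunConfig) -> SpectraDataset:
    if config.input_path is not None:
        from .core import read_spectra_table

        return read_spectra_table(config.input_path)
    cfg = config.synth or SynthConfig(seed=config.seed)
    ds, _ = generate_dataset(cfg)
    return ds


def _prepare(dataset: SpectraDataset, config: RunConfig) -> SpectraDataset:
    """Average replicates, convert to absorbance, assign the split."""
    averaged = average_replicates(dataset, config.replicates_per_sample)
    ab = to_absorbance(averaged)
    return random_split(ab, config.fraction_calibration, seed=config.seed)


def _pls_eval(X_cal, y_cal, X_pred, y_pred, n_folds, seed):
    """Fit PLS (CV-chosen latent count); return calibration/CV/prediction metrics."""
    k = calibrate.select_n_latent(X_cal, y_cal, n_folds=n_folds, seed=seed)
    model = calibrate.pls_fit(X_cal, y_cal, k)
    cal = compute_metrics(y_cal, model.predict(X_cal))
    folds = calibrate._fold_assignment(y_cal.size, n_folds, seed)
    cv_pred = np.empty_like(y_cal)
    for f in range(n_folds):
        test = folds == f
        kf = min(k, int((~test).sum()) - 1)
        cv_pred[test] = calibrate.pls_fit(X_cal[~test], y_cal[~test], kf).predict(X_cal[test])
    cv = compute_metrics(y_cal, cv_pred)
    pred = (
        compute_metrics(y_pred, model.predict(X_pred)) if y_pred is not None else None
    )
    return model, {"calibration": cal, "cross_validation": cv, "prediction": pred, "n_latent": k}


def _metrics_row(prefix: str, metrics) -> dict:
    if metrics is None:
        return {}
    return {
        f"{prefix}_r2": metrics.r2,
        f"{prefix}_rmse": metrics.rmse,
        f"{prefix}_rpd": metrics.rpd,
        f"{prefix}_rsd": metrics.rsd,
    }


def _run_selector(method, X, y, config: RunConfig, seed):
    p = X.shape[1]
    if method == "uve":
        return varselect.uve(X, y, seed=seed)
    if method == "cars":
        return varselect.cars(X, y, n_runs=config.cars_runs, seed=seed)
    if method == "spa":
        lo, hi = config.spa_range
        hi = min(hi, X.shape[0] - 2, p)
        return varselect.spa(X, y, min_vars=min(lo, hi), max_vars=hi, seed=seed)
    if method == "iriv":
        step = max(1, config.iriv_downsample)
        cols = np.arange(0, p, step)
        res = varselect.iriv(
            X[:, cols], y, n_rows_bms=max(config.iriv_rows, 50), seed=seed
        )
        return replace(res, selected=cols[res.selected])
    raise ValueError(f"unknown selection method {method!r}")


def run_single_species(config: RunConfig) -> dict:
    """Execute the per-species workflow; returns a report bundle of tables."""
    data = _load(config)
    reports: dict[str, dict] = {}
    for species in np.unique(data.species.astype(str)):
        try:
            reports[species] = _single_species_branch(
                data.subset(data.species.astype(str) == species), config
            )
        except Exception:  # keep other species running
            logger.exception("species branch %r failed", species)
    if not reports:
        raise RuntimeError("every species branch failed")
    if config.output_dir:
        _write_reports(reports, config)
    return reports


def _single_species_branch(data: SpectraDataset, config: RunConfig) -> dict:
    split = _prepare(data, config)
    scorer = preprocess.pls_cv_scorer(n_folds=config.n_folds, seed=config.seed)

    if config.wavelet is not None:
        spec, wavelet_table = config.wavelet, pd.DataFrame()
    else:
        spec, wavelet_table = preprocess.select_wavelet_params(split, scorer=scorer)

    denoise = preprocess.lwt_denoise if config.preprocessing != "wt" else preprocess.dwt_denoise
    denoised = denoise(split, spec) if config.preprocessing in ("lwt", "wt") else split

    cal_raw, pred_raw = split.calibration(), split.prediction()
    cal_dn, pred_dn = denoised.calibration(), denoised.prediction()
    y_cal, y_pred = cal_dn.density, pred_dn.density

    # --- selection comparison (Full and LWT baselines + the four methods)
    sel_rows = []
    _, full_res = _pls_eval(cal_raw.spectra, y_cal, None, None, config.n_folds, config.seed)
    sel_rows.append(
        {"method": "full", "n_variables": split.n_wavelengths}
        | _metrics_row("cal", full_res["calibration"])
        | _metrics_row("cv", full_res["cross_validation"])
    )
    _, lwt_res = _pls_eval(cal_dn.spectra, y_cal, None, None, config.n_folds, config.seed)
    sel_rows.append(
        {"method": "lwt", "n_variables": split.n_wavelengths}
        | _metrics_row("cal", lwt_res["calibration"])
        | _metrics_row("cv", lwt_res["cross_validation"])
    )
    selections: dict[str, varselect.SelectionResult] = {}
    for method in config.selection_methods:
        result = _run_selector(method, cal_dn.spectra, y_cal, config, config.seed)
        selections[method] = result
        _, res = _pls_eval(
            cal_dn.spectra[:, result.selected], y_cal, None, None, config.n_folds, config.seed
        )
        sel_rows.append(
            {
                "method": method,
                "n_variables": int(result.selected.size),
                "reduction_percent": varselect.reduction_percent(
                    result.selected.size, split.n_wavelengths
                ),
            }
            | _metrics_row("cal", res["calibration"])
            | _metrics_row("cv", res["cross_validation"])
        )
    selection_table = pd.DataFrame(sel_rows)
    method_rows = selection_table[selection_table["method"].isin(selections)]
    best_method = str(method_rows.sort_values("cv_rmse").iloc[0]["method"]) if selections else None
    chosen = selections[best_method].selected if best_method else np.arange(split.n_wavelengths)

    # --- calibration models on the winning subset, evaluated on raw and
    # denoised prediction spectra
    model_rows = []
    Xc = cal_dn.spectra[:, chosen]
    for kind in config.models:
        if kind == "pls":
            model, res = _pls_eval(Xc, y_cal, None, None, config.n_folds, config.seed)
        elif kind == "pcr":
            k = calibrate.select_n_latent(Xc, y_cal, n_folds=config.n_folds, seed=config.seed, kind="pcr")
            model = calibrate.pcr_fit(Xc, y_cal, k)
        elif kind == "foa_grnn":
            model, _ = optimize.foa_grnn_train(
                Xc, y_cal, replace(config.foa, seed=config.seed), n_cv=config.n_folds
            )
        elif kind == "rsm_pso_svm":
            model, _ = optimize.rsm_pso_svm_train(
                Xc, y_cal, design=config.rsm_design,
                pso_base_config=replace(config.pso, seed=config.seed),
            )
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        cal_metrics = compute_metrics(y_cal, model.predict(Xc))
        for label, pred_set in (("raw", pred_raw), ("lwt", pred_dn)):
            pm = compute_metrics(y_pred, model.predict(pred_set.spectra[:, chosen]))
            model_rows.append(
                {"model": kind, "prediction_spectra": label, "n_variables": int(len(chosen))}
                | _metrics_row("cal", cal_metrics)
                | _metrics_row("pred", pm)
            )
    model_table = pd.DataFrame(model_rows)

    return {
        "wavelet_spec": spec,
        "wavelet_table": wavelet_table,
        "selection_table": selection_table,
        "selections": selections,
        "best_selector": best_method,
        "selected_wavelengths": split.wavelengths[chosen],
        "model_table": model_table,
        "density_summary": describe_density(split),
        "reduction_percent": varselect.reduction_percent(len(chosen), split.n_wavelengths),
    }


# ---------------------------------------------------------------------------
# Signal vs combined models
# ---------------------------------------------------------------------------


def _linear_eval(group: SpectraDataset, config: RunConfig) -> dict:
    """PLS and PCR metrics (calibration / CV / prediction) for one grouping."""
    cal, pred = group.calibration(), group.prediction()
    out = {}
    for kind in ("pls", "pcr"):
        if kind == "pls":
            model, res = _pls_eval(
                cal.spectra, cal.density, pred.spectra, pred.density, config.n_folds, config.seed
            )
            out[kind] = res | {"model": model}
        else:
            k = calibrate.select_n_latent(
                cal.spectra, cal.density, n_folds=config.n_folds, seed=config.seed, kind="pcr"
            )
            model = calibrate.pcr_fit(cal.spectra, cal.density, k)
            folds = calibrate._fold_assignment(cal.density.size, config.n_folds, config.seed)
            cv_pred = np.empty_like(cal.density)
            for f in range(config.n_folds):
                test = folds == f
                kf = min(k, int((~test).sum()) - 1)
                cv_pred[test] = calibrate.pcr_fit(
                    cal.spectra[~test], cal.density[~test], kf
                ).predict(cal.spectra[test])
            out[kind] = {
                "calibration": compute_metrics(cal.density, model.predict(cal.spectra)),
                "cross_validation": compute_metrics(cal.density, cv_pred),
                "prediction": compute_metrics(pred.density, model.predict(pred.spectra)),
                "n_latent": k,
                "model": model,
            }
    return out


def run_combined(config: RunConfig) -> pd.DataFrame:
    """Signal (single-species) versus combined (pooled) PLS/PCR models on raw
    absorbance spectra, including cross-group prediction of the combined
    models (negative R2 left as reported)."""
    data = _load(config)
    # stratify the global split by (species, location) so every grouping has
    # consistent calibration/prediction membership
    pair = np.array(
        [f"{s}@{l}" for s, l in zip(data.species.astype(str), data.location.astype(str))],
        dtype=object,
    )
    keyed = replace(data, species=pair)
    split = _prepare(keyed, config)
    averaged = average_replicates(data, config.replicates_per_sample)
    assert np.array_equal(averaged.sample_id, split.sample_id)
    split.species = averaged.species  # restore true species labels
    species = split.species.astype(str)
    location = split.location.astype(str)
    groups: dict[str, np.ndarray] = {}
    for key in np.unique(pair):
        sp, loc = key.split("@")
        groups[f"signal:{sp}@{loc}"] = (species == sp) & (location == loc)
    if np.unique(location).size >= 2:
        for loc in np.unique(location):
            mask = location == loc
            if np.unique(species[mask]).size >= 2:
                groups[f"location:{loc}"] = mask
        for sp in np.unique(species):
            mask = species == sp
            if np.unique(location[mask]).size >= 2:
                groups[f"species-pooled:{sp}"] = mask
    if len(groups) >= 2:
        groups["combined:all"] = np.ones(split.n_samples, dtype=bool)

    rows = []
    for name, mask in groups.items():
        group = split.subset(mask)
        if group.n_samples < 8:
            logger.warning("grouping %s has %d samples; skipped", name, group.n_samples)
            continue
        results = _linear_eval(group, config)
        for kind, res in results.items():
            rows.append(
                {"grouping": name, "model": kind, "n": group.n_samples, "n_latent": res["n_latent"]}
                | _metrics_row("cal", res["calibration"])
                | _metrics_row("cv", res["cross_validation"])
                | _metrics_row("pred", res["prediction"])
            )
            if name.startswith(("combined", "location", "species-pooled")):
                # cross-group prediction: the pooled model applied to each
                # member species' prediction subset
                for sp in np.unique(group.species.astype(str)):
                    sub = group.subset(
                        (group.species.astype(str) == sp)
                        & (group.set_label == "prediction")
                    )
                    if sub.n_samples < 2:
                        continue
                    pm = compute_metrics(sub.density, res["model"].predict(sub.spectra))
                    rows.append(
                        {"grouping": name, "model": kind, "target_species": sp, "n": sub.n_samples}
                        | _metrics_row("pred", pm)
                    )
    table = pd.DataFrame(rows)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "combined_models.csv", index=False, float_format="%.6g")
    return table


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------


def _write_reports(reports: dict, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "fraction_calibration": config.fraction_calibration,
        "preprocessing": config.preprocessing,
        "selection_methods": list(config.selection_methods),
        "models": list(config.models),
    }
    for species, rep in reports.items():
        stem = out / species.replace("/", "_")
        stem.mkdir(exist_ok=True)
        if len(rep["wavelet_table"]):
            rep["wavelet_table"].to_csv(stem / "wavelet_search.csv", index=False, float_format="%.6g")
        rep["selection_table"].to_csv(stem / "selection_comparison.csv", index=False, float_format="%.6g")
        rep["model_table"].to_csv(stem / "model_metrics.csv", index=False, float_format="%.6g")
        rep["density_summary"].to_csv(stem / "density_summary.csv", index=False, float_format="%.6g")
        np.savetxt(stem / "selected_wavelengths_nm.txt", rep["selected_wavelengths"], fmt="%.1f")
        manifest.setdefault("species", {})[species] = {
            "wavelet": rep["wavelet_spec"].name,
            "level": rep["wavelet_spec"].level,
            "best_selector": rep["best_selector"],
            "reduction_percent": rep["reduction_percent"],
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
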