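"""End-to-end orchestration: simulate → preprocess → BIS → evaluate →
dose-response, with a manifest that suffices to reproduce every output.

A single root seed drives the run; each stochastic stage draws its own
sub-seed from (root seed, CRC32 of the stage name), so adding a stage
never perturbs the random streams of earlier ones. Identical
(config, seed) pairs produce byte-identical numeric outputs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bis import compute_bis, write_bis
from .config import RunConfig, run_config_to_dict, save_run_config
from .doseresponse import fit_hill, predict_mortality, survival_from_colonies
from .errors import FtirDoseError
from .evaluate import evaluate_windows, records_to_frame, summarize_windows
from .preprocess import preprocess_collection
from .spectra import write_spectra
from .synth import generate_design, simulate_clonogenic

log = logging.getLogger("ftirdose.pipeline")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig, output_dir) -> dict:
    """Execute every stage in order; returns the manifest dictionary."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = {}

    def _stage(name, fn):
        log.info("stage %s: start", name)
        try:
            result = fn()
        except FtirDoseError as exc:
            raise FtirDoseError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s: done", name)
        return result

    gen_config = replace(config.generator, seed=stage_seed(config.seed, "simulate"))

    def _simulate():
        collection = generate_design(gen_config)
        write_spectra(collection, out / "spectra.csv", dialect="wide")
        log.info("simulated %d spectra at %d concentrations",
                 len(collection), len(gen_config.concentrations))
        return collection

    raw = _stage("simulate", _simulate)

    def _preprocess():
        done = preprocess_collection(raw, config.preprocess)
        write_spectra(done, out / "preprocessed.csv", dialect="wide")
        return done

    pre = _stage("preprocess", _preprocess)

    def _bis():
        bis = compute_bis(pre)
        write_bis(bis, out / "bis.csv")
        log.info("BIS matrix: %d rows x %d wavenumbers", bis.n_rows, bis.X.shape[1])
        return bis

    _stage("bis", _bis)

    def _evaluate():
        records = evaluate_windows(
            pre, windows=config.windows, n_models=config.n_models,
            max_lv=config.max_lv, k_folds=config.k_folds,
            seed=stage_seed(config.seed, "evaluate"))
        frame = records_to_frame(records)
        frame.to_csv(out / "evaluation.csv", index=False)
        summary = summarize_windows(records)
        summary.to_csv(out / "evaluation_summary.csv", index=False)
        log.info("evaluation: %d records over %d windows",
                 len(records), len(config.windows))
        return summary

    _stage("evaluate", _evaluate)

    def _dose_response():
        rng = np.random.default_rng(stage_seed(config.seed, "clonogenic"))
        assay = simulate_clonogenic(gen_config.concentrations, config.n_cells,
                                    config.hill, rng)
        table = survival_from_colonies(assay)
        fit = fit_hill(table)
        curve_doses = np.linspace(0, max(gen_config.concentrations), 81)
        curve = pd.DataFrame({
            "dose": curve_doses,
            "predicted_mortality_pct": predict_mortality(fit, curve_doses),
        })
        result = pd.concat([
            pd.DataFrame({"key": ["ec50", "slope", "residual_ss", "converged"],
                          "value": [fit.ec50, fit.slope, fit.residual_ss,
                                    float(fit.converged)]}),
        ])
        with open(out / "dose_response.csv", "w", encoding="utf-8") as fh:
            result.to_csv(fh, index=False)
            fh.write("# predicted curve follows\n")
            curve.to_csv(fh, index=False)
        assay.to_csv(out / "clonogenic.csv", index=False)
        log.info("dose-response: LC50 %.3f ug/mL (slope %.2f, converged=%s)",
                 fit.ec50, fit.slope, fit.converged)
        return fit

    _stage("dose-response", _dose_response)

    for name in ("spectra.csv", "preprocessed.csv", "bis.csv", "evaluation.csv",
                 "evaluation_summary.csv", "dose_response.csv", "clonogenic.csv"):
        outputs[name] = str(out / name)

    manifest = {
        "package": "ftirdose",
        "version": __version__,
        "config": run_config_to_dict(config),
        "outputs": outputs,
    }
    import yaml

    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    save_run_config(config, out / "config.yaml")
    return manifest
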