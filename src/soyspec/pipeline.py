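"""End-to-end orchestration: simulate -> preprocess -> parameters ->
band search -> screening -> model grid -> metrics and figures."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .bandsearch import best_pairs_table, search_all_formulas
from .core import LAYERS, PipelineError, ParameterMatrix
from .estimation import ModelConfig, run_experiment_grid, split_modeling_validation
from .parameters import parameter_matrix
from .preprocess import first_derivative, savitzky_golay_smooth, validate_full_grid
from .screening import build_combinations, layer_target
from .simulate import GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed for a full reproducible run."""

    seed: int = 0
    spectra_path: str | None = None  # None -> simulate
    lnc_path: str | None = None
    sg_window: int = 9
    sg_order: int = 4
    sg_iterations: int = 1
    search_stride: int = 5
    alpha: float = 0.05
    split_fraction: float = 2.0 / 3.0
    layer_specific_pairs: bool = True
    figures: bool = False
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen_raw = raw.pop("generator", {})
        model_raw = raw.pop("model", {})
        cfg = cls(**raw)
        if gen_raw:
            means = gen_raw.pop("treatment_means", None)
            cfg.generator = dataclasses.replace(cfg.generator, **gen_raw)
            if means:
                cfg.generator.treatment_means = {
                    (k.split(",")[0], k.split(",")[1].strip().lower() == "true"): v
                    for k, v in means.items()
                }
        if model_raw:
            cfg.model = dataclasses.replace(cfg.model, **model_raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["treatment_means"] = {
            f"{lv},{inoc}": v
            for (lv, inoc), v in self.generator.treatment_means.items()
        }
        return d


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("[%s] started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise PipelineError(f"[{name}] {exc}") from exc
            logger.info("[%s] done in %.2f s", name, dt)

    return _Timer()


def run_all(config: RunConfig, outdir) -> Path:
    """Run the complete pipeline; write artifacts and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    config.generator.seed = config.seed
    config.model.seed = config.seed

    with _stage("ingest"):
        if config.spectra_path is None or config.lnc_path is None:
            spectra, lnc = generate_dataset(config.generator)
        else:
            spectra = sio.read_spectra(config.spectra_path)
            lnc = sio.read_lnc(config.lnc_path)
        validate_full_grid(spectra)
        sio.write_spectra(spectra, outdir / "spectra_raw.csv")
        sio.write_lnc(lnc, outdir / "lnc.csv")
        files += [outdir / "spectra_raw.csv", outdir / "lnc.csv"]

    with _stage("preprocess"):
        smoothed = savitzky_golay_smooth(
            spectra, config.sg_window, config.sg_order, config.sg_iterations
        )
        sio.write_spectra(smoothed, outdir / "spectra_smoothed.csv")
        files.append(outdir / "spectra_smoothed.csv")

    with _stage("band_search"):
        pairs_by_layer: dict[str, dict[str, tuple[int, int]]] = {}
        search_tables = []
        search_layers = LAYERS if config.layer_specific_pairs else ("CL",)
        for layer in search_layers:
            target = layer_target(lnc, layer, smoothed.sample_ids)
            results = search_all_formulas(
                smoothed, target, stride=config.search_stride
            )
            pairs_by_layer[layer] = {f: r.best_pair for f, r in results.items()}
            table = best_pairs_table(results)
            table.insert(0, "layer", layer)
            search_tables.append(table)
            if config.figures:
                for fid, res in results.items():
                    fig_path = outdir / f"heatmap_{layer}_{fid}.png"
                    sio.render_heatmap(res, fig_path)
                    files.append(fig_path)
        if not config.layer_specific_pairs:
            for layer in LAYERS:
                pairs_by_layer[layer] = pairs_by_layer["CL"]
        pairs_df = pd.concat(search_tables, ignore_index=True)
        pairs_df.to_csv(outdir / "best_pairs.csv", index=False)
        files.append(outdir / "best_pairs.csv")

    with _stage("parameters"):
        params_by_layer: dict[str, ParameterMatrix] = {}
        for layer in LAYERS:
            params_by_layer[layer] = parameter_matrix(
                smoothed, pairs_by_layer[layer]
            )
        params_by_layer["CL"].to_csv(outdir / "parameters_CL.csv")
        files.append(outdir / "parameters_CL.csv")

    with _stage("screening"):
        combos = build_combinations(params_by_layer, lnc, alpha=config.alpha)
        combos_path = outdir / "combinations.json"
        combos_path.write_text(
            json.dumps([c.to_record() for c in combos], indent=2)
        )
        files.append(combos_path)

    with _stage("model_grid"):
        split = split_modeling_validation(
            smoothed.sample_ids, config.split_fraction, config.seed
        )
        metrics, predictions = run_experiment_grid(
            params_by_layer, lnc, combos, split, config.model
        )
        metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.8g")
        predictions.to_csv(outdir / "predictions.csv", index=False,
                           float_format="%.8g")
        files += [outdir / "metrics.csv", outdir / "predictions.csv"]
        if config.figures:
            for (layer, combo, model), sub in predictions.groupby(
                ["layer", "combination", "model"]
            ):
                fig_path = outdir / f"scatter_{layer}_{combo}_{model}.png"
                sio.render_scatter(sub, fig_path, f"{layer} / {combo} / {model}")
                files.append(fig_path)

    with _stage("manifest"):
        sio.write_manifest(outdir, config.seed, config.to_dict(), files)
    return outdir
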