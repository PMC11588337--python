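"""Pipeline orchestration: simulate -> rank -> decode -> noisecorr.

A run is driven by a structured config (YAML or JSON mapping), expands a
single global seed into fixed per-stage child seeds, executes the
requested stages, and writes a manifest plus machine-readable JSON/CSV
reports mirroring the figure-level summaries: cumulative error CDFs
against chance, performance curves and pooled tau distributions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import AnalysisConfig, ResponseDataset, read_dataset, write_dataset
from .decoding import (
    chance_error_distribution,
    compare_to_chance,
    loo_decode,
    performance_curve,
)
from .noise_correlations import corr_shift_test, correlation_contribution
from .synthetic_data import sample_dataset, spec_presets
from .unit_stats import chi2_dependency, kruskal_wallis_tuning, neuronal_snr, rank_units

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "make_report", "stage_seeds"]

_STAGES = ("simulate", "rank", "decode", "noisecorr")


def stage_seeds(seed: int) -> dict[str, int]:
    """Expand one global seed into deterministic per-stage child seeds."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(_STAGES, children)
    }


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seeds: dict
    input_hash: str | None
    outputs: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_ALLOWED_TOP = {"seed", "out_dir", "data", "simulate", "rank", "decode", "noisecorr"}


def _validate_config(cfg: dict) -> list[str]:
    problems = []
    if not isinstance(cfg, dict):
        return ["config must be a mapping"]
    for key in cfg:
        if key not in _ALLOWED_TOP:
            problems.append(f"unknown config section {key!r}")
    if "data" in cfg and "simulate" in cfg:
        problems.append("provide either 'data' or 'simulate', not both")
    if "data" not in cfg and "simulate" not in cfg:
        problems.append("one of 'data' or 'simulate' is required")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        problems.append("'seed' must be an integer")
    if "data" in cfg and "path" not in (cfg["data"] or {}):
        problems.append("'data' section needs a 'path'")
    return problems


def _error_cdf(errors: np.ndarray, grid) -> dict:
    support = np.arange(0.0, grid.angles[-1] - grid.angles[0] + grid.step, grid.step)
    return {
        "support_deg": support.tolist(),
        "cdf": [float(np.mean(errors <= v + 1e-9)) for v in support],
    }


def make_report(stage_outputs: dict, grid=None) -> dict:
    """Consolidate stage outputs into one machine-readable report.

    Always includes the chance-model reference CDF; regeneration from the
    same stage outputs is idempotent.
    """
    if not stage_outputs:
        raise ValueError("need at least one stage output")
    from .data_model import DEFAULT_GRID

    grid = grid or DEFAULT_GRID
    chance = chance_error_distribution(grid)
    report: dict = {
        "chance": {
            "median_error_deg": chance.median,
            "mean_error_deg": chance.mean,
            "p_error_zero": chance.p_error(0.0),
            **{"cdf": _error_cdf(chance.errors, grid)},
        }
    }
    report.update(stage_outputs)
    return report


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the configured stages and write manifest plus reports.

    Config sections: ``data`` (path, schema, modality) or ``simulate``
    (preset, overrides); optional ``rank`` (alpha, bins), ``decode``
    (selector, classifier, sizes), ``noisecorr`` (top, surrogates).
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        cfg = dict(config)
    problems = _validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))

    seed = int(cfg.get("seed", 0))
    seeds = stage_seeds(seed)
    out = Path(out_dir or cfg.get("out_dir", "popazi_run"))
    out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(config=cfg, seed=seed, stage_seeds=seeds, input_hash=None)
    outputs: dict = {}

    # --- data stage -------------------------------------------------------
    if "simulate" in cfg:
        sim = cfg["simulate"] or {}
        spec = spec_presets(sim.get("preset", "ephys-like"), **(sim.get("overrides") or {}))
        dataset = sample_dataset(spec, seed=seeds["simulate"])
        data_path = out / "dataset.csv"
        write_dataset(dataset, data_path)
        manifest.outputs["dataset"] = str(data_path)
        logger.info("simulate: %d trials x %d units", dataset.n_trials, dataset.n_units)
    else:
        data = cfg["data"]
        data_path = Path(data["path"])
        dataset = read_dataset(
            data_path,
            schema=data.get("schema", "azimuth"),
            modality=data.get("modality", "imaging"),
        )
    manifest.input_hash = _sha256(data_path)

    # --- rank stage -------------------------------------------------------
    ranking = None
    if "rank" in cfg:
        rank_cfg = cfg["rank"] or {}
        alpha = float(rank_cfg.get("alpha", 0.05))
        bins = int(rank_cfg.get("bins", 10))
        chi2 = chi2_dependency(dataset, n_bins=bins)
        ranking = rank_units(chi2.pvalues, chi2.statistics, alpha=alpha)
        kw = kruskal_wallis_tuning(dataset, alpha=alpha)
        snr = neuronal_snr(dataset)
        outputs["rank"] = {
            "alpha": alpha,
            "n_bins": bins,
            "chi2_pvalues": chi2.pvalues,
            "chi2_statistics": chi2.statistics,
            "order": ranking.order,
            "fraction_chi2_significant": ranking.fraction_significant,
            "fraction_kw_tuned": kw.fraction_tuned,
            "snr_median": float(np.nanmedian(snr.defined))
            if snr.defined.size
            else None,
        }
        _dump(outputs["rank"], out / "ranking.json")
        manifest.outputs["rank"] = str(out / "ranking.json")
        logger.info(
            "rank: %.1f%% units chi2-significant (bins=%d)",
            100 * ranking.fraction_significant,
            bins,
        )

    # --- decode stage -----------------------------------------------------
    if "decode" in cfg:
        dec_cfg = cfg["decode"] or {}
        selector = dec_cfg.get("selector", "top_ranked:7")
        classifier = dec_cfg.get("classifier", "bayes")
        acfg = AnalysisConfig(seed=seeds["decode"])
        size_needed = (
            int(selector.split(":")[1]) if ":" in selector else 0
        )
        if size_needed > dataset.n_units:
            raise ValueError(
                f"decode: selector {selector!r} needs {size_needed} units but the "
                f"dataset has {dataset.n_units}"
            )
        res = loo_decode(dataset, selector=selector, classifier=classifier, config=acfg)
        chance = chance_error_distribution(dataset.grid)
        cmp_ = compare_to_chance(res.errors, chance)
        decode_out = {
            "selector": selector,
            "classifier": classifier,
            "kernel": acfg.kernel,
            "bandwidth": acfg.bandwidth,
            "median_error_deg": res.errors.median,
            "errors_deg": res.errors.errors,
            "predictions_deg": res.predictions,
            "true_labels_deg": res.true_labels,
            "ks_vs_chance": {
                "statistic": cmp_.ks_statistic,
                "pvalue": cmp_.pvalue,
                "direction": cmp_.direction,
            },
            "error_cdf": _error_cdf(res.errors.errors, dataset.grid),
        }
        sizes = dec_cfg.get("sizes")
        if sizes:
            family = selector.split(":")[0] if ":" in selector else "pca"
            curve = performance_curve(
                dataset, family, sizes, classifier=classifier, config=acfg
            )
            decode_out["performance_curve"] = {
                "sizes": curve.sizes,
                "medians_deg": curve.medians,
                "pvalues_adjusted": curve.pvalues_adjusted,
                "smallest_significant": curve.smallest_significant,
                "overfitting": curve.overfitting,
            }
        outputs["decode"] = decode_out
        _dump(decode_out, out / "decode.json")
        pd.DataFrame(
            {
                "true_deg": res.true_labels,
                "predicted_deg": res.predictions,
                "error_deg": res.errors.errors,
            }
        ).to_csv(out / "errors.csv", index=False)
        manifest.outputs["decode"] = str(out / "decode.json")
        logger.info(
            "decode: median error %.0f deg (selector=%s, kernel=%s)",
            res.errors.median,
            selector,
            acfg.kernel,
        )

    # --- noise-correlation stage -----------------------------------------
    if "noisecorr" in cfg:
        nc_cfg = cfg["noisecorr"] or {}
        top = int(nc_cfg.get("top", 7))
        n_surrogates = int(nc_cfg.get("surrogates", 20))
        acfg = AnalysisConfig(seed=seeds["noisecorr"], n_surrogates=n_surrogates)
        if ranking is None:
            chi2 = chi2_dependency(dataset)
            ranking = rank_units(chi2.pvalues, chi2.statistics)
        top_units = ranking.top(top)
        shift = corr_shift_test(dataset, n_surrogates, acfg, units=top_units)
        contrib = correlation_contribution(
            dataset,
            selector=f"top_ranked:{top}",
            n_surrogates=n_surrogates,
            config=acfg,
        )
        nc_out = {
            "top_units": top_units,
            "n_surrogates": n_surrogates,
            "pooled_tau": shift.real.pooled,
            "tau_median_real": shift.real_median,
            "tau_median_surrogate": shift.surrogate_median,
            "tau_shift_pvalue": shift.pvalue,
            "decoding": {
                "real_median_deg": contrib.real_median,
                "surrogate_median_deg": contrib.surrogate_median,
                "real_vs_surrogate_pvalue_adjusted": contrib.real_vs_surrogate_pvalue_adjusted,
                "direction": contrib.direction,
            },
        }
        outputs["noisecorr"] = nc_out
        _dump(nc_out, out / "noisecorr.json")
        manifest.outputs["noisecorr"] = str(out / "noisecorr.json")
        logger.info(
            "noisecorr: tau median %.3f vs surrogate %.3f; %s",
            shift.real_median,
            shift.surrogate_median,
            contrib.direction,
        )

    report = make_report(outputs, grid=dataset.grid) if outputs else None
    if report is not None:
        _dump(report, out / "report.json")
        manifest.outputs["report"] = str(out / "report.json")
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
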