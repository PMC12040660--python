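"""End-to-end orchestration and human-readable result artifacts.

`run_all` drives the whole pipeline — simulate (or load) a cohort,
preprocess, run the repeated-split protocol, extract VIP bands — and
writes a small set of text artifacts into an output directory, together
with a run manifest (config snapshot, seeds, version, input digests)
sufficient to re-run bit-identically.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import SpectralDataset
from .errors import ConfigurationError, DataError
from .evaluate import METRICS, ProtocolResult, band_report, run_protocol
from .preprocess import PreprocessConfig, preprocess_dataset
from .synth import CohortConfig, PeakSpec, generate_cohort

__all__ = ["table3_render", "run_all", "OUTPUT_FILES"]

#: artifacts every successful run produces
OUTPUT_FILES = (
    "per_iteration_metrics.csv",
    "aggregate_metrics.json",
    "mean_vip.csv",
    "band_report.json",
    "performance_table.txt",
)

_ROWS = (("train", "Training"), ("test", "Test"))
_COLS = (
    ("specificity", "Specificity"),
    ("sensitivity", "Sensitivity"),
    ("accuracy", "Accuracy"),
    ("auc", "ROC AUC"),
)


def table3_render(result: ProtocolResult) -> str:
    """Render the aggregate metrics as a Training/Test 'mean (min–max)' table."""
    if result.per_iteration.empty:
        raise DataError("cannot render a table from an empty protocol result")
    agg = result.aggregate
    header = ["Subsample"] + [f"{label} mean (min–max)" for _, label in _COLS]
    lines = ["\t".join(header)]
    for key, label in _ROWS:
        if key not in agg.index:
            raise DataError(f"protocol result lacks the {key!r} subsample")
        cells = [label]
        for metric, _ in _COLS:
            m = agg.loc[key, f"{metric}_mean"]
            lo = agg.loc[key, f"{metric}_min"]
            hi = agg.loc[key, f"{metric}_max"]
            cells.append(f"{m:.2f} ({lo:.2f}–{hi:.2f})")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cohort_config(section: dict) -> CohortConfig:
    kw = dict(section)
    if "shared_peaks" in kw:
        kw["shared_peaks"] = tuple(PeakSpec(**p) for p in kw["shared_peaks"])
    if "effect_bands" in kw:
        kw["effect_bands"] = tuple(tuple(b) for b in kw["effect_bands"])
    return CohortConfig(**kw)


def load_config(path: str | Path) -> dict:
    """Read a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("run configuration must be a mapping")
    return cfg


def mean_spectrum_plot(ds: SpectralDataset, path: Path) -> None:
    """Mean spectrum with a +/- sd band per group (illustrative)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for grp, color in (("Target", "tab:red"), ("Control", "tab:blue")):
        rows = ds.intensities[ds.group == grp]
        if not len(rows):
            continue
        m, s = rows.mean(axis=0), rows.std(axis=0, ddof=1)
        ax.plot(ds.axis, m, color=color, label=grp)
        ax.fill_between(ds.axis, m - s, m + s, color=color, alpha=0.25, lw=0)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("Intensity (a.u.)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def vip_plot(axis: np.ndarray, vip_values: np.ndarray, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.plot(axis, vip_values, color="black", lw=0.9)
    ax.axhline(1.0, color="tab:red", ls="--", lw=0.8)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("VIP")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_all(config: dict | str | Path, out_dir: str | Path, plots: bool = False) -> Path:
    """Simulate-or-load -> preprocess -> evaluate -> render, into ``out_dir``.

    The configuration mapping has sections ``simulate`` (CohortConfig
    fields) or ``spectra``/``meta`` file paths, plus optional
    ``preprocess`` (PreprocessConfig fields) and ``evaluate``
    (iterations, kfold, seed, vip_threshold, subject_vote) sections.
    Deterministic given the config: metric CSVs are byte-identical
    across runs.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": _jsonable(config),
        "inputs": {},
    }

    # -- stage: obtain spectra ----------------------------------------------
    try:
        if "spectra" in config or "meta" in config:
            for key in ("spectra", "meta"):
                if key not in config:
                    raise ConfigurationError(f"configuration key {key!r} is required")
            ds = SpectralDataset.from_csv(config["spectra"], config["meta"])
            for key in ("spectra", "meta"):
                manifest["inputs"][key] = _digest(Path(config[key]))
        elif "simulate" in config:
            cohort_cfg = _cohort_config(config["simulate"])
            ds = generate_cohort(cohort_cfg)
            ds.to_csv(out / "spectra_raw.csv", out / "meta.csv")
            manifest["inputs"]["spectra"] = _digest(out / "spectra_raw.csv")
            manifest["inputs"]["meta"] = _digest(out / "meta.csv")
        else:
            raise ConfigurationError(
                "configuration must provide either a 'simulate' section or "
                "'spectra' and 'meta' file paths"
            )
    except ConfigurationError:
        raise
    except Exception as exc:
        raise type(exc)(f"stage 'simulate/load': {exc}") from exc

    # -- stage: preprocess ---------------------------------------------------
    try:
        pp_cfg = PreprocessConfig(**config.get("preprocess", {}))
        pp = preprocess_dataset(ds, pp_cfg)
        pp.to_csv(out / "spectra_preprocessed.csv", out / "meta.csv")
    except Exception as exc:
        raise type(exc)(f"stage 'preprocess': {exc}") from exc

    # -- stage: evaluate -----------------------------------------------------
    ev = dict(config.get("evaluate", {}))
    seed = int(ev.get("seed", 0))
    try:
        result = run_protocol(
            pp,
            n_iterations=int(ev.get("iterations", 30)),
            k=int(ev.get("kfold", 7)),
            grid=ev.get("grid"),
            base_seed=seed,
            subject_vote=bool(ev.get("subject_vote", False)),
        )
        bands = band_report(result.mean_vip, float(ev.get("vip_threshold", 1.0)))
    except Exception as exc:
        raise type(exc)(f"stage 'evaluate': {exc}") from exc

    # -- stage: render -------------------------------------------------------
    result.per_iteration.to_csv(out / "per_iteration_metrics.csv", index=False)
    agg = {
        sub: {
            m: {
                s: float(result.aggregate.loc[sub, f"{m}_{s}"])
                for s in ("mean", "min", "max")
            }
            for m in METRICS
        }
        for sub in result.aggregate.index
    }
    (out / "aggregate_metrics.json").write_text(json.dumps(agg, indent=2) + "\n")
    pd.DataFrame(
        {"wavenumber": result.mean_vip.axis, "vip": result.mean_vip.vip}
    ).to_csv(out / "mean_vip.csv", index=False, float_format="%.17g")
    (out / "band_report.json").write_text(
        json.dumps(
            {"threshold": bands.threshold, "intervals": bands.by_height()}, indent=2
        )
        + "\n"
    )
    (out / "performance_table.txt").write_text(table3_render(result))
    manifest["seeds"] = {"evaluate": seed}
    manifest["chosen_components"] = result.chosen_A
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    if plots:
        mean_spectrum_plot(ds, out / "mean_spectrum.png")
        vip_plot(result.mean_vip.axis, result.mean_vip.vip, out / "vip_profile.png")
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
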