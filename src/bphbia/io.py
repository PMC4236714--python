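"""Result serialization: CSV tables and the run manifest.

Report rounding follows the convention of the published tables — euros to
whole units, percentages to two decimals, patient/event counts to whole
patients — while all internal arithmetic stays unrounded. Passing
``full_precision=True`` disables report rounding (used by test oracles).
Every run writes a manifest recording the configuration hash, seed,
package version and the list of assumption-flagged parameters, so that
(config, seed) determines every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import ModelConfig
from .pipeline import BudgetImpact, ScenarioResult, clinical_summary

__all__ = ["write_results", "config_hash", "log_assumptions"]

logger = logging.getLogger("bphbia")

_EURO_COLS = ("consultation_cost", "surgery_cost", "aur_cost", "drug_cost",
              "total_cost", "consultation_offset", "surgery_offset",
              "aur_offset", "drug_offset", "net_impact")
_COUNT_COLS = ("turps", "aur_episodes", "soc_turps", "soc_aur_episodes",
               "fdc_world_turps", "fdc_world_aur_episodes", "avoided_turps",
               "avoided_aur_episodes", "avoided_aur")
_PCT_COLS = ("percent_impact",)


def _rounded(df: pd.DataFrame, full_precision: bool) -> pd.DataFrame:
    if full_precision:
        return df
    out = df.copy()
    for c in out.columns:
        if c in _EURO_COLS or c in _COUNT_COLS:
            out[c] = out[c].astype(float).round(0).astype("int64")
        elif c in _PCT_COLS:
            out[c] = out[c].astype(float).round(2)
    return out


def config_hash(config: ModelConfig) -> str:
    """Stable SHA-256 of the canonicalised configuration document."""
    doc = yaml.safe_dump(config.model_dump(), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()


def log_assumptions(config: ModelConfig) -> None:
    """Log every assumption-flagged parameter at run start."""
    for name in config.assumed:
        logger.info("assumed parameter: %s", name)


def write_results(results: dict, out_dir: str | Path, config: ModelConfig,
                  full_precision: bool = False) -> list[Path]:
    """Write result CSVs and a run manifest to ``out_dir``.

    ``results`` maps sector name to a dict with keys ``soc``, ``fdc``
    (:class:`ScenarioResult`) and ``impact`` (:class:`BudgetImpact`).
    Writes ``clinical_results.csv`` (from the first sector — clinical
    events are sector-independent), ``cost_analysis_<sector>.csv`` and
    ``budget_impact_<sector>.csv`` per sector, and ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    first_sector = next(iter(results))
    r0 = results[first_sector]
    if r0["soc"].turps is not None:
        path = out_dir / "clinical_results.csv"
        _rounded(clinical_summary(r0["soc"], r0["fdc"]), full_precision).to_csv(
            path, index=False)
        written.append(path)

    for sector, r in results.items():
        cost = pd.concat([r["soc"].to_frame(), r["fdc"].to_frame()],
                         ignore_index=True)
        path = out_dir / f"cost_analysis_{sector}.csv"
        _rounded(cost, full_precision).to_csv(path, index=False)
        written.append(path)

        path = out_dir / f"budget_impact_{sector}.csv"
        _rounded(r["impact"].to_frame(), full_precision).to_csv(path, index=False)
        written.append(path)

    manifest = {
        "package": "bphbia",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config_hash(config),
        "assumed_parameters": list(config.assumed),
        "full_precision": full_precision,
        "files": [p.name for p in written],
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written
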