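"""Report writers and the single entry point tying config to outputs.

:func:`run_case` loads a configuration, runs the requested survival mode
and analyses, and writes delimited-text reports plus a JSON run manifest
(config digest, seed, outputs) so a run is reproducible and auditable.
The summary table mirrors the shape results are conventionally reported
in: per-arm cost, QALYs split by health state, increments, and the ICER
or dominance label.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .model import Comparison, CostEffectivenessModel, MODES
from .parameters import load_parameters
from .survival import ConditionalSurvivalTable, LifeTable
from .uncertainty import (
    DEFAULT_WTP_GRID,
    ceac,
    one_way_dsa,
    run_psa,
    tornado_frame,
)

__all__ = ["RunManifest", "summary_frame", "run_case"]

log = logging.getLogger(__name__)

ANALYSES = ("deterministic", "dsa", "psa")


def summary_frame(comp: Comparison) -> pd.DataFrame:
    """Two-row summary: cost, QALYs by state, increments, ICER."""
    inc = comp.incremental
    rows = [
        {
            "strategy": "Pembrolizumab",
            "cost_usd": round(comp.monotherapy.cost),
            "qalys_pfs": round(comp.monotherapy.qalys_pfs, 2),
            "qalys_pd": round(comp.monotherapy.qalys_pd, 2),
            "qalys_total": round(comp.monotherapy.qalys, 2),
            "incremental_cost_usd": None,
            "incremental_qalys": None,
            "icer_usd_per_qaly": None,
        },
        {
            "strategy": "Pembrolizumab+chemotherapy",
            "cost_usd": round(comp.combination.cost),
            "qalys_pfs": round(comp.combination.qalys_pfs, 2),
            "qalys_pd": round(comp.combination.qalys_pd, 2),
            "qalys_total": round(comp.combination.qalys, 2),
            "incremental_cost_usd": round(inc.delta_cost),
            "incremental_qalys": round(inc.delta_qalys, 2),
            "icer_usd_per_qaly": inc.label,
        },
    ]
    return pd.DataFrame(rows)


@dataclass
class RunManifest:
    config_path: str
    config_digest: str
    mode: str
    analyses: tuple[str, ...]
    seed: int
    version: str
    timestamp: str
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2))

    def check(self) -> None:
        missing = [o for o in self.outputs if not Path(o).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")


def run_case(
    config_path: str | Path,
    mode: str = "base",
    analyses: Sequence[str] = ("deterministic",),
    out_dir: str | Path = "pembrocea_out",
    seed: int = 0,
    registry_path: Optional[str | Path] = None,
    life_table_path: Optional[str | Path] = None,
    horizon: int = 240,
    discount_rate: Optional[float] = None,
    psa_iterations: int = 10_000,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
) -> RunManifest:
    """Run one configuration end to end and write reports.

    Returns the manifest; raises on invalid mode/analyses or config
    validation failure so callers (and the CLI) can exit non-zero.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    bad = [a for a in analyses if a not in ANALYSES]
    if bad:
        raise ValueError(f"unknown analyses {bad}; choose from {ANALYSES}")

    config_path = Path(config_path)
    params = load_parameters(config_path)
    registry = (
        ConditionalSurvivalTable.from_tsv(registry_path) if registry_path else None
    )
    life_table = LifeTable.from_tsv(life_table_path) if life_table_path else None
    model = CostEffectivenessModel(
        params, mode=mode, registry=registry, life_table=life_table, horizon=horizon
    )
    overrides = {"discount_rate": discount_rate} if discount_rate is not None else None

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_path=str(config_path),
        config_digest=hashlib.sha256(config_path.read_bytes()).hexdigest(),
        mode=mode,
        analyses=tuple(analyses),
        seed=seed,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )

    if "deterministic" in analyses:
        comp = model.run(overrides)
        path = out / f"summary_{params.histology}_{mode}.tsv"
        summary_frame(comp).to_csv(path, sep="\t", index=False)
        manifest.outputs.append(str(path))
        log.info("deterministic summary written to %s", path)
    if "dsa" in analyses:
        entries = one_way_dsa(model)
        path = out / f"tornado_{params.histology}_{mode}.tsv"
        tornado_frame(entries).to_csv(path, sep="\t", index=False)
        manifest.outputs.append(str(path))
    if "psa" in analyses:
        psa = run_psa(model, n_iter=psa_iterations, seed=seed)
        samples_path = out / f"psa_samples_{params.histology}_{mode}.tsv"
        psa.frame().to_csv(samples_path, sep="\t", index=False)
        ceac_path = out / f"ceac_{params.histology}_{mode}.tsv"
        ceac(psa, wtp_grid).to_csv(ceac_path, sep="\t", index=False)
        manifest.outputs += [str(samples_path), str(ceac_path)]
        if psa.n_failed:
            log.warning("%d PSA iterations failed and were excluded", psa.n_failed)

    manifest_path = out / f"manifest_{params.histology}_{mode}.json"
    manifest.outputs.append(str(manifest_path))
    manifest.write(manifest_path)
    manifest.check()
    return manifest
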