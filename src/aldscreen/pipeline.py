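"""Stage orchestration: reproducible runs writing auditable artifacts.

Every output CSV starts with a header comment carrying the tool version,
the configuration hash and the gate parameters; a JSON-lines log records
per-stage counts. All randomness flows from the single configured seed.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

import aldscreen
from aldscreen import gating, screen, spheres, synth
from aldscreen.config import RunConfig
from aldscreen.wells import load_platemap


def _audit_header(config: RunConfig, gate: gating.GateThreshold | None = None) -> str:
    parts = [f"aldscreen v{aldscreen.__version__}", f"config_hash={config.config_hash()}",
             f"seed={config.seed}", f"gate_k={config.gate_k}"]
    if gate is not None:
        parts.append(
            f"gate: mean={gate.mean_deab:.6g} sd={gate.sd_deab:.6g} "
            f"threshold={gate.threshold:.6g} n_control={gate.n_control_cells}"
        )
    return "# " + " | ".join(parts) + "\n"


def write_csv(df: pd.DataFrame, path: Path, config: RunConfig,
              gate: gating.GateThreshold | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_audit_header(config, gate))
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


class RunLog:
    """Structured JSON-lines log of per-stage counts."""

    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, **fields) -> None:
        rec = {"t": round(time.time(), 3), "stage": stage, **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def default_demo_layout() -> tuple[dict[str, str], dict[str, tuple[str, float]]]:
    """A demo 384-well layout: column 1 DMSO, column 2 DEAB, rest samples."""
    layout: dict[str, str] = {}
    compounds: dict[str, tuple[str, float]] = {}
    from aldscreen.wells import ROWS_384, N_COLS_384

    for r in ROWS_384:
        layout[f"{r}01"] = "dmso"
        layout[f"{r}02"] = "deab"
        for c in range(3, N_COLS_384 + 1):
            well = f"{r}{c:02d}"
            layout[well] = "sample"
            compounds[well] = (f"CPD{r}{c:02d}", 10.0)
    return layout, compounds


def run_synth(config: RunConfig, out_dir: Path, log: RunLog) -> None:
    """Generate a demo synthetic plate: cell table CSV, platemap, ground truth."""
    layout, compounds = default_demo_layout()
    spec = synth.PlateSpec(
        layout=layout,
        compounds=compounds,
        base_mixture=synth.MixtureSpec(n_cells=2000),
        seed=config.seed,
    )
    tables, platemap, truth = synth.gen_plate_dataset(spec)
    cells = pd.concat(tables.values(), ignore_index=True)
    write_csv(cells, out_dir / "cells.csv", config)
    write_csv(platemap, out_dir / "platemap.csv", config)
    (out_dir / "ground_truth.json").write_text(
        json.dumps({"per_well_fraction": truth.per_well_fraction}, indent=1)
    )
    log.event("synth", n_wells=len(tables), n_cells=int(len(cells)))


def run_gate(config: RunConfig, out_dir: Path, log: RunLog,
             cells_path: Path | None = None,
             platemap_path: Path | None = None) -> pd.DataFrame:
    """Gate a plate's cell tables against its pooled DEAB control wells."""
    cells = read_csv(cells_path or out_dir / "cells.csv")
    platemap = load_platemap(platemap_path or out_dir / "platemap.csv")
    control_wells = platemap.index[platemap["role"] == config.full_effect_role]
    control = cells[cells["well"].isin(control_wells)]
    gate = gating.compute_gate_threshold(
        control["intensity"].to_numpy(),
        k=config.gate_k,
        min_cells=config.gate_min_cells,
        source_wells=tuple(control_wells),
    )
    tables = {w: g for w, g in cells.groupby("well")}
    summary = screen.summarize_wells(tables, platemap, gate)
    write_csv(summary, out_dir / "well_summary.csv", config, gate)
    log.event("gate", threshold=gate.threshold, n_wells=len(summary))
    return summary


def run_spheres(config: RunConfig, out_dir: Path, log: RunLog,
                image_path: Path, n_seeded: int = 200) -> pd.DataFrame:
    """Detect tumorspheres in a Day-7 image and score TFC."""
    img = tifffile.imread(image_path).astype(float)
    records = spheres.detect_spheres(
        img, config.pixel_size, config.sphere_d_min, config.sphere_d_max,
        config.sphere_sf_min,
    )
    tfc = spheres.compute_tfc(records, n_seeded=n_seeded)
    df = pd.DataFrame([vars(r) for r in records])
    write_csv(df, out_dir / "spheres.csv", config)
    (out_dir / "tfc.json").write_text(json.dumps(vars(tfc), indent=1))
    log.event("spheres", n_objects=len(records), n_pass=tfc.n_spheres_pass, tfc=tfc.tfc)
    return df


def run_screen(config: RunConfig, out_dir: Path, log: RunLog,
               summary_path: Path | None = None,
               followup_path: Path | None = None) -> screen.PlateResult:
    """Apply masking, normalization, hit calling and plate QC to a well summary."""
    summary = read_csv(summary_path or out_dir / "well_summary.csv")
    cfg = screen.NormalizationConfig(
        neutral_role=config.neutral_role,
        full_effect_role=config.full_effect_role,
        aggregation=config.control_aggregation,  # type: ignore[arg-type]
    )
    followup = read_csv(followup_path) if followup_path else None
    result = screen.analyze_plate(
        summary, cfg,
        reduction_threshold=config.hit_reduction_pct,
        mask_fraction=config.mask_fraction,
        followup=followup,
        t_fast=config.t_fast,
        t_rebound=config.t_rebound,
    )
    write_csv(result.wells, out_dir / "screen_result.csv", config)
    qc = {
        "rz_prime": result.rz_prime,
        "signal_to_background": result.s_b,
        "n_masked": result.n_masked,
        "n_hits": result.n_hits,
        "config": config.model_dump(),
    }
    (out_dir / "plate_qc.json").write_text(json.dumps(qc, indent=1))
    log.event("screen", **{k: v for k, v in qc.items() if k != "config"})
    return result


def run_pipeline(config: RunConfig, command: str, out_dir: str | Path,
                 **kwargs) -> None:
    """Dispatch one stage (synth|gate|screen|all) with fail-fast input checks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(out / "run_log.jsonl")
    log.event("start", command=command, seed=config.seed,
              config_hash=config.config_hash())
    if command == "synth":
        run_synth(config, out, log)
    elif command == "gate":
        run_gate(config, out, log, **kwargs)
    elif command == "screen":
        run_screen(config, out, log, **kwargs)
    elif command == "all":
        run_synth(config, out, log)
        run_gate(config, out, log)
        run_screen(config, out, log)
    else:
        raise ValueError(f"unknown command {command!r}")
    log.event("done", command=command)
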