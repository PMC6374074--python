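"""CSV/TSV/JSON readers and writers for titrations, SEC runs and results.

Dialects (all comma-separated, UTF-8, header required):

* titration CSV: ``ligand, analyte, channel, conc_uM, response_RU`` —
  one series per (ligand, analyte, channel) group;
* SEC runs CSV: ``load_conc_uM`` plus either ``peak_volume_mL`` or
  ``trace_file`` (path to a trace CSV, relative to the runs file);
* trace CSV: ``volume_mL, absorbance_mAU``.

Result writers emit JSON plus a TSV mirror; every artifact carries a
provenance block (package version, seed, configuration).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .energetics import PanelRow
from .errors import DataError
from .sec import SECFitResult, SECRun
from .spr import AffinityFit, TitrationSeries

__all__ = [
    "read_titrations",
    "write_titrations",
    "read_trace",
    "read_sec_runs",
    "write_sec_runs",
    "fits_to_frame",
    "write_fits",
    "write_sec_result",
    "panel_to_frame",
    "write_panel",
    "provenance_block",
]

TITRATION_COLUMNS = ["ligand", "analyte", "channel", "conc_uM", "response_RU"]
TRACE_COLUMNS = ["volume_mL", "absorbance_mAU"]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_titrations(path) -> list[TitrationSeries]:
    """Read a titration CSV into one series per (ligand, analyte, channel)."""
    df = pd.read_csv(path)
    _require_columns(df, TITRATION_COLUMNS[:2] + TITRATION_COLUMNS[3:], path)
    if "channel" not in df.columns:
        df["channel"] = ""
    out = []
    for (lig, ana, chan), grp in df.groupby(
        ["ligand", "analyte", "channel"], sort=True
    ):
        out.append(
            TitrationSeries(
                ligand=str(lig),
                analyte=str(ana),
                channel=str(chan),
                concentrations=grp["conc_uM"].to_numpy(float),
                responses=grp["response_RU"].to_numpy(float),
            )
        )
    return out


def write_titrations(series: Iterable[TitrationSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "ligand": s.ligand,
                "analyte": s.analyte,
                "channel": s.channel,
                "conc_uM": s.concentrations,
                "response_RU": s.responses,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    return df["volume_mL"].to_numpy(float), df["absorbance_mAU"].to_numpy(float)


def read_sec_runs(path) -> list[SECRun]:
    """Read an SEC runs CSV; trace_file paths resolve relative to the CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["load_conc_uM"], path)
    if "peak_volume_mL" not in df.columns and "trace_file" not in df.columns:
        raise DataError(
            f"{path}: need either a peak_volume_mL or a trace_file column"
        )
    runs = []
    for _, row in df.iterrows():
        peak = row.get("peak_volume_mL")
        trace = None
        if pd.isna(peak) if peak is not None else True:
            peak = None
        if peak is None:
            tf = row.get("trace_file")
            if tf is None or pd.isna(tf):
                raise DataError(
                    f"{path}: row with load {row['load_conc_uM']} has neither "
                    "peak_volume_mL nor trace_file"
                )
            trace = read_trace(path.parent / str(tf))
        runs.append(
            SECRun(
                load_conc=float(row["load_conc_uM"]),
                trace=trace,
                peak_volume=float(peak) if peak is not None else None,
            )
        )
    return runs


def write_sec_runs(runs: Iterable[SECRun], out_dir, stem: str = "sec") -> Path:
    """Write runs + any traces under ``out_dir``; returns the runs CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, run in enumerate(runs):
        rec: dict[str, Any] = {"load_conc_uM": run.load_conc}
        if run.trace is not None:
            tf = f"{stem}_trace_{i:02d}.csv"
            pd.DataFrame(
                {"volume_mL": run.trace[0], "absorbance_mAU": run.trace[1]}
            ).to_csv(out_dir / tf, index=False)
            rec["trace_file"] = tf
        if run.peak_volume is not None:
            rec["peak_volume_mL"] = run.peak_volume
        rows.append(rec)
    runs_path = out_dir / f"{stem}_runs.csv"
    pd.DataFrame(rows).to_csv(runs_path, index=False)
    return runs_path


def fits_to_frame(fits: Iterable[AffinityFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ligand": f.ligand,
                "analyte": f.analyte,
                "channel": f.channel,
                "model": f.model,
                "kd_uM": f.kd_hat,
                "ci_low_uM": f.ci_low,
                "ci_high_uM": f.ci_high,
                "rmax_RU": f.rmax_hat,
                "rmax_constrained": f.rmax_constrained,
                "r_squared": f.r_squared,
                "n_points": f.n_points,
            }
            for f in fits
        ]
    )


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_fits(fits: list[AffinityFit], out_dir, provenance: dict, stem="spr_fits"):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = fits_to_frame(fits)
    frame.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
    payload = {
        "provenance": provenance,
        "fits": frame.to_dict(orient="records"),
    }
    (out_dir / f"{stem}.json").write_text(
        json.dumps(payload, indent=2, default=_json_default)
    )


def write_sec_result(result: SECFitResult, out_dir, provenance: dict, stem="sec_fit"):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_run = pd.DataFrame([dataclasses.asdict(r) for r in result.per_run])
    per_run.to_csv(out_dir / f"{stem}_runs.tsv", sep="\t", index=False)
    payload = {
        "provenance": provenance,
        "kd_uM": result.kd_hat,
        "ci_low_uM": result.ci_low,
        "ci_high_uM": result.ci_high,
        "residual_norm": result.residual_norm,
        "n_runs": result.n_runs,
        "per_run": per_run.to_dict(orient="records"),
    }
    (out_dir / f"{stem}.json").write_text(
        json.dumps(payload, indent=2, default=_json_default)
    )


def panel_to_frame(rows: Iterable[PanelRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct": r.construct,
                "partner": r.partner,
                "kd_wt_uM": r.kd_wt,
                "kd_mut_uM": r.kd_mut,
                "fold_change": r.fold_change,
                "ddg_kcal_mol": r.ddg,
                "censored": r.censored,
            }
            for r in rows
        ]
    )


def write_panel(rows: list[PanelRow], out_dir, provenance: dict, stem="panel"):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = panel_to_frame(rows)
    frame.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
    payload = {"provenance": provenance, "panel": frame.to_dict(orient="records")}
    (out_dir / f"{stem}.json").write_text(
        json.dumps(payload, indent=2, default=_json_default)
    )


def provenance_block(seed: int | None, config: dict | None = None) -> dict:
    from . import __version__

    return {
        "package": "dimerfit",
        "version": __version__,
        "seed": seed,
        "config": config or {},
    }
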