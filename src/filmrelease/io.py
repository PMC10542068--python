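"""File formats and run configuration.

CSV dialect: comma-separated, UTF-8, header required, "." decimal separator.
Release curves travel as long-format tables with columns ``time_h`` and
``conc_mg_gae_per_kg`` plus optional grouping columns ``simulant``,
``temperature_C`` and ``replicate``.  Times are hours on disk and seconds in
memory.  Every output file is accompanied (or annotated) with the seed and a
hash of the options that produced it, so a pipeline run is reproducible and
auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, ReleaseCurve

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "read_release_csv",
    "write_curves_csv",
    "write_fit_report",
]

REQUIRED_COLUMNS = ("time_h", "conc_mg_gae_per_kg")
GROUP_COLUMNS = ("simulant", "temperature_C", "replicate")


@dataclass
class RunConfig:
    """Options for a simulate/fit pipeline run."""

    # geometry
    thickness_m: float = 1e-4
    exposure: str = "two_sided"
    volume_film_m3: float = 2e-7
    volume_simulant_m3: float = 1e-4
    # partition: exactly one of the two
    K_FS: float | None = None
    alpha: float | None = None
    # fitting options
    n_roots: int = 12
    plateau_points: int = 3
    model: str | None = None
    # synthetic options
    scenarios: list[str] = field(default_factory=list)
    noise_cv: float | None = None
    n_replicates: int | None = None
    seed: int = 0
    # paths
    output_dir: str = "."

    def __post_init__(self) -> None:
        if (self.K_FS is None) == (self.alpha is None):
            raise ValueError("exactly one of K_FS or alpha must be supplied")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(options: dict) -> str:
    """Short stable hash of an options mapping."""
    canon = json.dumps(options, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:12]


def _fail(path, row: int, message: str) -> None:
    raise ValueError(f"{path}: row {row}: {message}")


def read_release_csv(path) -> list[ReleaseCurve]:
    """Read release curves from a long-format CSV.

    One curve is returned per distinct combination of the optional grouping
    columns; rows are sorted by time within each group.  Non-numeric cells,
    negative concentrations and duplicate (group, time) rows are rejected
    with the offending row number (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in REQUIRED_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            _fail(path, int(bad[0]) + 1, f"non-numeric value in column {col!r}")
        df[col] = numeric
    neg = df.index[df["conc_mg_gae_per_kg"] < 0]
    if len(neg):
        _fail(path, int(neg[0]) + 1, "negative concentration")

    groups = [c for c in GROUP_COLUMNS if c in df.columns]
    curves: list[ReleaseCurve] = []
    grouped = df.groupby(groups, sort=True, dropna=False) if groups else [((), df)]
    for key, sub in grouped:
        dup = sub.index[sub["time_h"].duplicated()]
        if len(dup):
            _fail(path, int(dup[0]) + 1, "duplicate timepoint within a group")
        sub = sub.sort_values("time_h")
        key = key if isinstance(key, tuple) else (key,)
        meta = dict(zip(groups, key))
        temp = meta.get("temperature_C")
        if temp is not None and pd.isna(temp):
            temp = None
        rep = meta.get("replicate")
        curves.append(
            ReleaseCurve(
                times=sub["time_h"].to_numpy() * 3600.0,
                concentrations=sub["conc_mg_gae_per_kg"].to_numpy(),
                simulant_label=str(meta.get("simulant", "")),
                temperature_label="" if temp is None else f"{temp:g}C",
                replicate=None if rep is None or pd.isna(rep) else int(rep),
            )
        )
    return curves


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def write_curves_csv(curves: list[ReleaseCurve], path, manifest: dict | None = None) -> None:
    """Write curves as long-format CSV; optionally a JSON manifest sidecar.

    The manifest records the options and seeds that generated the curves
    plus a hash of those options; it is written next to the CSV with the
    suffix ``.manifest.json``.
    """
    if not curves:
        raise ValueError("no curves to write")
    rows = []
    for c in curves:
        for t, conc in zip(c.times, c.concentrations):
            rows.append(
                {
                    "time_h": _fmt(t / 3600.0),
                    "conc_mg_gae_per_kg": _fmt(conc),
                    "simulant": c.simulant_label,
                    "temperature_C": c.temperature_label.rstrip("C"),
                    "replicate": "" if c.replicate is None else str(c.replicate),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    if manifest is not None:
        manifest = dict(manifest)
        manifest["config_sha256_12"] = config_hash(manifest)
        side = Path(path).with_suffix(".manifest.json")
        side.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", "utf-8")


def write_fit_report(
    results: list[tuple[ReleaseCurve, FitResult]],
    path,
    options: dict | None = None,
) -> pd.DataFrame:
    """Write a fit summary table (CSV) plus a JSON sidecar of run metadata.

    Results are aggregated per (simulant, temperature) group: D is reported
    as mean +/- sample SD over replicates in units of 1e-14 m^2/s, alpha in
    units of 1e-4, together with the mean R^2 and the model variant used.
    Returns the summary as a DataFrame.
    """
    if not results:
        raise ValueError("no fit results to report")
    rows = []
    for curve, fit in results:
        rows.append(
            {
                "simulant": curve.simulant_label,
                "temperature_C": curve.temperature_label.rstrip("C"),
                "replicate": curve.replicate,
                "D_1e14_m2_s": fit.D_hat * 1e14,
                "alpha_1e4": fit.alpha_used * 1e4,
                "model": fit.model_used.value,
                "r_squared": fit.r_squared,
                "converged": fit.converged,
            }
        )
    per_rep = pd.DataFrame(rows)
    agg = (
        per_rep.groupby(["simulant", "temperature_C"], sort=True)
        .agg(
            n=("D_1e14_m2_s", "size"),
            D_mean_1e14=("D_1e14_m2_s", "mean"),
            D_sd_1e14=("D_1e14_m2_s", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            alpha_mean_1e4=("alpha_1e4", "mean"),
            r_squared_mean=("r_squared", "mean"),
            model=("model", "first"),
            all_converged=("converged", "all"),
        )
        .reset_index()
    )
    out = agg.copy()
    for col in ("D_mean_1e14", "D_sd_1e14", "alpha_mean_1e4", "r_squared_mean"):
        out[col] = out[col].map(_fmt)
    out.to_csv(path, index=False)
    meta = {"options": options or {}}
    meta["config_sha256_12"] = config_hash(meta["options"])
    Path(path).with_suffix(".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n", "utf-8"
    )
    return agg
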