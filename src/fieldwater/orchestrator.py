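"""Make-like incremental execution of the pipeline stages.

Each :class:`Stage` declares the external files it reads, the configuration
keys it depends on, and its upstream stages.  A stage's fingerprint is a
SHA-256 digest over (its code-version tag, the content digests of its
declared input files, its declared parameter values, and the fingerprints
of its upstream stages).  A stage re-executes exactly when its fingerprint
differs from the cached one — content decides staleness, not modification
times, so copied-but-identical files never trigger work, and a change
anywhere propagates to every DAG-descendant through the fingerprint chain.

The cache is a single JSON manifest beside the stage outputs, updated
atomically after each successful stage; an advisory lock file guards
against concurrent runs in the single-user lab setting this serves.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .config import TrialConfig
from .errors import FieldWaterError, GraphCycleError, StageFailedError

logger = logging.getLogger(__name__)

MANIFEST_NAME = "fingerprints.json"
LOCK_NAME = ".fieldwater.lock"


@dataclass
class StageContext:
    input_dir: Path
    work_dir: Path
    config: TrialConfig


@dataclass(frozen=True)
class Stage:
    """One node of the pipeline DAG."""

    name: str
    operation: Callable[[StageContext], None]
    upstream: Tuple[str, ...] = ()
    input_files: Tuple[str, ...] = ()  # relative to the input directory
    params_subset: Tuple[str, ...] = ()  # TrialConfig keys this stage reads
    code_version: str = "1"


def plan(stages: Sequence[Stage]) -> List[str]:
    """Deterministic topological order (Kahn's algorithm, name tie-break)."""
    by_name = {s.name: s for s in stages}
    for s in stages:
        for up in s.upstream:
            if up not in by_name:
                raise FieldWaterError(f"stage '{s.name}' references unknown upstream '{up}'")
    indeg = {s.name: len(set(s.upstream)) for s in stages}
    downstream: Dict[str, List[str]] = {s.name: [] for s in stages}
    for s in stages:
        for up in set(s.upstream):
            downstream[up].append(s.name)
    ready = sorted(n for n, d in indeg.items() if d == 0)
    order: List[str] = []
    while ready:
        name = ready.pop(0)
        order.append(name)
        changed = False
        for down in downstream[name]:
            indeg[down] -= 1
            if indeg[down] == 0:
                ready.append(down)
                changed = True
        if changed:
            ready.sort()
    if len(order) != len(stages):
        raise GraphCycleError([n for n, d in indeg.items() if d > 0])
    return order


def _file_digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def fingerprint(stage: Stage, ctx: StageContext, upstream_fps: Dict[str, str]) -> str:
    """Content fingerprint of a stage; deterministic given identical inputs."""
    payload = {
        "stage": stage.name,
        "code_version": stage.code_version,
        "inputs": {},
        "params": ctx.config.params_subset(stage.params_subset),
        "upstream": {up: upstream_fps[up] for up in sorted(set(stage.upstream))},
    }
    for rel in sorted(stage.input_files):
        path = ctx.input_dir / rel
        if not path.exists():
            raise FieldWaterError(f"stage '{stage.name}': declared input missing: {path}")
        payload["inputs"][rel] = _file_digest(path)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _load_manifest(path: Path) -> Dict[str, str]:
    if path.exists():
        return json.loads(path.read_text())
    return {}


def _save_manifest(path: Path, manifest: Dict[str, str]) -> None:
    tmp = path.with_suffix(".tmp")
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    os.replace(tmp, path)


@dataclass
class RunReport:
    order: List[str]
    status: Dict[str, str]  # executed | skipped | failed | blocked
    timings_s: Dict[str, float] = field(default_factory=dict)

    @property
    def executed(self) -> List[str]:
        return [n for n in self.order if self.status[n] == "executed"]

    @property
    def ok(self) -> bool:
        return all(v in ("executed", "skipped") for v in self.status.values())


def run(
    stages: Sequence[Stage],
    ctx: StageContext,
    force: bool = False,
    dry_run: bool = False,
) -> RunReport:
    """Execute stale stages in dependency order.

    ``force`` re-executes everything; ``dry_run`` reports what would execute
    without running anything or touching the cache.  On a stage failure the
    run halts: downstream stages are reported ``blocked`` and the failed
    stage's cache entry is left untouched.
    """
    order = plan(stages)
    by_name = {s.name: s for s in stages}
    ctx.work_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = ctx.work_dir / MANIFEST_NAME
    manifest = _load_manifest(manifest_path)

    fps: Dict[str, str] = {}
    status: Dict[str, str] = {}
    timings: Dict[str, float] = {}

    lock = ctx.work_dir / LOCK_NAME
    if not dry_run:
        try:
            fd = os.open(lock, os.O_CREAT | os.O_EXCL | os.O_WRONLY)
            os.close(fd)
        except FileExistsError:
            raise FieldWaterError(f"another run appears active (lock file {lock} exists)")
    try:
        failed = False
        for name in order:
            stage = by_name[name]
            if failed:
                status[name] = "blocked"
                continue
            fp = fingerprint(stage, ctx, fps)
            fps[name] = fp
            stale = force or manifest.get(name) != fp
            if not stale:
                status[name] = "skipped"
                logger.info("stage %-16s skipped (up to date)", name)
                continue
            if dry_run:
                status[name] = "executed"
                continue
            t0 = time.perf_counter()
            try:
                stage.operation(ctx)
            except Exception as exc:  # halt; leave cache for this stage untouched
                status[name] = "failed"
                failed = True
                logger.error("stage %-16s FAILED: %r", name, exc)
                continue
            dt = time.perf_counter() - t0
            timings[name] = dt
            manifest[name] = fp
            _save_manifest(manifest_path, manifest)
            status[name] = "executed"
            logger.info("stage %-16s executed in %.3f s", name, dt)
    finally:
        if not dry_run and lock.exists():
            lock.unlink()
    return RunReport(order=order, status=status, timings_s=timings)


def status(stages: Sequence[Stage], ctx: StageContext) -> RunReport:
    """What a run would execute, without executing anything."""
    return run(stages, ctx, dry_run=True)


# ---------------------------------------------------------------------------
# The standard pipeline bound as stages
# ---------------------------------------------------------------------------


def _op_canopy(ctx: StageContext) -> None:
    from .canopy import interpolate_all_plots, standardise_ndvi
    from .io import read_calendar, read_canopy_obs, read_weather

    weather = read_weather(ctx.input_dir / "weather.csv")
    obs = standardise_ndvi(read_canopy_obs(ctx.input_dir / "ndvi.csv"))
    calendar = read_calendar(ctx.input_dir / "calendar.csv")
    daily = interpolate_all_plots(obs, calendar, ctx.config, pd.DatetimeIndex(weather["date"]))
    _write_csv(daily, ctx.work_dir / "canopy_daily.csv")


def _op_storage(ctx: StageContext) -> None:
    from .io import read_probe
    from .soil import storage_table

    probe = read_probe(ctx.input_dir / "probe.csv")
    _write_csv(storage_table(probe, ctx.config), ctx.work_dir / "storage.csv")


def _op_field_capacity(ctx: StageContext) -> None:
    from .io import read_calendar
    from .pipeline import fallow_storages
    from .soil import estimate_field_capacity

    storages = _read_csv(ctx.work_dir / "storage.csv")
    calendar = read_calendar(ctx.input_dir / "calendar.csv")
    rows = []
    for plot in sorted(storages["plot_id"].unique()):
        fc = estimate_field_capacity(fallow_storages(storages, calendar, plot), ctx.config)
        rows.append({"plot_id": fc.plot_id, "fc_mm": fc.fc_mm, "n_obs": fc.n_obs})
    _write_csv(pd.DataFrame(rows, columns=["plot_id", "fc_mm", "n_obs"]), ctx.work_dir / "field_capacity.csv")


def _op_balance(ctx: StageContext) -> None:
    from .balance import FROM_FIRST_OBSERVATION, run_balance
    from .io import read_irrigation, read_weather
    from .pipeline import build_forcings
    from .soil import FieldCapacity

    weather = read_weather(ctx.input_dir / "weather.csv")
    irrigation = read_irrigation(ctx.input_dir / "irrigation.csv")
    canopy_daily = _read_csv(ctx.work_dir / "canopy_daily.csv")
    storages = _read_csv(ctx.work_dir / "storage.csv")
    fc_table = _read_csv(ctx.work_dir / "field_capacity.csv")
    out = []
    for row in fc_table.itertuples(index=False):
        fc = FieldCapacity(plot_id=str(row.plot_id), fc_mm=float(row.fc_mm), n_obs=int(row.n_obs))
        forcings = build_forcings(weather, irrigation, canopy_daily, storages, fc.plot_id)
        out.append(run_balance(forcings, fc, ctx.config, smd_init=FROM_FIRST_OBSERVATION))
    _write_csv(pd.concat(out, ignore_index=True), ctx.work_dir / "balance.csv")


def _op_events(ctx: StageContext) -> None:
    from .events import detect_events, events_to_frame

    balance = _read_csv(ctx.work_dir / "balance.csv")
    events = []
    for plot in sorted(balance["plot_id"].unique()):
        events.extend(detect_events(balance[balance["plot_id"] == plot], ctx.config))
    _write_csv(events_to_frame(events), ctx.work_dir / "events.csv")


def _op_export(ctx: StageContext) -> None:
    from .io import export_long_table

    balance = _read_csv(ctx.work_dir / "balance.csv")
    balance["reset"] = balance["reset"].astype(bool)
    canopy_daily = _read_csv(ctx.work_dir / "canopy_daily.csv")
    export_long_table(balance, canopy_daily, ctx.work_dir / "results_long.csv")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.12g")


def _read_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["plot_id"] = df["plot_id"].astype(str)
    for col in ("date", "start_date", "end_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
    return df


def default_stages() -> List[Stage]:
    """The standard read -> canopy/storage -> FC -> balance -> events -> export DAG."""
    return [
        Stage(
            name="canopy",
            operation=_op_canopy,
            input_files=("weather.csv", "ndvi.csv", "calendar.csv"),
            params_subset=("ndvi_bare", "ndvi_closure"),
        ),
        Stage(
            name="storage",
            operation=_op_storage,
            input_files=("probe.csv",),
            params_subset=("profile_depth_cm",),
        ),
        Stage(
            name="field_capacity",
            operation=_op_field_capacity,
            upstream=("storage",),
            input_files=("calendar.csv",),
            params_subset=("fc_rule", "fc_quantile", "fallow_window"),
        ),
        Stage(
            name="balance",
            operation=_op_balance,
            upstream=("canopy", "storage", "field_capacity"),
            input_files=("weather.csv", "irrigation.csv"),
            params_subset=("stress_model", "taw_mm", "raw_mm"),
        ),
        Stage(
            name="events",
            operation=_op_events,
            upstream=("balance",),
            params_subset=("event_min_mm", "event_merge_gap_days"),
        ),
        Stage(
            name="export",
            operation=_op_export,
            upstream=("balance", "canopy", "events"),
        ),
    ]
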