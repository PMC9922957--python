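import shutil
from pathlib import Path

import pandas as pd
import pytest

from fieldwater import TrialConfig
from fieldwater.errors import GraphCycleError
from fieldwater.orchestrator import (
    Stage,
    StageContext,
    default_stages,
    plan,
    run,
    status,
)
from fieldwater.synthetic import generate_trial_files

OUTPUTS = (
    "canopy_daily.csv", "storage.csv", "field_capacity.csv",
    "balance.csv", "events.csv", "results_long.csv",
)


def _noop(ctx):
    pass


class TestPlan:
    def test_chain_orders_linearly(self):
        stages = [
            Stage("C", _noop, upstream=("B",)),
            Stage("B", _noop, upstream=("A",)),
            Stage("A", _noop),
        ]
        assert plan(stages) == ["A", "B", "C"]

    def test_diamond_breaks_ties_by_name(self):
        stages = [
            Stage("D", _noop, upstream=("B", "C")),
            Stage("C", _noop, upstream=("A",)),
            Stage("B", _noop, upstream=("A",)),
            Stage("A", _noop),
        ]
        assert plan(stages) == ["A", "B", "C", "D"]

    def test_cycle_is_reported_with_its_stages(self):
        stages = [Stage("A", _noop, upstream=("B",)), Stage("B", _noop, upstream=("A",))]
        with pytest.raises(GraphCycleError) as err:
            plan(stages)
        assert set(err.value.stages) == {"A", "B"}


@pytest.fixture()
def trial_dirs(tmp_path):
    input_dir = tmp_path / "inputs"
    generate_trial_files(input_dir, n_plots=2, seed=13, start="2020-06-01", end="2021-05-31")
    ctx = StageContext(input_dir=input_dir, work_dir=tmp_path / "work", config=TrialConfig())
    return ctx


def _snapshot(work_dir: Path) -> dict:
    return {name: (work_dir / name).read_bytes() for name in OUTPUTS}


class TestIncrementalRun:
    def test_first_run_executes_all_then_fixpoint(self, trial_dirs):
        report = run(default_stages(), trial_dirs)
        assert report.ok
        assert set(report.executed) == {s.name for s in default_stages()}
        again = run(default_stages(), trial_dirs)
        assert again.executed == []
        assert all(v == "skipped" for v in again.status.values())
        # idempotence: outputs unchanged by the no-op rerun
        assert _snapshot(trial_dirs.work_dir) == _snapshot(trial_dirs.work_dir)

    def test_irrigation_edit_reruns_only_downstream_of_it(self, trial_dirs):
        run(default_stages(), trial_dirs)
        irr = trial_dirs.input_dir / "irrigation.csv"
        df = pd.read_csv(irr)
        df.loc[0, "amount_mm"] = float(df.loc[0, "amount_mm"]) + 1.0
        df.to_csv(irr, index=False)
        report = run(default_stages(), trial_dirs)
        assert set(report.executed) == {"balance", "events", "export"}
        assert report.status["canopy"] == "skipped"
        assert report.status["storage"] == "skipped"

    def test_param_change_is_scoped_to_declaring_stages(self, trial_dirs):
        run(default_stages(), trial_dirs)
        ctx2 = StageContext(
            input_dir=trial_dirs.input_dir,
            work_dir=trial_dirs.work_dir,
            config=TrialConfig(event_min_mm=3.0),
        )
        report = run(default_stages(), ctx2)
        assert set(report.executed) == {"events", "export"}

    def test_undeclared_file_change_triggers_nothing(self, trial_dirs):
        run(default_stages(), trial_dirs)
        (trial_dirs.input_dir / "truth.csv").write_text("tampered\n")
        (trial_dirs.input_dir / "notes.txt").write_text("field diary\n")
        report = run(default_stages(), trial_dirs)
        assert report.executed == []

    def test_copying_identical_files_triggers_nothing(self, trial_dirs, tmp_path):
        """Content hashing, not mtimes: a byte-identical copy is up to date."""
        run(default_stages(), trial_dirs)
        copy_dir = tmp_path / "copy"
        shutil.copytree(trial_dirs.input_dir, copy_dir)
        ctx2 = StageContext(input_dir=copy_dir, work_dir=trial_dirs.work_dir, config=trial_dirs.config)
        assert run(default_stages(), ctx2).executed == []

    def test_incremental_outputs_equal_forced_full_rerun(self, trial_dirs, tmp_path):
        run(default_stages(), trial_dirs)
        ndvi = trial_dirs.input_dir / "ndvi.csv"
        df = pd.read_csv(ndvi)
        df.loc[0, "ndvi_raw"] = min(1.0, float(df.loc[0, "ndvi_raw"]) + 0.05)
        df.to_csv(ndvi, index=False)
        run(default_stages(), trial_dirs)
        incremental = _snapshot(trial_dirs.work_dir)
        fresh = StageContext(input_dir=trial_dirs.input_dir, work_dir=tmp_path / "fresh", config=trial_dirs.config)
        run(default_stages(), fresh, force=True)
        assert incremental == _snapshot(fresh.work_dir)

    def test_status_previews_without_executing(self, trial_dirs):
        preview = status(default_stages(), trial_dirs)
        assert set(preview.executed) == {s.name for s in default_stages()}
        assert not any(trial_dirs.work_dir.glob("*.csv"))

    def test_failure_blocks_downstream_and_preserves_cache(self, trial_dirs):
        run(default_stages(), trial_dirs)
        probe = trial_dirs.input_dir / "probe.csv"
        original = probe.read_text()
        probe.write_text("plot_id,date\nP01,2020-06-01\n")  # missing columns
        report = run(default_stages(), trial_dirs)
        assert report.status["storage"] == "failed"
        assert report.status["field_capacity"] == "blocked"
        assert report.status["balance"] == "blocked"
        assert not report.ok
        # restoring the file returns to a consistent incremental state
        probe.write_text(original)
        recovered = run(default_stages(), trial_dirs)
        assert recovered.ok
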