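"""Schema validation for the trial and roster tables.

The trial CSV schema is one row per trial with columns child_id, task,
item_id, condition, response.  Validation checks enum values, the
condition/item_id contracts per task, per-task trial counts against the
study design, and orphan child/item identifiers, reporting row-level
messages.  Errors are contract violations; warnings are departures from
the expected design (e.g. unusual trial counts) that the pipeline can
still process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tasks import N_ITEMS, Condition, Task, TRIAL_COLUMNS

__all__ = ["ValidationReport", "validate"]

EXPECTED_COUNTS = {
    Task.ME.value: 16,
    Task.DISCOURSE.value: 12,
    Task.COMPREHENSION.value: 16,
    Task.PRODUCTION.value: 16,
    Task.COMBINATION.value: 16,
}


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = [f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        lines += [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


def validate(trials: pd.DataFrame, roster: pd.DataFrame, n_items: int = N_ITEMS) -> ValidationReport:
    """Validate a trial table against the schema and the roster."""
    rep = ValidationReport()
    err, warn = rep.errors.append, rep.warnings.append

    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            err(f"trials missing column {col!r}")
    for col in ("child_id", "age_years"):
        if col not in roster.columns:
            err(f"roster missing column {col!r}")
    if rep.errors:
        return rep

    if roster["child_id"].duplicated().any():
        err("roster contains duplicate child_id values")
    known_children = set(roster["child_id"])
    tasks = {t.value for t in Task}
    conds = {c.value for c in Condition}

    for row in trials.itertuples():
        where = f"row {row.Index}"
        if row.task not in tasks:
            err(f"{where}: unknown task {row.task!r}")
            continue
        if row.child_id not in known_children:
            err(f"{where}: child {row.child_id!r} not in roster")
        if row.response not in (0, 1):
            err(f"{where}: response must be 0/1, got {row.response!r}")
        cond = row.condition
        if row.task == Task.COMBINATION.value:
            if cond not in conds or cond == Condition.NA.value:
                err(f"{where}: combination trial needs congruent/incongruent, got {cond!r}")
        elif not (pd.isna(cond) or cond == Condition.NA.value):
            err(f"{where}: condition set on non-combination task")
        if row.task == Task.DISCOURSE.value:
            if not pd.isna(row.item_id):
                warn(f"{where}: discourse trial carries item_id {row.item_id!r} (ignored)")
        else:
            if pd.isna(row.item_id):
                err(f"{where}: {row.task} trial missing item_id")
            elif not 0 <= int(row.item_id) < n_items:
                err(f"{where}: item_id {row.item_id!r} outside 0..{n_items - 1}")

    counts = trials.groupby(["child_id", "task"]).size()
    for (cid, task), n in counts.items():
        expected = EXPECTED_COUNTS.get(task)
        if expected is not None and n != expected:
            warn(f"child {cid!r}: {n} {task} trials (study design has {expected})")
    for cid in known_children - set(trials["child_id"]):
        warn(f"child {cid!r} has no trials")
    return rep
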