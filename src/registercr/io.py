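"""Reading, writing and validation of the three cohort CSV tables.

Formats (comma-separated, UTF-8, header row):

* ``individuals.csv`` — id, sex, birth_year, country_group, registration_year
* ``observations.csv`` — id, year, list_id, value (0/1)
* ``events.csv`` — id, year, event (death | deregister | reregister)

Validation is strict: every violated rule is reported with the file, row
number (1-based, excluding the header) and rule name, and reading fails
hard — no silent repair.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import COUNTRY_GROUPS, ModelConfig

__all__ = ["CohortTables", "read_cohort", "write_cohort", "validate_tables",
           "CohortValidationError"]

INDIVIDUALS_COLUMNS = ["id", "sex", "birth_year", "country_group",
                       "registration_year"]
OBSERVATIONS_COLUMNS = ["id", "year", "list_id", "value"]
EVENTS_COLUMNS = ["id", "year", "event"]
EVENT_KINDS = {"death", "deregister", "reregister"}


class CohortTables(NamedTuple):
    individuals: pd.DataFrame
    observations: pd.DataFrame
    events: pd.DataFrame


class CohortValidationError(ValueError):
    """One or more cohort-table invariants violated."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        head = problems[:20]
        more = f"\n... and {len(problems) - 20} more" if len(problems) > 20 else ""
        super().__init__(
            f"{len(problems)} cohort validation error(s):\n" + "\n".join(head)
            + more
        )


def validate_tables(tables: CohortTables, config: ModelConfig) -> None:
    """Check every table invariant; raise CohortValidationError listing all
    violations (file, row number, rule name)."""
    ind, obs, ev = tables
    problems: list[str] = []

    def report(file, rows, rule):
        for r in np.atleast_1d(rows):
            problems.append(f"{file}: row {int(r) + 1}: {rule}")

    for file, df, cols in (("individuals.csv", ind, INDIVIDUALS_COLUMNS),
                           ("observations.csv", obs, OBSERVATIONS_COLUMNS),
                           ("events.csv", ev, EVENTS_COLUMNS)):
        if list(df.columns) != cols:
            problems.append(
                f"{file}: header {list(df.columns)} != expected {cols} "
                f"(rule: exact-header)"
            )
    if problems:
        raise CohortValidationError(problems)

    dup = ind.index[ind["id"].duplicated()].to_numpy()
    report("individuals.csv", dup, "duplicate-id")
    bad_sex = ind.index[~ind["sex"].isin([0, 1])].to_numpy()
    report("individuals.csv", bad_sex, "sex-not-binary")
    bad_cg = ind.index[~ind["country_group"].isin(COUNTRY_GROUPS)].to_numpy()
    report("individuals.csv", bad_cg, "unknown-country-group")
    bad_reg = ind.index[~ind["registration_year"].between(
        config.first_year, config.last_year)].to_numpy()
    report("individuals.csv", bad_reg, "registration-year-out-of-range")

    ids = set(ind["id"])
    reg_year = ind.set_index("id")["registration_year"]

    bad = obs.index[~obs["id"].isin(ids)].to_numpy()
    report("observations.csv", bad, "unknown-id")
    report("observations.csv",
           obs.index[~obs["year"].between(config.first_year,
                                          config.last_year)].to_numpy(),
           "year-out-of-range")
    report("observations.csv",
           obs.index[~obs["list_id"].between(1, config.n_lists)].to_numpy(),
           "list-id-out-of-range")
    report("observations.csv",
           obs.index[~obs["value"].isin([0, 1])].to_numpy(),
           "value-not-binary")
    ok = obs["id"].isin(ids)
    if ok.any():
        before = obs.loc[ok].index[
            obs.loc[ok, "year"].to_numpy()
            < reg_year.loc[obs.loc[ok, "id"]].to_numpy()].to_numpy()
        for r in before:
            problems.append(
                f"observations.csv: row {int(r) + 1}: observation before "
                f"registration (id {obs.loc[r, 'id']})"
            )

    report("events.csv", ev.index[~ev["id"].isin(ids)].to_numpy(),
           "unknown-id")
    report("events.csv",
           ev.index[~ev["year"].between(config.first_year,
                                        config.last_year)].to_numpy(),
           "year-out-of-range")
    report("events.csv", ev.index[~ev["event"].isin(EVENT_KINDS)].to_numpy(),
           "unknown-event-kind")
    ok = ev["id"].isin(ids) & ev["event"].isin(EVENT_KINDS)
    evv = ev.loc[ok]
    if len(evv):
        before = evv.index[
            evv["year"].to_numpy() <= reg_year.loc[evv["id"]].to_numpy()
        ].to_numpy()
        report("events.csv", before, "event-not-after-registration")
        for id_, g in evv.groupby("id"):
            deaths = g[g["event"] == "death"]
            if len(deaths) > 1:
                report("events.csv", deaths.index[1:].to_numpy(),
                       f"multiple-deaths (id {id_})")
            mig = g[g["event"].isin(["deregister", "reregister"])]
            mig = mig.sort_values("year")
            expected = "deregister"
            for r, row in mig.iterrows():
                if row["event"] != expected:
                    report("events.csv", r,
                           f"deregister/reregister-alternation (id {id_})")
                    break
                expected = ("reregister" if expected == "deregister"
                            else "deregister")
            if len(deaths) == 1:
                dy = int(deaths["year"].iloc[0])
                after = g.index[(g["event"] != "death")
                                & (g["year"].to_numpy() >= dy)].to_numpy()
                report("events.csv", after, f"event-after-death (id {id_})")

    if problems:
        raise CohortValidationError(problems)


def read_cohort(directory: str | Path, config: ModelConfig) -> CohortTables:
    """Read and validate the three cohort tables from ``directory``."""
    directory = Path(directory)
    frames = []
    for name, cols in (("individuals.csv", INDIVIDUALS_COLUMNS),
                       ("observations.csv", OBSERVATIONS_COLUMNS),
                       ("events.csv", EVENTS_COLUMNS)):
        path = directory / name
        if not path.exists():
            raise FileNotFoundError(f"missing cohort table {path}")
        frames.append(pd.read_csv(path))
    tables = CohortTables(*frames)
    validate_tables(tables, config)
    return tables


def _canonical(tables: CohortTables) -> CohortTables:
    ind = tables.individuals.sort_values("id").reset_index(drop=True)
    obs = tables.observations.sort_values(
        ["id", "year", "list_id"]).reset_index(drop=True)
    ev = tables.events.sort_values(["id", "year", "event"]).reset_index(drop=True)
    return CohortTables(ind, obs, ev)


def write_cohort(tables: CohortTables, directory: str | Path) -> None:
    """Write the three tables as CSV in canonical (sorted) row order.

    Writing the same cohort twice produces byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ind, obs, ev = _canonical(tables)
    ind.to_csv(directory / "individuals.csv", index=False)
    obs.to_csv(directory / "observations.csv", index=False)
    ev.to_csv(directory / "events.csv", index=False)
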