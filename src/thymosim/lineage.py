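"""Clonal lineage tracking and clone-size statistics.

Every immigrant founder receives a clone identifier (its own cell id) which
is inherited by all descendants, giving an in silico clonal label. The
lineage forest records one node per cell (parent, birth and end times, end
cause) and one founder record per immigration. Clone size is the number of
terminal leaves of the clone's binary lineage tree, counted regardless of
each leaf's ultimate fate (exit, death, or still alive at simulation end);
log2 of the average clone size expresses rounds of cell division.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

END_CAUSES = ("divided", "died", "exited", "alive_at_end")


class UnknownCloneError(KeyError):
    pass


class UndefinedResultError(ValueError):
    pass


@dataclass
class LineageForest:
    """Node and founder tables of all clonal lineage trees in one run.

    ``nodes`` columns: cell_id, clone_id, parent_id (-1 for founders),
    birth_hr, end_hr (NaN while alive), end_cause.
    ``founders`` columns: clone_id, homing_hr, lesioned.
    """

    nodes: pd.DataFrame
    founders: pd.DataFrame

    @classmethod
    def from_records(
        cls,
        node_records: Iterable[Mapping],
        founder_records: Iterable[Mapping],
    ) -> "LineageForest":
        nodes = pd.DataFrame(
            node_records,
            columns=["cell_id", "clone_id", "parent_id", "birth_hr",
                     "end_hr", "end_cause"],
        )
        founders = pd.DataFrame(
            founder_records, columns=["clone_id", "homing_hr", "lesioned"]
        )
        return cls(nodes=nodes, founders=founders)

    def validate(self) -> None:
        """Structural invariants: unique parents, clone consistency, at most
        one lesioned founder, leaves = divisions + 1 per clone."""
        nodes = self.nodes
        non_founders = nodes[nodes.parent_id >= 0]
        parent_cause = nodes.set_index("cell_id").loc[
            non_founders.parent_id, "end_cause"
        ]
        if not (parent_cause == "divided").all():
            raise ValueError("a non-founder's parent did not end by division")
        clone_of = nodes.set_index("cell_id")["clone_id"]
        if not (
            non_founders.clone_id.values
            == clone_of.loc[non_founders.parent_id].values
        ).all():
            raise ValueError("clone identifier not inherited from parent")
        if int(self.founders.lesioned.sum()) > 1:
            raise ValueError("more than one lesioned founder")
        for clone_id, grp in nodes.groupby("clone_id"):
            leaves = (grp.end_cause != "divided").sum()
            divisions = (grp.end_cause == "divided").sum()
            if leaves != divisions + 1:
                raise ValueError(
                    f"clone {clone_id}: leaves != divisions + 1"
                )

    # ------------------------------------------------------------------
    def clone_size(self, clone_id: int) -> int:
        """Number of terminal leaves of the clone's lineage tree.

        Leaves are nodes that did not divide, counted regardless of fate
        (died, exited, or alive at simulation end).
        """
        grp = self.nodes[self.nodes.clone_id == clone_id]
        if grp.empty:
            raise UnknownCloneError(f"unknown clone_id {clone_id}")
        return int((grp.end_cause != "divided").sum())

    def clone_sizes(self, lesioned: bool | None = None) -> pd.Series:
        """Leaf counts for every clone, optionally filtered by genotype."""
        founders = self.founders
        if lesioned is not None:
            founders = founders[founders.lesioned == lesioned]
        leaf = self.nodes[self.nodes.end_cause != "divided"]
        counts = leaf.groupby("clone_id").size()
        return counts.reindex(founders.clone_id.values, fill_value=0)


def rounds_of_division(clone_sizes: Iterable[int]) -> float:
    """log2 of the mean clone size pooled over clones (and replicates)."""
    sizes = np.asarray(list(clone_sizes), dtype=float)
    if sizes.size == 0:
        raise UndefinedResultError("no clones to average")
    if (sizes < 1).any():
        raise ValueError("clone sizes must be >= 1")
    return float(np.log2(sizes.mean()))


def per_clone_rounds(clone_sizes: Iterable[int]) -> np.ndarray:
    """Per-clone log2 leaf counts (for distribution mean and SD)."""
    sizes = np.asarray(list(clone_sizes), dtype=float)
    if sizes.size == 0:
        raise UndefinedResultError("no clones")
    return np.log2(sizes)


def genotype_summary(
    forest: LineageForest,
    scenario: str,
    replicate: int = 0,
    parameters: Mapping | None = None,
) -> pd.DataFrame:
    """One row per genotype (normal / lesioned) for a single replicate run,
    in the long layout used for cross-scenario comparison: log2 of the
    average clone size, clone count, plus echoed parameter columns."""
    rows = []
    for genotype, flag in (("normal", False), ("lesioned", True)):
        sizes = forest.clone_sizes(lesioned=flag)
        if sizes.empty:
            continue
        row = {
            "grouping": scenario,
            "simulation_datafile": f"{scenario}_rep{replicate}",
            "genotype": genotype,
            "n_clones": int(sizes.size),
            "log2_avg_clone_size": rounds_of_division(sizes),
        }
        if parameters:
            row.update(parameters)
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_to_homing(
    clone_series: pd.DataFrame, forest: LineageForest
) -> dict[int, pd.DataFrame]:
    """Shift each clone's cell-count time series so t=0 is its homing time.

    ``clone_series`` is long-format (time_hr, clone_id, count) sampled at a
    stride. Returns {clone_id: DataFrame(time_since_homing_hr, count)}.
    """
    homing = forest.founders.set_index("clone_id")["homing_hr"]
    out: dict[int, pd.DataFrame] = {}
    for clone_id, grp in clone_series.groupby("clone_id"):
        if clone_id not in homing.index:
            continue
        shifted = grp[["time_hr", "count"]].copy()
        shifted["time_since_homing_hr"] = shifted.time_hr - homing[clone_id]
        out[int(clone_id)] = shifted.reset_index(drop=True)
    return out


def turnover_time(forest: LineageForest) -> float:
    """Median homing-to-last-departure interval across completed clones.

    A clone is completed when none of its members is alive at simulation
    end; clones still alive are censored out of the median.
    """
    nodes = forest.nodes
    alive_clones = set(
        nodes.loc[nodes.end_cause == "alive_at_end", "clone_id"]
    )
    intervals = []
    homing = forest.founders.set_index("clone_id")["homing_hr"]
    for clone_id, grp in nodes.groupby("clone_id"):
        if clone_id in alive_clones or clone_id not in homing.index:
            continue
        intervals.append(float(grp.end_hr.max() - homing[clone_id]))
    if not intervals:
        raise UndefinedResultError("no completed clones")
    return float(np.median(intervals))
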