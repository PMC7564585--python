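"""Same-same permutation analysis and the empirical BH threshold.

When a state has six replicates, they can be split into triplet-vs-triplet
"same-same" comparisons — biologically identical groups in which every
protein called differentially expressed is by construction a false
discovery at the protein-quantitation level. The fraction of proteins
called significant at a BH Q threshold q, expressed as a percentage, is
the protein-quantitation false discovery rate, PQ-FDR(q).

The procedure: enumerate all C(6,3)/2 = 10 non-redundant 3-vs-3 splits,
run BH-adjusted pooled t-tests on lnNSAF within each, sweep q over a grid
from 0 to 1 in steps of 0.01, average the ten curves per state, average
the per-state curves, and read off the largest q whose grand-average
PQ-FDR stays at or below a target (default 1%). That empirically derived
Q replaces the standard 0.05 cut-off when the control-vs-treatment
comparison is re-classified — a more permissive, experimentally calibrated
multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .quantitation import DEFAULT_PSEUDOCOUNT, log_transform, nsaf_for_state
from .stat_tests import bh_adjust, ttest_rows
from .stringency import StateMatrix, high_stringency_ids

logger = logging.getLogger(__name__)

__all__ = [
    "TripletPartition",
    "PQFDRCurve",
    "DerivedThreshold",
    "enumerate_partitions",
    "nonredundant_splits",
    "bh_adjust",
    "pqfdr_for_partition",
    "average_curves",
    "derive_threshold",
    "samesame_state_curve",
    "default_q_grid",
    "DEFAULT_TARGET_PQFDR",
    "SAME_SAME_REPLICATES",
]

#: replicate count required per state for same-same analysis
SAME_SAME_REPLICATES = 6
#: target protein-quantitation FDR, as a percentage
DEFAULT_TARGET_PQFDR = 1.0


@dataclass(frozen=True)
class TripletPartition:
    """One unordered 3-vs-3 split of six replicate numbers."""

    group_a: tuple[int, int, int]
    group_b: tuple[int, int, int]

    def __post_init__(self):
        a, b = set(self.group_a), set(self.group_b)
        if len(a) != 3 or len(b) != 3 or a & b:
            raise ValueError("groups must be disjoint sets of 3 replicate numbers")
        if min(a) > min(b):
            raise ValueError("canonical form keeps the lowest replicate number in group_a")

    @property
    def label(self) -> str:
        return "{}v{}".format("".join(map(str, self.group_a)), "".join(map(str, self.group_b)))


def nonredundant_splits(items: list[int], k: int) -> list[tuple[tuple, tuple]]:
    """All unordered k-vs-k splits of 2k items, each counted once.

    Fixing the smallest item in the first group de-duplicates the A-vs-B /
    B-vs-A mirror pairs, yielding C(2k, k)/2 splits.
    """
    items = sorted(items)
    if len(items) != 2 * k:
        raise ValueError(f"need exactly {2 * k} items, got {len(items)}")
    first, rest = items[0], items[1:]
    out = []
    for combo in combinations(rest, k - 1):
        a = (first, *combo)
        b = tuple(x for x in rest if x not in combo)
        out.append((a, b))
    return out


def enumerate_partitions(replicate_numbers: set[int] | list[int]) -> list[TripletPartition]:
    """The ten non-redundant triplet-vs-triplet partitions of six replicates."""
    reps = sorted(set(replicate_numbers))
    if len(reps) != SAME_SAME_REPLICATES:
        raise ValueError(
            f"same-same analysis needs exactly {SAME_SAME_REPLICATES} distinct replicates, got {len(reps)}"
        )
    return [TripletPartition(a, b) for a, b in nonredundant_splits(reps, 3)]


def default_q_grid(step: float = 0.01) -> np.ndarray:
    """BH Q thresholds 0, step, ..., 1."""
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


@dataclass
class PQFDRCurve:
    """PQ-FDR (percent) as a function of the BH Q threshold."""

    q_grid: np.ndarray = field(repr=False)
    pqfdr: np.ndarray = field(repr=False)
    n_proteins_tested: int = 0
    source: str = ""

    def __post_init__(self):
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.pqfdr = np.asarray(self.pqfdr, dtype=float)
        if self.q_grid.shape != self.pqfdr.shape:
            raise ValueError("q_grid and pqfdr must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bh_q_threshold": self.q_grid, "pqfdr_percent": self.pqfdr})


def pqfdr_for_partition(
    matrix: StateMatrix,
    partition: TripletPartition,
    q_grid: np.ndarray | None = None,
    *,
    min_summed_count: int = 5,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PQFDRCurve:
    """PQ-FDR curve of one triplet-vs-triplet split of a six-replicate state.

    Proteins tested are the state's high-stringency set (MSC evaluated over
    all six replicates). Per protein, group A vs group B lnNSAF is tested
    and BH-adjusted; PQ-FDR(q) = 100 x (#adjusted q-values <= q) / n.
    """
    if q_grid is None:
        q_grid = default_q_grid()
    high = high_stringency_ids(matrix, min_summed_count)
    if not high:
        raise ValueError(f"state {matrix.state!r} has an empty high-stringency set")
    ln = nsaf_for_state(matrix, pseudocount).ln_nsaf.loc[sorted(high)]
    a = ln[list(partition.group_a)].to_numpy()
    b = ln[list(partition.group_b)].to_numpy()
    q_values = bh_adjust(ttest_rows(a, b))
    pq = 100.0 * (q_values[None, :] <= np.asarray(q_grid)[:, None]).mean(axis=1)
    return PQFDRCurve(
        q_grid=q_grid,
        pqfdr=pq,
        n_proteins_tested=len(high),
        source=f"{matrix.state}:{partition.label}",
    )


def average_curves(curves: list[PQFDRCurve], source: str = "average") -> PQFDRCurve:
    """Pointwise arithmetic mean of PQ-FDR curves on a shared grid."""
    if not curves:
        raise ValueError("no curves to average")
    grid = curves[0].q_grid
    for c in curves[1:]:
        if c.q_grid.shape != grid.shape or not np.allclose(c.q_grid, grid):
            raise ValueError("q-grid mismatch between curves")
    return PQFDRCurve(
        q_grid=grid,
        pqfdr=np.mean([c.pqfdr for c in curves], axis=0),
        n_proteins_tested=int(round(np.mean([c.n_proteins_tested for c in curves]))),
        source=source,
    )


def samesame_state_curve(
    matrix: StateMatrix,
    q_grid: np.ndarray | None = None,
    *,
    min_summed_count: int = 5,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[PQFDRCurve, list[PQFDRCurve]]:
    """Average PQ-FDR curve of one state over its ten partitions."""
    partitions = enumerate_partitions(matrix.replicate_numbers)
    curves = [
        pqfdr_for_partition(
            matrix, p, q_grid, min_summed_count=min_summed_count, pseudocount=pseudocount
        )
        for p in partitions
    ]
    return average_curves(curves, source=f"{matrix.state}:average"), curves


@dataclass
class DerivedThreshold:
    """Empirical BH Q threshold achieving the target PQ-FDR."""

    q_star: float
    target_pqfdr: float = DEFAULT_TARGET_PQFDR


def derive_threshold(
    grand_average: PQFDRCurve, target: float = DEFAULT_TARGET_PQFDR
) -> DerivedThreshold:
    """Largest Q whose grand-average PQ-FDR stays <= *target* percent.

    The grid point is refined by linear interpolation towards the first
    point exceeding the target, giving sub-grid resolution. If even the
    first positive grid point exceeds the target, no permissive threshold
    exists and q_star = 0 is returned with a warning.
    """
    q, f = grand_average.q_grid, grand_average.pqfdr
    below = f <= target
    if not below[0]:
        # pqfdr(0) should be 0 unless some p-values are exactly 0
        logger.warning("PQ-FDR already above target at q=0; q_star = 0")
        return DerivedThreshold(q_star=0.0, target_pqfdr=target)
    if below.all():
        return DerivedThreshold(q_star=float(q[-1]), target_pqfdr=target)
    i = int(np.argmin(below))  # first grid index above target
    if i == 1:
        logger.warning(
            "PQ-FDR exceeds %.3g%% already at q=%.3g; no permissive threshold exists",
            target, q[1],
        )
        return DerivedThreshold(q_star=0.0, target_pqfdr=target)
    q_lo, q_hi = q[i - 1], q[i]
    f_lo, f_hi = f[i - 1], f[i]
    if f_hi > f_lo:
        q_star = q_lo + (target - f_lo) * (q_hi - q_lo) / (f_hi - f_lo)
    else:
        q_star = q_lo
    return DerivedThreshold(q_star=float(min(q_star, q_hi)), target_pqfdr=target)


def samesame_analysis(
    matrices: list[StateMatrix],
    *,
    q_grid: np.ndarray | None = None,
    min_summed_count: int = 5,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    target_pqfdr: float = DEFAULT_TARGET_PQFDR,
) -> tuple[DerivedThreshold, PQFDRCurve, dict[str, tuple[PQFDRCurve, list[PQFDRCurve]]]]:
    """Full same-same workflow over every six-replicate state supplied.

    Returns the derived threshold, the grand-average curve (mean of the
    per-state averages) and, per state, its average curve plus the ten
    per-partition curves.
    """
    eligible = [m for m in matrices if m.n_replicates == SAME_SAME_REPLICATES]
    if not eligible:
        raise ValueError("same-same analysis needs at least one state with six replicates")
    per_state = {}
    state_averages = []
    for m in eligible:
        avg, curves = samesame_state_curve(
            m, q_grid, min_summed_count=min_summed_count, pseudocount=pseudocount
        )
        per_state[m.state] = (avg, curves)
        state_averages.append(avg)
    grand = average_curves(state_averages, source="grand_average")
    return derive_threshold(grand, target_pqfdr), grand, per_state
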