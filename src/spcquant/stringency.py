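"""Replicate collation and minimum-spectral-count (MSC) stringency filtering.

The replicates of one biological state are collated by outer union of
protein identifiers into a protein x replicate matrix — the unfiltered
"All Proteins" view of that state, with absence encoded as a zero count.

MSC then defines the high-stringency subset: a protein qualifies in a
state when it is identified (count > 0) in *every* replicate of that state
and its counts summed over the state's replicates reach a user-specified
minimum (default 5). Because random noise identifications are, by
definition, not reproducible across replicates, the surviving list is a
far higher-stringency inventory suitable for downstream quantitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import ReplicateTable

logger = logging.getLogger(__name__)

__all__ = [
    "StateMatrix",
    "StringencyPartition",
    "collate_state",
    "msc_qualify",
    "high_stringency_ids",
    "build_stringency_partition",
    "DEFAULT_MIN_SUMMED_COUNT",
]

#: default replicate-summed spectral-count threshold for MSC
DEFAULT_MIN_SUMMED_COUNT = 5


@dataclass
class StateMatrix:
    """Protein x replicate matrices for one state.

    ``counts`` and ``scores`` are DataFrames indexed by protein identifier
    with one column per replicate number (ascending); missing (protein,
    replicate) cells are 0 counts / NaN scores. ``molecular_weight`` is a
    per-protein Series, consistent across replicates (on conflict the first
    seen value is kept with a warning).
    """

    state: str
    replicate_numbers: list[int]
    counts: pd.DataFrame = field(repr=False)
    scores: pd.DataFrame = field(repr=False)
    molecular_weight: pd.Series = field(repr=False)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_numbers)

    @property
    def identifiers(self) -> list[str]:
        return list(self.counts.index)

    def subset(self, replicate_numbers: list[int]) -> "StateMatrix":
        """Restrict to a subset of replicates, dropping all-zero proteins."""
        missing = set(replicate_numbers) - set(self.replicate_numbers)
        if missing:
            raise ValueError(f"state {self.state!r} has no replicate(s) {sorted(missing)}")
        reps = sorted(replicate_numbers)
        counts = self.counts[reps]
        keep = counts.sum(axis=1) > 0
        return StateMatrix(
            state=self.state,
            replicate_numbers=reps,
            counts=counts[keep],
            scores=self.scores[reps][keep],
            molecular_weight=self.molecular_weight[keep],
        )


def collate_state(replicates: list[ReplicateTable]) -> StateMatrix:
    """Outer-collate the replicates of one state into a :class:`StateMatrix`."""
    if not replicates:
        raise ValueError("need at least one replicate")
    states = {r.state for r in replicates}
    if len(states) > 1:
        raise ValueError(f"mixed state labels in one collation: {sorted(states)}")
    rep_numbers = [r.replicate_number for r in replicates]
    if len(set(rep_numbers)) != len(rep_numbers):
        raise ValueError(f"duplicate replicate numbers for state {replicates[0].state!r}")

    replicates = sorted(replicates, key=lambda r: r.replicate_number)
    count_cols, score_cols = {}, {}
    mw: dict[str, float] = {}
    for rep in replicates:
        f = rep.frame.set_index("identifier")
        count_cols[rep.replicate_number] = f["spectral_count"]
        score_cols[rep.replicate_number] = f["score"]
        for ident, weight in f["molecular_weight"].items():
            if ident in mw:
                if abs(mw[ident] - weight) > 1e-9 * max(abs(weight), 1.0):
                    logger.warning(
                        "state %s: molecular weight conflict for %s (%g vs %g); keeping first",
                        rep.state, ident, mw[ident], weight,
                    )
            else:
                mw[ident] = float(weight)

    counts = pd.DataFrame(count_cols).astype(float).fillna(0).astype(int).sort_index()
    scores = pd.DataFrame(score_cols).reindex(counts.index)
    weight = pd.Series(mw, name="molecular_weight").reindex(counts.index)
    return StateMatrix(
        state=replicates[0].state,
        replicate_numbers=[r.replicate_number for r in replicates],
        counts=counts,
        scores=scores,
        molecular_weight=weight,
    )


def msc_qualify(matrix: StateMatrix, protein: str, min_summed_count: int) -> bool:
    """MSC rule for a single protein in one state.

    True iff the protein has count > 0 in every replicate of the state AND
    its counts summed across the state's replicates reach *min_summed_count*.
    """
    if protein not in matrix.counts.index:
        raise KeyError(f"protein {protein!r} not in state {matrix.state!r}")
    row = matrix.counts.loc[protein]
    return bool((row > 0).all() and row.sum() >= min_summed_count)


def high_stringency_ids(matrix: StateMatrix, min_summed_count: int) -> set[str]:
    """Vectorised MSC over every protein of one state."""
    present_all = (matrix.counts > 0).all(axis=1)
    summed_ok = matrix.counts.sum(axis=1) >= min_summed_count
    return set(matrix.counts.index[present_all & summed_ok])


@dataclass
class StringencyPartition:
    """Per-state high-stringency sets alongside the unfiltered inventories."""

    high: dict[str, set[str]]
    all_proteins: dict[str, set[str]]
    min_summed_count: int

    @property
    def states(self) -> list[str]:
        return list(self.high)

    @property
    def experiment_high(self) -> set[str]:
        """Proteins qualifying in at least one state."""
        return set().union(*self.high.values()) if self.high else set()


def build_stringency_partition(
    matrices: list[StateMatrix],
    min_summed_count: int = DEFAULT_MIN_SUMMED_COUNT,
) -> StringencyPartition:
    """Apply MSC to each state independently.

    The summed-count rule is evaluated within each state separately. Fewer
    than three replicates in a state is permitted with a warning — the
    rule is well defined for any replicate count, but reproducibility
    filtering is weak below three.
    """
    if not matrices:
        raise ValueError("need at least one state")
    if min_summed_count < 1:
        raise ValueError("min_summed_count must be a positive integer")
    high, allp = {}, {}
    for m in matrices:
        if m.state in high:
            raise ValueError(f"duplicate state {m.state!r}")
        if m.n_replicates < 3:
            logger.warning(
                "state %s has only %d replicate(s); MSC reproducibility filtering is weak below 3",
                m.state, m.n_replicates,
            )
        high[m.state] = high_stringency_ids(m, min_summed_count)
        allp[m.state] = set(m.counts.index)
    return StringencyPartition(high=high, all_proteins=allp, min_summed_count=min_summed_count)
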