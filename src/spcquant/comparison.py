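"""Two-state differential-expression comparison.

All comparisons are made relative to the control group (the first state
supplied). Shared proteins are tested with a two-sided Students t-test
(pooled variance) on lnNSAF replicate vectors and every protein is
classified as upregulated, downregulated, unchanged, or unique to one
state. The analysis runs in parallel on two streams: the MSC-filtered
high-stringency inventory and the unfiltered "All Proteins" inventory —
the latter kept for transparency, so users can see why a protein of
interest failed the stringency criteria.

A protein counts as *unique* to a state only when it is absent even from
the other state's unfiltered list; a protein seen at low stringency in the
other state is shared-for-testing instead, since low-stringency presence
is meaningful context rather than true absence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .quantitation import DEFAULT_PSEUDOCOUNT, compute_nsaf, fold_change, log_transform
from .stat_tests import bh_adjust, ttest_rows, ttest_shared
from .stringency import StateMatrix, StringencyPartition

__all__ = [
    "Category",
    "Stream",
    "shared_and_unique",
    "ttest_shared",
    "ttest_rows",
    "compare_states",
    "classify",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.05


class Category(str, Enum):
    UP = "upregulated"
    DOWN = "downregulated"
    UNCHANGED = "unchanged"
    UNIQUE_CONTROL = "unique_control"
    UNIQUE_TREATMENT = "unique_treatment"


class Stream(str, Enum):
    HIGH_STRINGENCY = "high_stringency"
    ALL_PROTEINS = "all_proteins"


def shared_and_unique(
    partition: StringencyPartition, control_state: str, treatment_state: str
) -> tuple[set[str], set[str], set[str]]:
    """Split the high-stringency union into (shared, unique_control, unique_treatment).

    shared: qualifies in at least one state and observed (any stringency) in
    both. unique_X: qualifies in X and entirely unobserved in the other
    state's All Proteins list.
    """
    for s in (control_state, treatment_state):
        if s not in partition.high:
            raise KeyError(f"state {s!r} not in partition")
    high_c, high_t = partition.high[control_state], partition.high[treatment_state]
    all_c, all_t = partition.all_proteins[control_state], partition.all_proteins[treatment_state]
    unique_c = high_c - all_t
    unique_t = high_t - all_c
    shared = (high_c & all_t) | (high_t & all_c)
    return shared, unique_c, unique_t


def _nsaf_on_inventory(
    matrix: StateMatrix,
    inventory: list[str],
    molecular_weight: pd.Series,
    pseudocount: float,
) -> pd.DataFrame:
    """NSAF of one state's replicates over an arbitrary protein inventory.

    The normalisation denominator always runs over the state's full
    "All Proteins" inventory (proteins absent from the state contribute
    zero to it and get the pseudocount numerator), so the returned values
    agree with the state's own NSAF regardless of which subset is asked
    for.
    """
    basis = list(matrix.counts.index) + [i for i in inventory if i not in matrix.counts.index]
    counts = matrix.counts.reindex(basis).fillna(0)
    mw = molecular_weight.reindex(basis)
    if mw.isna().any():
        missing = list(mw.index[mw.isna()])
        raise ValueError(f"no molecular weight known for {missing[:5]}...")
    full = pd.DataFrame(
        {rep: compute_nsaf(counts[rep], mw, pseudocount) for rep in matrix.replicate_numbers},
        index=pd.Index(basis, name="identifier"),
    )
    return full.loc[list(inventory)]


@dataclass
class StateComparison:
    """One control-vs-treatment comparison with both stringency streams."""

    control: StateMatrix
    treatment: StateMatrix
    partition: StringencyPartition
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def table(self, stream: Stream) -> pd.DataFrame:
        return compare_states(
            self.control, self.treatment, self.partition, stream, pseudocount=self.pseudocount
        )


def compare_states(
    control: StateMatrix,
    treatment: StateMatrix,
    partition: StringencyPartition,
    stream: Stream,
    *,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Build the per-protein comparison table for one stringency stream.

    Rows carry group mean NSAF/lnNSAF, log2 fold change (treatment relative
    to control), the t-test p-value and BH-adjusted q-value; unique proteins
    (high-stringency stream only) have no test statistics. Classification
    into categories is a separate step (:func:`classify`) so the same table
    can be cut at the standard alpha or at a same-same derived BH threshold.
    """
    shared, unique_c, unique_t = shared_and_unique(partition, control.state, treatment.state)
    if stream is Stream.HIGH_STRINGENCY:
        tested = sorted(shared)
        uniques = [(u, Category.UNIQUE_CONTROL) for u in sorted(unique_c)] + [
            (u, Category.UNIQUE_TREATMENT) for u in sorted(unique_t)
        ]
    else:
        tested = sorted(
            partition.all_proteins[control.state] | partition.all_proteins[treatment.state]
        )
        uniques = []

    mw = control.molecular_weight.combine_first(treatment.molecular_weight)
    rows = []
    if tested:
        nsaf_c = _nsaf_on_inventory(control, tested, mw, pseudocount)
        nsaf_t = _nsaf_on_inventory(treatment, tested, mw, pseudocount)
        ln_c, ln_t = log_transform(nsaf_c), log_transform(nsaf_t)
        p = ttest_rows(ln_c.to_numpy(), ln_t.to_numpy())
        fc = fold_change(nsaf_c.mean(axis=1), nsaf_t.mean(axis=1))
        rows.append(
            pd.DataFrame(
                {
                    "identifier": tested,
                    "mean_nsaf_control": nsaf_c.mean(axis=1).to_numpy(),
                    "mean_nsaf_treatment": nsaf_t.mean(axis=1).to_numpy(),
                    "mean_ln_nsaf_control": ln_c.mean(axis=1).to_numpy(),
                    "mean_ln_nsaf_treatment": ln_t.mean(axis=1).to_numpy(),
                    "log2_fold_change": fc.to_numpy(),
                    "p_value": p,
                    "q_value": bh_adjust(p),
                    "category": pd.NA,
                }
            )
        )
    for ident, cat in uniques:
        present = control if cat is Category.UNIQUE_CONTROL else treatment
        nsaf_u = _nsaf_on_inventory(present, [ident], mw, pseudocount)
        mean_nsaf = float(nsaf_u.mean(axis=1).iloc[0])
        mean_ln = float(log_transform(nsaf_u).mean(axis=1).iloc[0])
        rows.append(
            pd.DataFrame(
                {
                    "identifier": [ident],
                    "mean_nsaf_control": [mean_nsaf if cat is Category.UNIQUE_CONTROL else np.nan],
                    "mean_nsaf_treatment": [mean_nsaf if cat is Category.UNIQUE_TREATMENT else np.nan],
                    "mean_ln_nsaf_control": [mean_ln if cat is Category.UNIQUE_CONTROL else np.nan],
                    "mean_ln_nsaf_treatment": [mean_ln if cat is Category.UNIQUE_TREATMENT else np.nan],
                    "log2_fold_change": [np.nan],
                    "p_value": [np.nan],
                    "q_value": [np.nan],
                    "category": [cat.value],
                }
            )
        )
    if not rows:
        table = pd.DataFrame(
            columns=[
                "identifier", "mean_nsaf_control", "mean_nsaf_treatment",
                "mean_ln_nsaf_control", "mean_ln_nsaf_treatment",
                "log2_fold_change", "p_value", "q_value", "category",
            ]
        )
    else:
        table = pd.concat(rows, ignore_index=True)
    table["stream"] = stream.value
    return table.sort_values("identifier", kind="stable").reset_index(drop=True)


def classify(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    *,
    use_bh: bool = False,
    bh_q: float | None = None,
) -> pd.DataFrame:
    """Assign UP / DOWN / UNCHANGED to every tested protein.

    Without BH a protein is significant when p < *alpha* (no fold-change
    magnitude gate). With ``use_bh`` significance is ``q_value <= bh_q``,
    where *bh_q* is typically the same-same derived threshold replacing the
    standard 0.05 cut-off. Unique-protein rows keep their category.
    """
    if use_bh and bh_q is None:
        raise ValueError("use_bh=True requires bh_q")
    out = table.copy()
    tested = out["p_value"].notna()
    if use_bh:
        significant = tested & (out["q_value"] <= bh_q)
    else:
        significant = tested & (out["p_value"] < alpha)
    fc = out["log2_fold_change"]
    out.loc[tested, "category"] = Category.UNCHANGED.value
    out.loc[significant & (fc > 0), "category"] = Category.UP.value
    out.loc[significant & (fc < 0), "category"] = Category.DOWN.value
    return out
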