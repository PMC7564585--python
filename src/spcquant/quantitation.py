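"""NSAF quantitation.

The normalised spectral abundance factor of protein *k* in one replicate is

    NSAF_k = (SpC_k / L_k) / sum_j (SpC_j / L_j)

where SpC is the spectral count and L the protein's length proxy (here the
molecular weight supplied by the search engine — NSAF is invariant to any
global unit factor, so Da vs kDa is immaterial). Dividing by length corrects
for larger proteins yielding more peptides and hence more spectra; the
denominator sums over the replicate's full "All Proteins" inventory so the
values are abundance fractions that sum to 1 within a replicate and remain
comparable between the high-stringency and unfiltered output streams.

Zero-count cells (a protein not identified in that replicate) receive a
small additive pseudocount in the numerator only, so that ln(NSAF) — the
scale used for t-tests and PCA — is defined everywhere while the sum-to-one
normalisation of observed proteins is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stringency import StateMatrix

__all__ = [
    "NSAFMatrix",
    "compute_nsaf",
    "nsaf_for_state",
    "log_transform",
    "fold_change",
    "DEFAULT_PSEUDOCOUNT",
]

#: additive spectral-count pseudocount applied to zero cells
DEFAULT_PSEUDOCOUNT = 0.5


def compute_nsaf(
    counts: np.ndarray | pd.Series,
    lengths: np.ndarray | pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """NSAF for one replicate over its basis inventory.

    The denominator uses the raw counts (zeros contribute nothing), so the
    NSAF of observed proteins sums to exactly 1; zero-count entries get
    ``pseudocount / L`` in the numerator so their NSAF is small but positive.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have the same shape")
    if np.any(counts < 0):
        raise ValueError("spectral counts must be non-negative")
    if np.any(lengths <= 0) or np.any(~np.isfinite(lengths)):
        raise ValueError("all protein lengths / molecular weights must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    denom = np.sum(counts / lengths)
    if denom == 0:
        raise ValueError("all spectral counts are zero; NSAF undefined")
    numer = np.where(counts > 0, counts, pseudocount) / lengths
    return numer / denom


@dataclass
class NSAFMatrix:
    """Per-replicate NSAF and lnNSAF for one state's protein inventory."""

    state: str
    nsaf: pd.DataFrame = field(repr=False)
    ln_nsaf: pd.DataFrame = field(repr=False)
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def basis_ids(self) -> list[str]:
        return list(self.nsaf.index)


def nsaf_for_state(
    matrix: StateMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> NSAFMatrix:
    """NSAF and lnNSAF per replicate, normalised over the state's inventory."""
    nsaf = pd.DataFrame(
        {
            rep: compute_nsaf(matrix.counts[rep], matrix.molecular_weight, pseudocount)
            for rep in matrix.replicate_numbers
        },
        index=matrix.counts.index,
    )
    return NSAFMatrix(
        state=matrix.state,
        nsaf=nsaf,
        ln_nsaf=log_transform(nsaf, pseudocount=pseudocount),
        pseudocount=pseudocount,
    )


def log_transform(
    nsaf: pd.DataFrame | np.ndarray, *, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame | np.ndarray:
    """Elementwise natural log of NSAF (the lnNSAF statistics/PCA scale)."""
    values = nsaf.to_numpy() if isinstance(nsaf, pd.DataFrame) else np.asarray(nsaf, float)
    if np.any(values <= 0):
        raise ValueError(
            "NSAF matrix contains non-positive entries; set a positive pseudocount "
            "so proteins unobserved in a replicate get a defined lnNSAF"
        )
    out = np.log(values)
    if isinstance(nsaf, pd.DataFrame):
        return pd.DataFrame(out, index=nsaf.index, columns=nsaf.columns)
    return out


def fold_change(
    control_means: np.ndarray | pd.Series, treatment_means: np.ndarray | pd.Series
) -> np.ndarray | pd.Series:
    """log2(treatment mean / control mean); positive = up in treatment."""
    c = np.asarray(control_means, dtype=float)
    t = np.asarray(treatment_means, dtype=float)
    if np.any(c <= 0) or np.any(t <= 0):
        raise ValueError("group means must be positive for a log fold change")
    out = np.log2(t / c)
    if isinstance(control_means, pd.Series):
        return pd.Series(out, index=control_means.index)
    return out
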