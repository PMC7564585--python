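"""Synthetic search-engine exports with known ground truth.

Emulates the per-replicate protein-identification CSVs a PSM search engine
would produce for a spectral-counting experiment: per-protein baseline
abundances are log-normal across the proteome, per-replicate spectral
counts are drawn from a negative binomial (over-dispersed, as real
spectral counts are; Poisson available as the clean-null option), and a
dropout probability removes a protein from a replicate's file entirely —
a zero count is never written, it is simply not identified, exercising the
zero-handling path end to end.

Differential expression is planted multiplicatively on a chosen fraction
of proteins in every non-control state, half up and half down, and the
ground truth is returned alongside the files. Everything is a pure
function of the design's seed.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import Dialect, dialect_registry, format_filename

__all__ = ["SyntheticDesign", "generate_dataset", "generate_worked_example", "design_from_yaml"]


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic experiment.

    Defaults describe a routine two-condition shotgun experiment: a couple
    of hundred quantifiable proteins, median baseline around 10 spectra per
    protein with order-of-magnitude spread, mild over-dispersion, 5%
    per-replicate dropout, and a fifth of the proteome shifted four-fold.
    """

    n_proteins: int = 200
    states: list[tuple[str, int]] = field(default_factory=lambda: [("control", 3), ("treatment", 3)])
    baseline_log_mean: float = np.log(10.0)  # log-normal location of mean SpC
    baseline_log_sd: float = 1.0
    de_fraction: float = 0.2
    de_fold_change: float = 4.0
    dropout_rate: float = 0.05
    noise_model: str = "negative_binomial"  # or "poisson"
    dispersion: float = 0.3  # NB: var = mu + dispersion * mu^2
    mw_range: tuple[float, float] = (10.0, 150.0)  # kDa
    dialect: Dialect = Dialect.GPM_XTANDEM
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if not self.states:
            raise ValueError("need at least one state")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.noise_model not in ("negative_binomial", "poisson"):
            raise ValueError("noise_model must be 'negative_binomial' or 'poisson'")
        if isinstance(self.dialect, str):
            self.dialect = Dialect(self.dialect)


def _sample_counts(rng: np.random.Generator, mean: np.ndarray, design: SyntheticDesign) -> np.ndarray:
    if design.noise_model == "poisson" or design.dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / design.dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _render_csv(design: SyntheticDesign, frame: pd.DataFrame) -> str:
    """Write canonical columns under the dialect's own column names."""
    cols = dialect_registry()[design.dialect.value]["columns"]
    out = pd.DataFrame(
        {
            cols["identifier"]: frame["identifier"],
            cols["spectral_count"]: frame["spectral_count"],
            cols["score"]: frame["score"],
            cols["molecular_weight"]: frame["molecular_weight"],
        }
    )
    buf = _stdio.StringIO()
    out.to_csv(buf, index=False)
    return buf.getvalue()


def generate_dataset(
    design: SyntheticDesign, out_dir: str | Path | None = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate one dialect-conformant CSV per (state, replicate).

    Returns ``(files, ground_truth)`` where *files* maps
    ``{state}-{R#}.csv`` to CSV text (also written to *out_dir* when
    given) and *ground_truth* lists each protein's baseline mean,
    molecular weight, DE status and true fold change. Proteins with a
    sampled count of zero (or dropped out) are omitted from that
    replicate's file, as a search engine would simply not report them.
    """
    rng = np.random.default_rng(design.seed)
    idents = np.array([f"PROT{i + 1:04d}" for i in range(design.n_proteins)])
    mw = rng.uniform(*design.mw_range, size=design.n_proteins).round(2)
    baseline = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd, design.n_proteins)

    n_de = int(round(design.de_fraction * design.n_proteins))
    de_idx = rng.choice(design.n_proteins, size=n_de, replace=False)
    direction = np.zeros(design.n_proteins)
    direction[de_idx[: n_de // 2]] = 1.0
    direction[de_idx[n_de // 2:]] = -1.0
    true_fc = np.where(
        direction > 0, design.de_fold_change,
        np.where(direction < 0, 1.0 / design.de_fold_change, 1.0),
    )

    score_better = dialect_registry()[design.dialect.value]["score_better"]
    files: dict[str, str] = {}
    for state_index, (state, n_reps) in enumerate(design.states):
        mean = baseline * (true_fc if state_index > 0 else 1.0)
        for rep in range(1, n_reps + 1):
            counts = _sample_counts(rng, mean, design)
            dropped = rng.random(design.n_proteins) < design.dropout_rate
            counts = np.where(dropped, 0, counts)
            keep = counts > 0
            # nominal engine scores; better identifications for higher counts
            raw = rng.uniform(2.0, 30.0, design.n_proteins) + np.log1p(counts)
            score = np.round(-raw if score_better == "low" else raw, 2)
            frame = pd.DataFrame(
                {
                    "identifier": idents[keep],
                    "spectral_count": counts[keep].astype(int),
                    "score": score[keep],
                    "molecular_weight": mw[keep],
                }
            )
            files[format_filename(state, rep)] = _render_csv(design, frame)

    truth = pd.DataFrame(
        {
            "identifier": idents,
            "baseline_mean_spc": baseline,
            "molecular_weight": mw,
            "is_de": direction != 0,
            "direction": np.where(direction > 0, "up", np.where(direction < 0, "down", "none")),
            "true_fold_change": true_fc,
        }
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, text in files.items():
            (out_dir / name).write_text(text)
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return files, truth


def design_from_yaml(path: str | Path) -> SyntheticDesign:
    """Load a design from a YAML file mirroring the dataclass fields."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "states" in data:
        data["states"] = [tuple(s) for s in data["states"]]
    if "mw_range" in data:
        data["mw_range"] = tuple(data["mw_range"])
    return SyntheticDesign(**data)


# ------------------------------------------------------------ worked example

# Hand-sized deterministic dataset: 20 proteins, 2 states x 3 replicates.
# Columns: MW (kDa), control R1-R3 counts, stress R1-R3 counts.
# Designed cases: W01-W10 stable and reproducible; W11/W12 strongly up/down
# in stress; W13 singleton noise in control R2 only; W14 reproducible but
# below the summed-count threshold (1,1,1); W15 present in all control
# replicates but absent from one stress replicate; W16 control-only
# (unique); W17 stress-only (unique); W18 low-stringency-only in stress
# (tested as shared, not unique); W19/W20 moderate shifts.
_WORKED_EXAMPLE = [
    # ident   MW     c1  c2  c3   s1  s2  s3
    ("W01", 50.0, 20, 22, 18, 21, 19, 20),
    ("W02", 25.0, 10, 12, 11, 10, 11, 12),
    ("W03", 75.0, 30, 28, 33, 29, 31, 30),
    ("W04", 40.0, 8, 9, 7, 8, 8, 9),
    ("W05", 60.0, 15, 14, 16, 15, 16, 14),
    ("W06", 90.0, 40, 38, 42, 41, 39, 40),
    ("W07", 30.0, 6, 5, 7, 6, 6, 5),
    ("W08", 55.0, 12, 13, 11, 12, 12, 13),
    ("W09", 45.0, 9, 10, 8, 9, 9, 10),
    ("W10", 65.0, 18, 17, 19, 18, 18, 17),
    ("W11", 35.0, 5, 6, 5, 25, 28, 26),
    ("W12", 80.0, 30, 32, 31, 7, 6, 8),
    ("W13", 20.0, 0, 3, 0, 0, 0, 0),
    ("W14", 15.0, 1, 1, 1, 1, 1, 1),
    ("W15", 70.0, 10, 11, 9, 12, 0, 11),
    ("W16", 85.0, 14, 15, 13, 0, 0, 0),
    ("W17", 95.0, 0, 0, 0, 16, 14, 15),
    ("W18", 28.0, 7, 8, 6, 0, 2, 0),
    ("W19", 48.0, 10, 10, 10, 15, 16, 14),
    ("W20", 52.0, 20, 19, 21, 13, 14, 12),
]


def generate_worked_example() -> tuple[dict[str, str], pd.DataFrame]:
    """Fixed 20-protein, 2x3-replicate dataset for worked examples and tests.

    Counts are hard-coded (no RNG) so MSC survivors, NSAF values and
    t-test p-values can be checked against independent hand computation.
    Scores are deterministic functions of the counts.
    """
    design = SyntheticDesign(dialect=Dialect.GPM_XTANDEM, seed=0)
    rows = pd.DataFrame(
        _WORKED_EXAMPLE,
        columns=["identifier", "molecular_weight", "c1", "c2", "c3", "s1", "s2", "s3"],
    )
    files: dict[str, str] = {}
    for state, cols in (("control", ["c1", "c2", "c3"]), ("stress", ["s1", "s2", "s3"])):
        for rep, col in enumerate(cols, start=1):
            keep = rows[col] > 0
            frame = pd.DataFrame(
                {
                    "identifier": rows.loc[keep, "identifier"],
                    "spectral_count": rows.loc[keep, col].astype(int),
                    "score": (-2.0 - rows.loc[keep, col].astype(float)).round(2),
                    "molecular_weight": rows.loc[keep, "molecular_weight"],
                }
            )
            files[format_filename(state, rep)] = _render_csv(design, frame)
    truth = rows.rename(
        columns={
            "c1": "control_R1", "c2": "control_R2", "c3": "control_R3",
            "s1": "stress_R1", "s2": "stress_R2", "s3": "stress_R3",
        }
    )
    return files, truth
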