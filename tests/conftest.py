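import pandas as pd
import pytest

from spcquant import io as pwio
from spcquant.simulate import generate_dataset, generate_worked_example, SyntheticDesign
from spcquant.stringency import collate_state


def make_replicate(state, rep, records):
    """Build a ReplicateTable directly from (identifier, count, score, mw) tuples."""
    frame = pd.DataFrame(
        records, columns=["identifier", "spectral_count", "score", "molecular_weight"]
    ).sort_values("identifier").reset_index(drop=True)
    return pwio.ReplicateTable(
        state=state, replicate_number=rep, dialect=pwio.Dialect.GPM_XTANDEM, frame=frame
    )


def matrix_from_counts(state, counts, mw=None):
    """StateMatrix from {identifier: [count per replicate]}."""
    reps = []
    n = len(next(iter(counts.values())))
    for r in range(1, n + 1):
        recs = [
            (ident, row[r - 1], -3.0, (mw or {}).get(ident, 50.0))
            for ident, row in counts.items()
            if row[r - 1] > 0
        ]
        reps.append(make_replicate(state, r, recs))
    return collate_state(reps)


@pytest.fixture(scope="session")
def worked_example():
    """The fixed 20-protein two-state dataset plus its count/MW truth table."""
    files, truth = generate_worked_example()
    return files, truth


@pytest.fixture()
def worked_example_dir(tmp_path, worked_example):
    files, _ = worked_example
    for name, text in files.items():
        (tmp_path / name).write_text(text)
    return tmp_path


@pytest.fixture(scope="session")
def null_design():
    """Clean-null six-plus-six design: identical states, Poisson counts, no dropout."""
    def make(seed):
        return SyntheticDesign(
            states=[("control", 6), ("treatment", 6)],
            de_fraction=0.0,
            noise_model="poisson",
            dropout_rate=0.0,
            seed=seed,
        )
    return make
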