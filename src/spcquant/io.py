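"""Reading and writing of protein-identification tables.

Input files are per-replicate CSV exports from PSM search engines
(X!Tandem/GPM, MetaMorpheus, Proteome Discoverer), each listing protein
identifications with spectral counts, a search-engine score and a molecular
weight. Filenames follow the ``{state}-{R#}.csv`` convention, where the
token after the final hyphen is the replicate number.

Column names per engine live in a dialect registry (``dialects.yaml``)
mapping each engine's export header to the four canonical fields; the
registry is data, so new engine versions can be accommodated without code
changes.
"""

from __future__ import annotations

import io as _stdio
import logging
import re
import zipfile
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Dialect",
    "ReplicateTable",
    "OutputBundle",
    "parse_filename",
    "format_filename",
    "detect_dialect",
    "read_replicate_csv",
    "write_protein_table",
    "bundle_outputs",
    "dialect_registry",
]

#: canonical per-protein fields every dialect must provide
CANONICAL_FIELDS = ("identifier", "spectral_count", "score", "molecular_weight")


class Dialect(str, Enum):
    """Supported search-engine export formats."""

    GPM_XTANDEM = "gpm_xtandem"
    METAMORPHEUS = "metamorpheus"
    PROTEOME_DISCOVERER = "proteome_discoverer"


class FilenameError(ValueError):
    """Raised for input filenames not matching ``{state}-{R#}.csv``."""


class SchemaError(ValueError):
    """Raised when a CSV lacks a required column or matches no dialect."""


def dialect_registry() -> dict[str, dict]:
    """Load the dialect registry shipped with the package."""
    text = resources.files("spcquant").joinpath("dialects.yaml").read_text()
    registry = yaml.safe_load(text)
    for name, entry in registry.items():
        missing = set(CANONICAL_FIELDS) - set(entry.get("columns", {}))
        if missing:
            raise SchemaError(f"dialect registry entry {name!r} lacks fields {sorted(missing)}")
    return registry


_FILENAME_RE = re.compile(r"^(?P<state>.+)-(?P<rep>\d+)\.csv$")


def parse_filename(name: str) -> tuple[str, int]:
    """Split ``{state}-{R#}.csv`` into (state, replicate_number).

    The split is on the final hyphen, so state labels may themselves
    contain hyphens (``IAC1131-drought-3.csv`` -> ``("IAC1131-drought", 3)``).
    """
    base = Path(name).name
    if not base.lower().endswith(".csv"):
        raise FilenameError(f"input file {name!r} does not end in .csv")
    m = _FILENAME_RE.match(base)
    if m is None:
        raise FilenameError(
            f"input file {name!r} does not match the '{{state}}-{{R#}}.csv' naming convention"
        )
    state = m.group("state")
    if not state:
        raise FilenameError(f"input file {name!r} has an empty state label")
    return state, int(m.group("rep"))


def format_filename(state: str, replicate_number: int) -> str:
    """Inverse of :func:`parse_filename`."""
    return f"{state}-{replicate_number}.csv"


def detect_dialect(header_row: list[str]) -> Dialect:
    """Return the dialect whose full column signature is present in *header_row*.

    Matching is case-insensitive on stripped column names. Raises
    :class:`SchemaError` listing the expected signatures when nothing matches.
    """
    if not header_row:
        raise SchemaError("empty header row")
    header = {str(h).strip().lower() for h in header_row}
    registry = dialect_registry()
    for name in (d.value for d in Dialect):
        signature = {c.lower() for c in registry[name]["columns"].values()}
        if signature <= header:
            return Dialect(name)
    expected = {
        name: sorted(entry["columns"].values()) for name, entry in registry.items()
    }
    raise SchemaError(
        f"header {sorted(header)} matches no supported search-engine export; "
        f"expected one of these column signatures: {expected}"
    )


@dataclass
class ReplicateTable:
    """One parsed search-engine CSV: the protein list of a single replicate.

    ``frame`` holds one row per protein with the canonical columns
    ``identifier``, ``spectral_count`` (non-negative int), ``score`` and
    ``molecular_weight`` (positive; unit as given by the engine — used only
    as a relative length proxy). Identifiers are unique within a replicate.
    """

    state: str
    replicate_number: int
    dialect: Dialect
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.replicate_number < 1:
            raise ValueError("replicate_number must be a positive integer")
        if self.frame["identifier"].duplicated().any():
            raise ValueError("duplicate identifiers within a replicate")


def read_replicate_csv(
    path: str | Path,
    dialect: Dialect | None = None,
    *,
    state: str | None = None,
    replicate_number: int | None = None,
) -> ReplicateTable:
    """Parse one replicate CSV into canonical form.

    When *dialect* is ``None`` it is detected from the header. State and
    replicate number default to what :func:`parse_filename` extracts from
    the file's own name. Duplicate identifiers are merged by summing
    spectral counts and keeping the best score (direction per the dialect
    registry); rows with missing or non-positive molecular weight are
    dropped with a warning.
    """
    path = Path(path)
    if state is None or replicate_number is None:
        state, replicate_number = parse_filename(path.name)
    raw = pd.read_csv(path)
    if dialect is None:
        dialect = detect_dialect(list(raw.columns))
    entry = dialect_registry()[dialect.value]
    colmap = {c.lower(): f for f, c in entry["columns"].items()}
    lower_cols = {str(c).strip().lower(): c for c in raw.columns}
    missing = [c for c in colmap if c not in lower_cols]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing} for dialect {dialect.value}"
        )
    frame = pd.DataFrame(
        {f: raw[lower_cols[c]] for c, f in colmap.items()}
    )[list(CANONICAL_FIELDS)]

    frame["identifier"] = frame["identifier"].astype(str).str.strip()
    frame["spectral_count"] = pd.to_numeric(frame["spectral_count"], errors="coerce")
    frame["score"] = pd.to_numeric(frame["score"], errors="coerce")
    frame["molecular_weight"] = pd.to_numeric(frame["molecular_weight"], errors="coerce")

    bad_mw = frame["molecular_weight"].isna() | (frame["molecular_weight"] <= 0)
    if bad_mw.any():
        logger.warning(
            "%s: dropping %d row(s) with missing or non-positive molecular weight",
            path.name,
            int(bad_mw.sum()),
        )
        frame = frame[~bad_mw]
    frame = frame.dropna(subset=["identifier", "spectral_count"])
    frame = frame[frame["identifier"] != ""]
    if (frame["spectral_count"] < 0).any():
        raise SchemaError(f"{path.name}: negative spectral counts")
    frame["spectral_count"] = frame["spectral_count"].round().astype(int)

    if frame["identifier"].duplicated().any():
        best = "min" if entry.get("score_better", "high") == "low" else "max"
        frame = (
            frame.groupby("identifier", as_index=False, sort=False)
            .agg(
                spectral_count=("spectral_count", "sum"),
                score=("score", best),
                molecular_weight=("molecular_weight", "first"),
            )
        )
    frame = frame.sort_values("identifier", kind="stable").reset_index(drop=True)
    return ReplicateTable(
        state=state, replicate_number=replicate_number, dialect=dialect, frame=frame
    )


def load_directory(directory: str | Path) -> list[ReplicateTable]:
    """Read every ``{state}-{R#}.csv`` file found in *directory*."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".csv")
    if not files:
        raise FileNotFoundError(f"no .csv files in {directory}")
    return [read_replicate_csv(p) for p in files]


def write_protein_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a protein-level table as CSV with deterministic ordering.

    One row per protein; rows sorted ascending by identifier, columns kept
    in the order supplied (builders order per-replicate columns replicate-
    ascending). An empty table produces a header-only CSV, which is a valid
    result (e.g. an empty high-stringency set).
    """
    out = table.copy()
    if "identifier" in out.columns:
        out = out.sort_values("identifier", kind="stable")
    out.to_csv(path, index=False)


def protein_table_to_csv_bytes(table: pd.DataFrame) -> bytes:
    """Serialise a protein table exactly as :func:`write_protein_table` would."""
    buf = _stdio.StringIO()
    out = table.copy()
    if "identifier" in out.columns:
        out = out.sort_values("identifier", kind="stable")
    out.to_csv(buf, index=False)
    return buf.getvalue().encode()


@dataclass
class OutputBundle:
    """All result files of one run, keyed by relative path inside the archive.

    Top-level subfolders group files by result class (data quality,
    comparison per stream, same-same analysis, figures).
    """

    files: dict[str, bytes] = field(default_factory=dict)

    def add(self, relpath: str, content: bytes | str) -> None:
        if relpath in self.files:
            raise ValueError(f"duplicate bundle path {relpath!r}")
        self.files[relpath] = content.encode() if isinstance(content, str) else content

    def add_table(self, relpath: str, table: pd.DataFrame) -> None:
        self.add(relpath, protein_table_to_csv_bytes(table))

    def __len__(self) -> int:
        return len(self.files)


def bundle_outputs(bundle: OutputBundle, path: str | Path) -> Path:
    """Write *bundle* as a reproducible zip archive at *path*.

    Entries are stored in sorted path order with fixed timestamps so that
    identical inputs yield byte-identical archives.
    """
    if not bundle.files:
        raise ValueError("refusing to write an empty output bundle")
    path = Path(path)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for relpath in sorted(bundle.files):
            info = zipfile.ZipInfo(relpath, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, bundle.files[relpath])
    return path
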