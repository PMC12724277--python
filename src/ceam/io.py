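"""Readers, writers, and run provenance for the command-line workflow.

All tabular files are TSV (UTF-8, Unix newlines, ``.`` decimal); commas
are accepted on read via delimiter sniffing. CpG identifiers are opaque
strings, so synthetic and Illumina ``cg``-prefixed IDs interchange freely.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .panels import (
    CELL_TYPES,
    SPECIFICITY_LEVELS,
    CellTypePanel,
    PanelError,
    validate_beta_matrix,
    validate_metadata,
)

logger = logging.getLogger(__name__)


class IOError_(ValueError):
    """Raised on malformed or empty input files."""


def _sniff_sep(first_line: str) -> str:
    return "\t" if "\t" in first_line else ("," if "," in first_line else "\t")


def read_beta_matrix(path) -> pd.DataFrame:
    """TSV with first column ``cpg_id`` and one column per sample."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    df = pd.read_csv(path, sep=_sniff_sep(first), index_col=0)
    df.index.name = "cpg_id"
    return validate_beta_matrix(df)


def write_beta_matrix(betas: pd.DataFrame, path) -> None:
    betas.to_csv(path, sep="\t", index_label="cpg_id")


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    meta = pd.read_csv(path, sep=_sniff_sep(first))
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_cpg_list(path) -> set[str]:
    """One CpG ID per line, or a TSV/CSV whose first column is ``cpg_id``.

    A header row named ``cpg_id`` is auto-detected and skipped; additional
    columns are ignored; duplicates are dropped with a logged count.
    """
    path = Path(path)
    ids: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise IOError_(f"{path}: empty CpG list")
    sep = _sniff_sep(lines[0])
    start = 0
    if lines[0].split(sep)[0].strip().lower() == "cpg_id":
        start = 1
        if len(lines) == 1:
            raise IOError_(f"{path}: header only, no CpG IDs")
    n_fields = len(lines[start].split(sep))
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        fields = ln.split(sep)
        if len(fields) != n_fields:
            raise IOError_(
                f"{path}: line {lineno} has {len(fields)} fields, expected {n_fields}"
            )
        ids.append(fields[0].strip())
    unique = set(ids)
    n_dup = len(ids) - len(unique)
    if n_dup:
        logger.info("%s: %d duplicate CpG IDs deduplicated", path, n_dup)
    return unique


def write_cpg_list(cpgs, path) -> None:
    with open(path, "w") as fh:
        for c in sorted(cpgs):
            fh.write(f"{c}\n")


def read_panel(path) -> dict[str, CellTypePanel]:
    """Panel TSV (``cpg_id  cell_type  specificity``) grouped by level.

    Vocabulary is validated; high-level rows assigning one CpG to two cell
    types violate the exclusivity invariant and raise an error.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    df = pd.read_csv(path, sep=_sniff_sep(first))
    required = {"cpg_id", "cell_type", "specificity"}
    if not required.issubset(df.columns):
        raise IOError_(f"{path}: expected columns {sorted(required)}")
    for i, row in df.iterrows():
        if row["cell_type"] not in CELL_TYPES:
            raise IOError_(f"{path}: row {i + 2}: unknown cell_type {row['cell_type']!r}")
        if row["specificity"] not in SPECIFICITY_LEVELS:
            raise IOError_(
                f"{path}: row {i + 2}: unknown specificity {row['specificity']!r}"
            )
    panels = {}
    for level, sub in df.groupby("specificity"):
        assignments = {
            c: frozenset(sub.loc[sub["cell_type"] == c, "cpg_id"]) for c in CELL_TYPES
        }
        try:
            panels[level] = CellTypePanel(level, assignments)
        except PanelError as exc:
            raise IOError_(f"{path}: {exc}") from exc
    return panels


def write_panel(panels, path) -> None:
    """Write one or several CellTypePanels to the 3-column panel TSV."""
    if isinstance(panels, CellTypePanel):
        panels = {panels.specificity: panels}
    rows = []
    for level in SPECIFICITY_LEVELS:
        panel = panels.get(level)
        if panel is None:
            continue
        for cell in CELL_TYPES:
            for cpg in sorted(panel.assignments[cell]):
                rows.append((cpg, cell, level))
    pd.DataFrame(rows, columns=["cpg_id", "cell_type", "specificity"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path) -> pd.DataFrame:
    """Probe annotation TSV: ``cpg_id  probe_design  island_context  gene_context``."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    df = pd.read_csv(path, sep=_sniff_sep(first))
    required = {"cpg_id", "probe_design", "island_context", "gene_context"}
    if not required.issubset(df.columns):
        raise IOError_(f"{path}: expected columns {sorted(required)}")
    if df["cpg_id"].duplicated().any():
        raise IOError_(f"{path}: duplicate cpg_id rows")
    return df


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def write_results(results, path, json_path=None) -> None:
    """Enrichment results to TSV (and optionally a JSON mirror)."""
    from .enrich import results_to_frame

    frame = results_to_frame(results) if not isinstance(results, pd.DataFrame) else results
    frame.to_csv(path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# run provenance
# ---------------------------------------------------------------------------

def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI run's outputs."""

    command: str
    parameters: dict
    input_digests: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, parameters: dict, inputs: dict | None = None,
               seed: int | None = None) -> "RunManifest":
        from . import __version__

        digests = {name: _digest(p) for name, p in (inputs or {}).items()}
        return cls(
            command=command,
            parameters={k: v for k, v in parameters.items() if v is not None},
            input_digests=digests,
            seed=seed,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def write(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "run_manifest.json"
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
        return path
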