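"""Read-depth matrices: construction from per-base records, TSV I/O and QC.

The atomic observation is the mean per-base read depth of one bin in one
specimen.  Matrices are stored targets x specimens (rows are bins or,
after grouping, target groups); every specimen carries a batch label —
the unit within which the robust batch reference mu is computed — and a
QC flag driven by the minimum-coverage rule (20x over the region of
interest).  QC-failing specimens are excluded from batch medians but are
still scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .panel import Panel

__all__ = [
    "DepthMatrix",
    "CoverageError",
    "read_depth_matrix",
    "write_depth_matrix",
    "aggregate_per_base",
    "read_per_base_tsv",
    "qc_matrix",
]

logger = logging.getLogger(__name__)


class CoverageError(ValueError):
    """Raised for malformed depth inputs."""


@dataclass
class DepthMatrix:
    """Target x specimen read-depth matrix with batch labels and QC state."""

    values: pd.DataFrame  # rows: target/group ids, cols: specimen ids
    batch_labels: pd.Series = None  # type: ignore[assignment]
    specimen_qc_pass: pd.Series = None  # type: ignore[assignment]
    target_qc_pass: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.batch_labels is None:
            self.batch_labels = pd.Series("default", index=self.values.columns)
        if self.specimen_qc_pass is None:
            self.specimen_qc_pass = pd.Series(True, index=self.values.columns)
        if self.target_qc_pass is None:
            self.target_qc_pass = pd.Series(True, index=self.values.index)
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise CoverageError(f"duplicate specimen column {dup!r}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise CoverageError(f"duplicate target id {dup!r}")
        if (self.values.to_numpy() < 0).any():
            raise CoverageError("negative depth values")
        if not self.batch_labels.index.equals(self.values.columns):
            self.batch_labels = self.batch_labels.reindex(self.values.columns)
        if self.batch_labels.isna().any() or (self.batch_labels == "").any():
            raise CoverageError("every specimen needs a nonempty batch label")

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def target_ids(self) -> list[str]:
        return list(self.values.index)

    def subset_specimens(self, specimens: Iterable[str]) -> "DepthMatrix":
        cols = list(specimens)
        return DepthMatrix(
            values=self.values[cols].copy(),
            batch_labels=self.batch_labels[cols].copy(),
            specimen_qc_pass=self.specimen_qc_pass[cols].copy(),
            target_qc_pass=self.target_qc_pass.copy(),
        )


def write_depth_matrix(matrix: DepthMatrix, path) -> None:
    """Write TSV: '#batch' header line, then target_id + one column/specimen."""
    with open(path, "w") as fh:
        fh.write("#batch\t" + "\t".join(matrix.batch_labels[c] for c in matrix.specimen_ids) + "\n")
        fh.write("target_id\t" + "\t".join(matrix.specimen_ids) + "\n")
        for tid, row in matrix.values.iterrows():
            fh.write(tid + "\t" + "\t".join(repr(float(v)) for v in row.to_numpy()) + "\n")


def read_depth_matrix(path) -> DepthMatrix:
    """Read the depth-matrix TSV dialect written by :func:`write_depth_matrix`.

    Header row carries specimen ids (first column ``target_id``); an
    optional leading ``#batch`` line maps specimens to batches, otherwise
    every specimen lands in batch "default".
    """
    batches: list[str] | None = None
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("#batch"):
            batches = first.split("\t")[1:]
            header = fh.readline().rstrip("\n").split("\t")
        else:
            header = first.split("\t")
        specimens = header[1:]
        seen: set[str] = set()
        for s in specimens:
            if s in seen:
                raise CoverageError(f"duplicated specimen column {s!r}")
            seen.add(s)
        tids: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=3 if batches is not None else 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(specimens) + 1:
                raise CoverageError(f"{path}:{lineno}: expected {len(specimens) + 1} columns")
            vals: list[float] = []
            for col, cell in enumerate(fields[1:], start=2):
                try:
                    vals.append(float(cell))
                except ValueError as exc:
                    raise CoverageError(
                        f"{path}:{lineno}, column {col}: non-numeric cell {cell!r}"
                    ) from exc
            if fields[0] in tids:
                raise CoverageError(f"{path}:{lineno}: duplicate target id {fields[0]!r}")
            tids.append(fields[0])
            rows.append(vals)
    values = pd.DataFrame(rows, index=tids, columns=specimens, dtype=float)
    labels = pd.Series(batches if batches is not None else "default", index=specimens)
    return DepthMatrix(values=values, batch_labels=labels)


# ---------------------------------------------------------------------------
# per-base aggregation
# ---------------------------------------------------------------------------

def read_per_base_tsv(path) -> Iterator[tuple[str, int, str, float]]:
    """Yield (chrom, pos1, specimen, depth) from a samtools-depth-like TSV.

    Dialect: header ``chrom<TAB>pos<TAB>spec1<TAB>spec2...``; positions are
    1-based as in common depth dumps.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        specimens = header[2:]
        for raw in fh:
            fields = raw.rstrip("\n").split("\t")
            if not fields or not fields[0]:
                continue
            chrom, pos = fields[0], int(fields[1])
            for s, cell in zip(specimens, fields[2:]):
                yield chrom, pos, s, float(cell)


def aggregate_per_base(
    depth_records: Iterable[tuple[str, int, str, float]], panel: Panel
) -> DepthMatrix:
    """Aggregate 1-based per-base depth records into per-bin mean depth.

    A bin's value is its mean per-base depth; bases absent from the stream
    count as depth 0.  Records on chromosomes absent from the panel are
    skipped (with a logged count); the result is order-invariant in the
    record stream.
    """
    bins = panel.bins()
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {b.chrom for b in bins}:
        cbins = [b for b in bins if b.chrom == chrom]
        starts = np.array([b.start for b in cbins])
        ends = np.array([b.end for b in cbins])
        by_chrom[chrom] = (starts, ends, [b.target_id for b in cbins])

    sums: dict[str, dict[str, float]] = {}
    specimens: list[str] = []
    skipped = 0
    for chrom, pos1, specimen, depth in depth_records:
        if specimen not in sums:
            sums[specimen] = {}
            specimens.append(specimen)
        if chrom not in by_chrom:
            skipped += 1
            continue
        starts, ends, tids = by_chrom[chrom]
        pos0 = pos1 - 1
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i >= 0 and pos0 < ends[i]:
            acc = sums[specimen]
            acc[tids[i]] = acc.get(tids[i], 0.0) + depth
    if skipped:
        logger.warning("aggregate_per_base: skipped %d records off-panel", skipped)
    tids_all = [b.target_id for b in bins]
    lengths = {b.target_id: b.length for b in bins}
    values = pd.DataFrame(0.0, index=tids_all, columns=specimens)
    for s in specimens:
        for tid, total in sums[s].items():
            values.at[tid, s] = total / lengths[tid]
    return DepthMatrix(values=values)


def qc_matrix(
    matrix: DepthMatrix,
    panel: Panel | None = None,
    min_depth: float = 20.0,
    target_fraction: float = 1.0,
) -> DepthMatrix:
    """Flag specimens whose covered fraction of unmasked bins is too low.

    A specimen fails when the fraction of unmasked bins with depth >=
    ``min_depth`` falls below ``target_fraction`` (default: every bin must
    clear 20x).  Failed specimens are excluded from batch medians downstream
    but still receive scores.
    """
    if panel is not None:
        keep = [t for t in panel.bins(include_masked=False) if t.target_id in matrix.values.index]
        idx = [t.target_id for t in keep]
    else:
        idx = list(matrix.values.index)
    sub = matrix.values.loc[idx]
    frac = (sub.to_numpy() >= min_depth).mean(axis=0) if len(idx) else np.ones(len(matrix.specimen_ids))
    qc = pd.Series(frac >= target_fraction, index=matrix.values.columns)
    return replace(matrix, specimen_qc_pass=qc)
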