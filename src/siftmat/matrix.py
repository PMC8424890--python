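"""The interaction-matrix data model.

An :class:`InteractionMatrix` is an ordered concatenation of per-residue
7×9 count blocks (:class:`ResidueBlock`) — rows are ligand pharmacophore
features, columns are interaction types — together with a residue index
and a fingerprint of the geometry parameters and increment mask used to
build it (mixing matrices built under different rules is an error, not a
silent bug).

This module also houses JSON serialization (lossless round-trip), CSV
export, alignment of matrices onto a shared generic-residue-number axis,
1D linearization and the Tanimoto / Euclidean fingerprint metrics.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._tables import default_mask_spec, mask_array
from .constants import FEATURE_ROWS, INTERACTION_COLS, N_COLS, N_ROWS

logger = logging.getLogger(__name__)

FORMAT_NAME = "siftmat-matrix"
FORMAT_VERSION = 1


class MatrixError(Exception):
    pass


class CompatibilityError(MatrixError):
    """Operands built under different geometry parameters / masks."""


@dataclass
class ResidueBlock:
    """7×9 non-negative integer count block for one residue."""

    counts: np.ndarray
    residue_key: tuple[str, int, str, str]  # (chain, seqnum, icode, name)
    generic_number: str | None = None
    absent: bool = False  # set by alignment: position missing from this complex

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (N_ROWS, N_COLS):
            raise MatrixError(
                f"block {self.residue_key}: counts must be {N_ROWS}x{N_COLS}, "
                f"got {c.shape}")
        if np.issubdtype(c.dtype, np.floating):
            if not np.allclose(c, np.round(c)):
                raise MatrixError(f"block {self.residue_key}: non-integer counts")
            c = np.round(c).astype(np.int64)
        c = c.astype(np.int64)
        if (c < 0).any():
            raise MatrixError(f"block {self.residue_key}: negative counts")
        self.counts = c

    @property
    def label(self) -> str:
        """Position label: generic number when present, else chain/seqnum."""
        if self.generic_number:
            return self.generic_number
        ch, num, icode, name = self.residue_key
        return f"{ch}/{name}{num}{icode}"

    def copy(self) -> "ResidueBlock":
        return ResidueBlock(self.counts.copy(), self.residue_key,
                            self.generic_number, self.absent)


@dataclass
class InteractionMatrix:
    blocks: list[ResidueBlock]
    complex_id: str = ""
    params_fingerprint: str = "unspecified"
    mask_spec: tuple[tuple[str, tuple[str, ...]], ...] = field(
        default_factory=default_mask_spec)
    metadata: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return mask_array(self.mask_spec)

    @property
    def n_residues(self) -> int:
        return len(self.blocks)

    def stacked(self) -> np.ndarray:
        """Dense 7 × (9·N) array, blocks side by side in residue order."""
        if not self.blocks:
            return np.zeros((N_ROWS, 0), dtype=np.int64)
        return np.hstack([b.counts for b in self.blocks])

    def labels(self) -> list[str]:
        return [b.label for b in self.blocks]

    def copy(self) -> "InteractionMatrix":
        return InteractionMatrix([b.copy() for b in self.blocks], self.complex_id,
                                 self.params_fingerprint, self.mask_spec,
                                 dict(self.metadata))


# ---------------------------------------------------------------------------
# serialization

def _matrix_to_dict(matrix: InteractionMatrix) -> dict:
    return {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "complex_id": matrix.complex_id,
        "params_fingerprint": matrix.params_fingerprint,
        "mask": {row: list(cols) for row, cols in matrix.mask_spec},
        "metadata": matrix.metadata,
        "feature_rows": list(FEATURE_ROWS),
        "interaction_cols": list(INTERACTION_COLS),
        "blocks": [
            {
                "chain": b.residue_key[0],
                "seqnum": b.residue_key[1],
                "insertion_code": b.residue_key[2],
                "name": b.residue_key[3],
                "generic_number": b.generic_number,
                "absent": b.absent,
                "counts": b.counts.tolist(),
            }
            for b in matrix.blocks
        ],
    }


def _matrix_from_dict(data: dict) -> InteractionMatrix:
    if data.get("format") != FORMAT_NAME:
        raise MatrixError(f"not a {FORMAT_NAME} file (format={data.get('format')!r})")
    if data.get("version") != FORMAT_VERSION:
        raise MatrixError(
            f"unsupported matrix format version {data.get('version')!r} "
            f"(this build reads version {FORMAT_VERSION})")
    mask_spec = tuple((row, tuple(cols)) for row, cols in data["mask"].items())
    blocks = []
    for i, b in enumerate(data["blocks"]):
        counts = np.asarray(b["counts"])
        if counts.shape != (N_ROWS, N_COLS):
            raise MatrixError(
                f"block {i} ({b.get('chain')}/{b.get('name')}{b.get('seqnum')}): "
                f"bad shape {counts.shape}, expected {(N_ROWS, N_COLS)}")
        blocks.append(ResidueBlock(
            counts=counts,
            residue_key=(b["chain"], int(b["seqnum"]),
                         b.get("insertion_code", ""), b["name"]),
            generic_number=b.get("generic_number"),
            absent=bool(b.get("absent", False))))
    return InteractionMatrix(blocks=blocks, complex_id=data.get("complex_id", ""),
                             params_fingerprint=data["params_fingerprint"],
                             mask_spec=mask_spec, metadata=data.get("metadata", {}))


def write_matrix(path, matrix: InteractionMatrix) -> None:
    with open(path, "w") as fh:
        json.dump(_matrix_to_dict(matrix), fh, indent=1)


def read_matrix(path) -> InteractionMatrix:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise MatrixError(f"{path}: not valid JSON: {exc}") from exc
    return _matrix_from_dict(data)


def matrix_to_frame(matrix: InteractionMatrix) -> pd.DataFrame:
    """Flat tabular view: rows = feature types, columns = residue ×
    interaction type (spreadsheet-friendly export)."""
    columns = pd.MultiIndex.from_tuples(
        [(b.label, col) for b in matrix.blocks for col in INTERACTION_COLS],
        names=["residue", "interaction"])
    return pd.DataFrame(matrix.stacked(), index=list(FEATURE_ROWS), columns=columns)


def write_matrix_csv(path, matrix: InteractionMatrix) -> None:
    matrix_to_frame(matrix).to_csv(path)


# ---------------------------------------------------------------------------
# generic-number alignment

_GENERIC_RE = re.compile(r"^(\d+)x(\d+)$")


def generic_sort_key(label: str) -> tuple:
    """Sort key for GPCRdb labels: (helix, position), with bulge labels
    (three digits, e.g. 5x461) interleaved between their two-digit
    neighbours (5x46 < 5x461 < 5x47)."""
    m = _GENERIC_RE.match(label)
    if not m:
        return (1, 0, 0, label)  # non-conforming labels sort after, by text
    helix, pos = int(m.group(1)), int(m.group(2))
    if pos < 100:
        pos *= 10
    return (0, helix, pos, label)


def align_by_generic(matrices: list[InteractionMatrix]) -> list[InteractionMatrix]:
    """Re-index matrices onto the sorted union of their generic numbers.

    Blocks lacking a generic number are dropped from the alignment
    (with a warning); positions missing from a given matrix are filled
    with all-zero blocks flagged ``absent`` (distinct from observed
    zero).  The operation is idempotent and invariant to input order.
    """
    fingerprints = {m.params_fingerprint for m in matrices}
    if len(fingerprints) > 1:
        raise CompatibilityError(
            f"cannot align matrices with different parameter fingerprints: "
            f"{sorted(fingerprints)}")
    per_matrix: list[dict[str, ResidueBlock]] = []
    for m in matrices:
        by_generic: dict[str, ResidueBlock] = {}
        for b in m.blocks:
            if not b.generic_number:
                logger.warning("%s: residue %s has no generic number; "
                               "dropped from alignment", m.complex_id, b.label)
                continue
            if b.generic_number in by_generic:
                raise MatrixError(
                    f"{m.complex_id}: duplicate generic number {b.generic_number}")
            by_generic[b.generic_number] = b
        per_matrix.append(by_generic)

    axis = sorted({g for d in per_matrix for g in d}, key=generic_sort_key)
    aligned = []
    for m, by_generic in zip(matrices, per_matrix):
        blocks = []
        for g in axis:
            if g in by_generic:
                # pass-through keeps an existing absent flag (idempotence)
                blk = by_generic[g].copy()
            else:
                blk = ResidueBlock(np.zeros((N_ROWS, N_COLS), dtype=np.int64),
                                   residue_key=("", 0, "", ""),
                                   generic_number=g, absent=True)
            blocks.append(blk)
        aligned.append(InteractionMatrix(blocks, m.complex_id,
                                         m.params_fingerprint, m.mask_spec))
    return aligned


# ---------------------------------------------------------------------------
# 1D linearization and fingerprint metrics

@dataclass
class LinearFingerprint:
    values: np.ndarray
    binary: bool
    index_map: list[tuple[str, str, str]]  # (position label, feature row, column)
    params_fingerprint: str = "unspecified"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != len(self.index_map):
            raise MatrixError("fingerprint values and index_map lengths differ")
        if (v < 0).any():
            raise MatrixError("fingerprint values must be non-negative")
        if self.binary and not np.isin(v, (0.0, 1.0)).all():
            raise MatrixError("binary fingerprint with values outside {0, 1}")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)

    def nonzero_positions(self) -> set[tuple[str, str, str]]:
        return {self.index_map[i] for i in np.nonzero(self.values)[0]}


def _mask_cells(mask: np.ndarray) -> list[tuple[int, int]]:
    return [(r, c) for r in range(N_ROWS) for c in range(N_COLS) if mask[r, c]]


def linearize_blocks(values_per_block: list[np.ndarray], labels: list[str],
                     mask: np.ndarray, binary: bool,
                     params_fingerprint: str = "unspecified") -> LinearFingerprint:
    """Flatten block values (int or real) over the incrementable cells,
    traversed in (block, row, column) order."""
    cells = _mask_cells(mask)
    out, index_map = [], []
    for label, block in zip(labels, values_per_block):
        for r, c in cells:
            v = float(block[r, c])
            out.append(1.0 if (binary and v > 0) else v)
            index_map.append((label, FEATURE_ROWS[r], INTERACTION_COLS[c]))
    return LinearFingerprint(np.array(out), binary, index_map, params_fingerprint)


def to_linear(matrix: InteractionMatrix, binary: bool = True) -> LinearFingerprint:
    """Linear fingerprint of a matrix: all incrementable cells in
    (residue, feature row, interaction column) order; binary mode maps
    every positive count to 1."""
    return linearize_blocks([b.counts for b in matrix.blocks], matrix.labels(),
                            matrix.mask, binary, matrix.params_fingerprint)


def _check_compatible(a: LinearFingerprint, b: LinearFingerprint) -> None:
    if len(a) != len(b):
        raise CompatibilityError(
            f"fingerprint lengths differ ({len(a)} vs {len(b)}; params "
            f"{a.params_fingerprint} vs {b.params_fingerprint})")


def tanimoto(a: LinearFingerprint, b: LinearFingerprint) -> float:
    """Tanimoto similarity |a∧b| / |a∨b| of two binary fingerprints.

    Two all-zero fingerprints compare as identical (1.0 by convention).
    """
    if not (a.binary and b.binary):
        raise MatrixError("tanimoto requires binary fingerprints")
    _check_compatible(a, b)
    av, bv = a.values > 0, b.values > 0
    union = np.logical_or(av, bv).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(av, bv).sum() / union)


def euclidean(a: LinearFingerprint, b: LinearFingerprint) -> float:
    """Euclidean distance between (count- or real-valued) fingerprints."""
    _check_compatible(a, b)
    return float(np.linalg.norm(a.values - b.values))
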