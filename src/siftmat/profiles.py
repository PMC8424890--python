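"""Interaction profiles over collections of matrices.

A profile is the cellwise mean of a collection of aligned interaction
matrices with sub-threshold values silenced (set to exactly 0) to
expose the dominant consensus binding mode.  On top of profiles this
module provides per-position contact frequencies, hotspot extraction
(positions contacted in more than a given fraction of the structures),
signed differential profiles between two collections (e.g. agonist-
vs antagonist-bound complexes) and an outlier ranking of individual
complexes against a profile.

Thresholds follow strict conventions: silencing removes values
strictly *lower than* the threshold (a mean of exactly 0.3 survives
the default 0.3), while the hotspot filter keeps positions with
frequency strictly *greater than* the cutoff (exactly 30% is excluded
at the default 0.30).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._tables import mask_array
from .constants import FEATURE_ROWS, INTERACTION_COLS, N_COLS, N_ROWS
from .matrix import (CompatibilityError, InteractionMatrix, LinearFingerprint,
                     MatrixError, euclidean, generic_sort_key, linearize_blocks)

PROFILE_FORMAT = "siftmat-profile"
PROFILE_VERSION = 1

#: numerical guard for the strict "lower than" silencing comparison
_SILENCE_EPS = 1e-12

#: interaction-column -> category labels used in summary tables
#: (with the conventional display colors)
CATEGORY_BY_COLUMN = {
    "C": ("charged", "#9467bd"),       # purple
    "A": ("hb_acceptor", "#e6c229"),   # yellow
    "D": ("hb_donor", "#1f77b4"),      # blue
    "H": ("hydrophobic", "#2ca02c"),   # green
    "R": ("aromatic", "#ff7f0e"),      # orange
    "Any": ("any", "#7f7f7f"),         # gray
    "P": ("polar", "#17becf"),
}


def _check_aligned(matrices: list[InteractionMatrix]) -> list[str]:
    if not matrices:
        raise MatrixError("need at least one matrix")
    fingerprints = {m.params_fingerprint for m in matrices}
    if len(fingerprints) > 1:
        raise CompatibilityError(
            f"matrices built under different parameters: {sorted(fingerprints)}")
    axis = matrices[0].labels()
    for m in matrices[1:]:
        if m.labels() != axis:
            raise MatrixError(
                "matrices are not aligned on a common position axis; "
                "run align_by_generic first")
    return axis


def silence(values: np.ndarray, threshold: float) -> np.ndarray:
    """Zero all values strictly lower than ``threshold`` (idempotent)."""
    out = np.asarray(values, dtype=float).copy()
    out[out < threshold - _SILENCE_EPS] = 0.0
    return out


@dataclass
class InteractionProfile:
    positions: list[str]
    values: list[np.ndarray]           # per position, 7x9 real block
    support: list[int]                 # per position, contributing matrices
    threshold: float
    denominator_mode: str              # all_matrices | present_only
    n_matrices: int
    params_fingerprint: str = "unspecified"
    mask_spec: tuple = ()
    complex_ids: list[str] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        return mask_array(self.mask_spec)

    def block(self, position: str) -> np.ndarray:
        return self.values[self.positions.index(position)]

    def to_linear(self) -> LinearFingerprint:
        return linearize_blocks(self.values, self.positions, self.mask,
                                binary=False,
                                params_fingerprint=self.params_fingerprint)


def average_profile(matrices: list[InteractionMatrix], threshold: float = 0.3,
                    denominator_mode: str = "all_matrices") -> InteractionProfile:
    """Cellwise mean of an aligned collection, then silencing.

    ``all_matrices`` divides by the collection size (a position absent
    from a complex counts as non-interacting); ``present_only`` divides
    by the number of complexes actually containing the position.
    """
    if denominator_mode not in ("all_matrices", "present_only"):
        raise ValueError("denominator_mode must be 'all_matrices' or 'present_only'")
    axis = _check_aligned(matrices)
    n = len(matrices)
    values, support = [], []
    for i in range(len(axis)):
        blocks = [m.blocks[i] for m in matrices]
        present = [b for b in blocks if not b.absent]
        total = np.sum([b.counts for b in present], axis=0) if present \
            else np.zeros((N_ROWS, N_COLS))
        denom = n if denominator_mode == "all_matrices" else max(len(present), 1)
        values.append(silence(total / denom, threshold))
        support.append(len(present))
    return InteractionProfile(
        positions=axis, values=values, support=support, threshold=threshold,
        denominator_mode=denominator_mode, n_matrices=n,
        params_fingerprint=matrices[0].params_fingerprint,
        mask_spec=tuple(matrices[0].mask_spec),
        complex_ids=[m.complex_id for m in matrices])


# ---------------------------------------------------------------------------
# contact frequency and hotspots

@dataclass
class FrequencyTable:
    positions: list[str]
    fractions: dict[str, float]            # position -> contact fraction
    cell_fractions: dict[str, np.ndarray]  # position -> 7x9 per-cell fraction
    n_matrices: int
    denominator_mode: str

    def dominant_labels(self, min_fraction: float = 0.3
                        ) -> dict[str, list[tuple[str, str, str, float]]]:
        """Per position: (feature row, column, category, frequency) for
        every specific cell whose frequency exceeds ``min_fraction``."""
        out: dict[str, list[tuple[str, str, str, float]]] = {}
        for pos in self.positions:
            cells = []
            cf = self.cell_fractions[pos]
            for r in range(N_ROWS):
                for c in range(N_COLS):
                    col = INTERACTION_COLS[c]
                    if col in ("BB", "SC", "Any", "P"):
                        continue  # region / aggregate columns are not categories
                    if cf[r, c] > min_fraction:
                        cells.append((FEATURE_ROWS[r], col,
                                      CATEGORY_BY_COLUMN[col][0], float(cf[r, c])))
            out[pos] = sorted(cells, key=lambda t: -t[3])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        labels = self.dominant_labels()
        for pos in self.positions:
            rows.append({
                "position": pos,
                "contact_fraction": self.fractions[pos],
                "dominant_interactions": ";".join(
                    f"{r}-{c}:{cat}" for r, c, cat, _ in labels[pos]),
            })
        return pd.DataFrame(rows)

    def to_html(self, min_fraction: float = 0.3) -> str:
        """Colored summary table (one row per position; interaction
        categories rendered with the conventional color legend)."""
        labels = self.dominant_labels(min_fraction)
        parts = ["<table border='1'><tr><th>position</th>"
                 "<th>contact fraction</th><th>interactions</th></tr>"]
        for pos in self.positions:
            chips = "".join(
                f"<span style='background:{CATEGORY_BY_COLUMN[col][1]};"
                f"padding:2px;margin:1px'>{row}-{col} {cat}</span>"
                for row, col, cat, _ in labels[pos])
            parts.append(f"<tr><td>{pos}</td>"
                         f"<td>{self.fractions[pos]:.3f}</td><td>{chips}</td></tr>")
        parts.append("</table><p>Legend: " + ", ".join(
            f"<span style='background:{color};padding:2px'>{name}</span>"
            for name, color in CATEGORY_BY_COLUMN.values()) + "</p>")
        return "\n".join(parts)


def contact_frequency(matrices: list[InteractionMatrix],
                      denominator_mode: str = "all_matrices") -> FrequencyTable:
    """Fraction of complexes in which each position interacts (any
    nonzero cell of its block), plus per-cell frequencies."""
    axis = _check_aligned(matrices)
    n = len(matrices)
    fractions, cell_fractions = {}, {}
    for i, pos in enumerate(axis):
        blocks = [m.blocks[i] for m in matrices]
        present = [b for b in blocks if not b.absent]
        denom = n if denominator_mode == "all_matrices" else max(len(present), 1)
        hit = sum(1 for b in present if b.counts.any())
        fractions[pos] = hit / denom
        cell_hits = np.sum([b.counts > 0 for b in present], axis=0) if present \
            else np.zeros((N_ROWS, N_COLS))
        cell_fractions[pos] = cell_hits / denom
    return FrequencyTable(positions=axis, fractions=fractions,
                          cell_fractions=cell_fractions, n_matrices=n,
                          denominator_mode=denominator_mode)


def hotspots(freq: FrequencyTable, min_fraction: float = 0.30) -> list[str]:
    """Positions with contact fraction strictly greater than
    ``min_fraction``, sorted by descending fraction then position."""
    keep = [p for p in freq.positions if freq.fractions[p] > min_fraction]
    return sorted(keep, key=lambda p: (-freq.fractions[p], generic_sort_key(p)))


# ---------------------------------------------------------------------------
# differential profiles and outliers

@dataclass
class DifferentialProfile:
    positions: list[str]
    classification: dict[str, str]   # common | unique_to_a | unique_to_b | neither
    differences: list[np.ndarray]    # per position, signed a - b block
    threshold_a: float
    threshold_b: float

    def block(self, position: str) -> np.ndarray:
        return self.differences[self.positions.index(position)]


def differential_profile(a: InteractionProfile,
                         b: InteractionProfile) -> DifferentialProfile:
    """Signed comparison of two profiles on the same axis: per position
    a membership classification (driven by nonzero support after
    silencing) and per cell the difference a − b."""
    if a.positions != b.positions:
        raise MatrixError("profiles are not on the same position axis")
    if a.params_fingerprint != b.params_fingerprint:
        raise CompatibilityError(
            f"profiles built under different parameters: "
            f"{a.params_fingerprint} vs {b.params_fingerprint}")
    classification, diffs = {}, []
    for pos, va, vb in zip(a.positions, a.values, b.values):
        in_a, in_b = bool(va.any()), bool(vb.any())
        classification[pos] = ("common" if in_a and in_b else
                               "unique_to_a" if in_a else
                               "unique_to_b" if in_b else "neither")
        diffs.append(va - vb)
    return DifferentialProfile(positions=list(a.positions),
                               classification=classification, differences=diffs,
                               threshold_a=a.threshold, threshold_b=b.threshold)


def outlier_scan(matrices: list[InteractionMatrix],
                 profile: InteractionProfile) -> list[tuple[str, float]]:
    """Rank complexes by Euclidean distance between their count-valued
    linearization and the profile's (descending; ties broken by
    complex id)."""
    axis = _check_aligned(matrices)
    if axis != profile.positions:
        raise MatrixError("matrices and profile are not on the same axis")
    pl = profile.to_linear()
    scored = []
    for m in matrices:
        ml = linearize_blocks([b.counts for b in m.blocks], m.labels(), m.mask,
                              binary=False, params_fingerprint=m.params_fingerprint)
        scored.append((m.complex_id, euclidean(ml, pl)))
    return sorted(scored, key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# profile serialization

def write_profile(path, profile: InteractionProfile) -> None:
    data = {
        "format": PROFILE_FORMAT,
        "version": PROFILE_VERSION,
        "threshold": profile.threshold,
        "denominator_mode": profile.denominator_mode,
        "n_matrices": profile.n_matrices,
        "params_fingerprint": profile.params_fingerprint,
        "mask": {row: list(cols) for row, cols in profile.mask_spec},
        "complex_ids": profile.complex_ids,
        "positions": [
            {"label": pos, "support": sup, "values": val.tolist()}
            for pos, sup, val in zip(profile.positions, profile.support,
                                     profile.values)
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_profile(path) -> InteractionProfile:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("format") != PROFILE_FORMAT:
        raise MatrixError(f"not a {PROFILE_FORMAT} file")
    if data.get("version") != PROFILE_VERSION:
        raise MatrixError(f"unsupported profile version {data.get('version')!r}")
    positions = [p["label"] for p in data["positions"]]
    values = [np.asarray(p["values"], dtype=float) for p in data["positions"]]
    for pos, v in zip(positions, values):
        if v.shape != (N_ROWS, N_COLS):
            raise MatrixError(f"profile position {pos}: bad block shape {v.shape}")
    return InteractionProfile(
        positions=positions, values=values,
        support=[int(p["support"]) for p in data["positions"]],
        threshold=float(data["threshold"]),
        denominator_mode=data["denominator_mode"],
        n_matrices=int(data["n_matrices"]),
        params_fingerprint=data["params_fingerprint"],
        mask_spec=tuple((row, tuple(cols)) for row, cols in data["mask"].items()),
        complex_ids=list(data.get("complex_ids", [])))
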