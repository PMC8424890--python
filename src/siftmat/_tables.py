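"""Loading of the bundled data tables (residue knowledge, feature
SMARTS definitions, increment mask) with optional user overrides."""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .constants import COL_INDEX, FEATURE_ROWS, N_COLS, N_ROWS, ROW_INDEX


def _data_text(name: str) -> str:
    return resources.files("siftmat.data").joinpath(name).read_text()


@functools.lru_cache(maxsize=None)
def residue_tables(path: str | None = None) -> dict:
    """Residue-side tables: classes, aliases, donor/acceptor/charged/
    aromatic/polar atom names.  ``path`` overrides the bundled file."""
    text = Path(path).read_text() if path else _data_text("residues.yaml")
    tables = yaml.safe_load(text)
    required = {"classes", "aliases", "donors", "acceptors",
                "charged_group", "aromatic_rings", "polar_sidechain"}
    missing = required - set(tables)
    if missing:
        raise ValueError(f"residue table file missing sections: {sorted(missing)}")
    return tables


def parse_feature_definitions(text: str) -> dict[str, list[tuple[str, str]]]:
    """Parse the feature-definition format into
    {feature letter: [(pattern name, SMARTS), ...]}."""
    defs: dict[str, list[tuple[str, str]]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(
                f"feature definition line {lineno}: expected "
                f"'<type> <name> <SMARTS>', got {raw!r}")
        ftype, name, smarts = parts
        if ftype not in FEATURE_ROWS or ftype == "vdW":
            raise ValueError(
                f"feature definition line {lineno}: unknown feature type {ftype!r}")
        defs.setdefault(ftype, []).append((name, smarts))
    return defs


@functools.lru_cache(maxsize=None)
def feature_definitions(path: str | None = None) -> dict[str, list[tuple[str, str]]]:
    text = Path(path).read_text() if path else _data_text("features.txt")
    return parse_feature_definitions(text)


@functools.lru_cache(maxsize=None)
def default_mask_spec(path: str | None = None) -> tuple[tuple[str, tuple[str, ...]], ...]:
    text = Path(path).read_text() if path else _data_text("increment_mask.yaml")
    spec = yaml.safe_load(text)
    return tuple((row, tuple(cols)) for row, cols in spec.items())


def mask_array(spec: tuple[tuple[str, tuple[str, ...]], ...]) -> np.ndarray:
    """Boolean 7x9 array from a {row: [columns]} mask specification."""
    mask = np.zeros((N_ROWS, N_COLS), dtype=bool)
    for row, cols in spec:
        if row not in ROW_INDEX:
            raise ValueError(f"unknown feature row in mask: {row!r}")
        for col in cols:
            if col not in COL_INDEX:
                raise ValueError(f"unknown interaction column in mask: {col!r}")
            mask[ROW_INDEX[row], COL_INDEX[col]] = True
    return mask
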