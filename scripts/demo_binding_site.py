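#!/usr/bin/env python
"""Demonstration workflow for a receptor crystal-structure collection.

This script documents how to run the hotspot / differential-profile
analysis on real structures.  It needs data you supply yourself —
prepared (protonated) PDB files, ligand MOL/SDF blocks, and a
generic-residue-number annotation CSV per receptor, e.g. as exported
from GPCRdb.  Nothing is downloaded and nothing here is part of the
test suite.

Expected layout (one directory per complex):

    data/
      2rh1/complex.pdb   2rh1/ligand.mol   2rh1/generic.csv
      3sn6/complex.pdb   ...

Usage:
    python scripts/demo_binding_site.py data/ --group-a 2rh1,... \
        --group-b 3sn6,... --out results_demo/
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

from siftmat import (attach_generic_numbers, average_profile, build_matrix,
                     contact_frequency, differential_profile, hotspots,
                     parse_complex, read_annotation_csv)
from siftmat.matrix import align_by_generic, write_matrix
from siftmat.profiles import write_profile
from siftmat.viz import RenderSpec, render_heatmap


def load_matrix(directory: Path):
    pdb = (directory / "complex.pdb").read_text()
    ligand = (directory / "ligand.mol").read_text()
    cx = parse_complex(pdb, ligand_block=ligand, identifier=directory.name)
    annotation_path = directory / "generic.csv"
    if annotation_path.exists():
        attach_generic_numbers(cx, read_annotation_csv(annotation_path))
    return build_matrix(cx)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("root", type=Path, help="directory of complexes")
    parser.add_argument("--group-a", default="", help="comma-separated ids")
    parser.add_argument("--group-b", default="", help="comma-separated ids")
    parser.add_argument("--out", type=Path, default=Path("results_demo"))
    args = parser.parse_args()

    dirs = sorted(d for d in args.root.iterdir() if d.is_dir())
    if not dirs:
        print(f"no complex directories under {args.root}", file=sys.stderr)
        return 1
    args.out.mkdir(parents=True, exist_ok=True)

    matrices = []
    for d in dirs:
        m = load_matrix(d)
        write_matrix(args.out / f"{d.name}.json", m)
        matrices.append(m)
    aligned = align_by_generic(matrices)

    # consensus binding site: contact frequencies and hotspots
    freq = contact_frequency(aligned)
    freq.to_frame().to_csv(args.out / "frequency.csv", index=False)
    (args.out / "frequency.html").write_text(freq.to_html())
    print("hotspot positions (contacted in >30% of structures):")
    for pos in hotspots(freq, 0.30):
        print(f"  {pos}\t{freq.fractions[pos]:.2f}")

    prof = average_profile(aligned, threshold=0.3)
    write_profile(args.out / "profile.json", prof)
    render_heatmap(prof, args.out / "profile.png")

    # optional two-group comparison (e.g. agonist- vs antagonist-bound)
    ids_a = {s for s in args.group_a.split(",") if s}
    ids_b = {s for s in args.group_b.split(",") if s}
    if ids_a and ids_b:
        pa = average_profile([m for m in aligned if m.complex_id in ids_a])
        pb = average_profile([m for m in aligned if m.complex_id in ids_b])
        diff = differential_profile(pa, pb)
        render_heatmap(diff, args.out / "differential.png",
                       RenderSpec(color_mode="diff_red_blue"))
        for pos, cls in diff.classification.items():
            if cls != "neither":
                print(f"  {pos}\t{cls}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
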