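#!/usr/bin/env python
"""Opt-in checks against real toxin/channel structures (local PDB files).

These analyses need experimentally determined coordinates that are not
bundled with the package: a PcTx1-channel complex (e.g. PDB 4FZ0), free
toxin NMR structures (e.g. 2KNI for PcTx1, 2WH9 for GxTx-1E). Download
them yourself and point this script at the files:

    python scripts/external_structure_check.py \
        --complex 4fz0.pdb --toxin-chain <chain> \
        [--free-pctx1 2kni.pdb --free-gxtx 2wh9.pdb]

It reports, per available input:

* the per-residue Delta-SASA footprint of the toxin on the channel
  (1.4 A probe) with the top-ranked residues,
* cystine C-alpha superposition RMSD between the two free toxins for a
  user-supplied residue selection (--cys-a/--cys-b, comma-separated
  residue numbers),
* hydrophobic patch area for a user-supplied residue set
  (--patch-residues).

Exact published patch areas depend on the original authors' residue
selections, which are not enumerated anywhere; treat those comparisons
as qualitative.
"""

from __future__ import annotations

import argparse

import numpy as np

from paddleclamp import structmap as sm


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--complex", help="toxin-channel complex PDB file")
    ap.add_argument("--toxin-chain", default="B")
    ap.add_argument("--free-pctx1")
    ap.add_argument("--free-gxtx")
    ap.add_argument("--cys-a", help="cystine CA residue ids in structure A, e.g. 3,18,21")
    ap.add_argument("--cys-b", help="matched residue ids in structure B")
    ap.add_argument("--patch-pdb", help="structure for the hydrophobic-patch area")
    ap.add_argument("--patch-chain", default="A")
    ap.add_argument("--patch-residues", help="comma-separated residue ids")
    ap.add_argument("--probe", type=float, default=1.4)
    ap.add_argument("--points", type=int, default=960)
    args = ap.parse_args()

    if args.complex:
        atoms = sm.read_structure(args.complex)
        rep = sm.delta_sasa(atoms, [args.toxin_chain], args.probe, args.points)
        print("Top Delta-SASA residues (toxin footprint):")
        print(rep.top_residues(8).to_string(index=False))
        print(f"total buried area: {rep.total:.1f} A^2")

    if args.free_pctx1 and args.free_gxtx and args.cys_a and args.cys_b:
        a = sm.read_structure(args.free_pctx1)
        b = sm.read_structure(args.free_gxtx)
        ids_a = [int(x) for x in args.cys_a.split(",")]
        ids_b = [int(x) for x in args.cys_b.split(",")]
        ca_a = a[(a.atom_name == "CA") & (np.isin(a.res_id, ids_a))].coord
        ca_b = b[(b.atom_name == "CA") & (np.isin(b.res_id, ids_b))].coord
        _, rmsd = sm.kabsch_superpose(ca_b, ca_a)
        print(f"cystine C-alpha superposition RMSD: {rmsd:.2f} A")

    if args.patch_pdb and args.patch_residues:
        atoms = sm.read_structure(args.patch_pdb)
        sel = atoms[atoms.chain_id == args.patch_chain]
        rep = sm.shrake_rupley_sasa(sel, args.probe, args.points)
        ids = [int(x) for x in args.patch_residues.split(",")]
        area = sm.hydrophobic_patch_area(sel, ids, rep)
        print(f"largest connected hydrophobic patch: {area:.0f} A^2")


if __name__ == "__main__":
    main()
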