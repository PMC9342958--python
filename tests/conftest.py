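"""Shared fixtures: simulated monomer control, negative gate, PDB writer."""

from __future__ import annotations

import numpy as np
import pytest

from nucleokit import damfret
from nucleokit import synthetic_cytometry as syn

THREE_LETTER = {
    "A": "ALA", "G": "GLY", "V": "VAL", "L": "LEU", "S": "SER", "T": "THR",
    "K": "LYS", "R": "ARG", "D": "ASP", "E": "GLU", "F": "PHE", "I": "ILE",
    "N": "ASN", "Q": "GLN", "Y": "TYR", "W": "TRP", "M": "MET", "P": "PRO",
    "H": "HIS", "C": "CYS",
}


@pytest.fixture(scope="session")
def monomer_control() -> "syn.EventTable":
    return syn.simulate_population(
        syn.PopulationParams(n_cells=200_000, archetype="monomer", rng_seed=990)
    )


@pytest.fixture(scope="session")
def negative_gate(monomer_control):
    return damfret.build_negative_gate(monomer_control)


def write_ca_pdb(path, coords, seq, chain="A", start=1, altlocs=None, skip_ca=()):
    """Write a minimal C-alpha-only PDB file for structure tests.

    ``altlocs`` maps residue index -> list of (altloc, coord) to emit extra
    conformers; ``skip_ca`` lists residue indices written without a CA atom.
    """
    lines = []
    serial = 1
    for i, (c, aa) in enumerate(zip(coords, seq)):
        resname = THREE_LETTER[aa]
        resnum = start + i
        if i in skip_ca:
            lines.append(
                f"ATOM  {serial:5d}  N   {resname} {chain}{resnum:4d}    "
                f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}  1.00  0.00           N"
            )
            serial += 1
            continue
        variants = altlocs.get(i) if altlocs else None
        if variants:
            for alt, cc in variants:
                lines.append(
                    f"ATOM  {serial:5d}  CA {alt}{resname} {chain}{resnum:4d}    "
                    f"{cc[0]:8.3f}{cc[1]:8.3f}{cc[2]:8.3f}  0.50  0.00           C"
                )
                serial += 1
        else:
            lines.append(
                f"ATOM  {serial:5d}  CA  {resname} {chain}{resnum:4d}    "
                f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}  1.00  0.00           C"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def ca_pdb_writer():
    return write_ca_pdb
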