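"""Shared fixtures: in-memory gemmi structures and small labeled sets."""

from __future__ import annotations

import gemmi
import numpy as np
import pytest

from metbind import PropertyTable, SynthSpec
from metbind.dataset import CANONICAL_AA


def build_structure(
    chains: dict[str, list[tuple[str, str, tuple[float, float, float]]]],
    hetero: list[tuple[str, list[tuple[str, str, tuple[float, float, float]]]]] = (),
    name: str = "TEST",
) -> gemmi.Structure:
    """Assemble a gemmi structure from plain tuples.

    ``chains`` maps chain id -> list of (residue_name, atom_element, xyz);
    each tuple becomes one single-atom residue.  ``hetero`` lists
    (residue_name, [(atom_name, element, xyz), ...]) appended as HETATM
    residues on chain 'Z'.
    """
    structure = gemmi.Structure()
    structure.name = name
    model = gemmi.Model("1")
    for chain_id, residues in chains.items():
        chain = gemmi.Chain(chain_id)
        for i, (res_name, element, xyz) in enumerate(residues):
            residue = gemmi.Residue()
            residue.name = res_name
            residue.seqid = gemmi.SeqId(i + 1, " ")
            residue.het_flag = "A"
            atom = gemmi.Atom()
            atom.name = "CA" if element == "C" else element.upper()
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    if hetero:
        chain = gemmi.Chain("Z")
        for j, (res_name, atoms) in enumerate(hetero):
            residue = gemmi.Residue()
            residue.name = res_name
            residue.seqid = gemmi.SeqId(100 + j, " ")
            residue.het_flag = "H"
            for atom_name, element, xyz in atoms:
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(element)
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    structure.add_model(model)
    return structure


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


@pytest.fixture(scope="session")
def property_table() -> PropertyTable:
    return PropertyTable.default()


@pytest.fixture(scope="session")
def small_spec() -> SynthSpec:
    return SynthSpec(seed=11, n_pos=60, n_neg=60, length_range=(60, 90))
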