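"""Structure-derived metal-binding labels.

A protein chain is called metal-binding when at least one of its heavy
(non-hydrogen, non-deuterium) atoms lies within a distance cutoff
(default 5.0 Å, inclusive) of a metal atom.  Metals are grouped into
element classes regardless of oxidation state or chemical context: the
iron of a heme or an Fe–S cluster counts as Fe, Zn(2+) is simply Zn.
Labels are assigned per chain so that, in a heteromeric structure, only
the chains actually contacting the metal are positives; all remaining
chains, and every chain of a metal-free structure, are negatives.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: Metal element classes handled by default. Oxidation states are ignored.
DEFAULT_ION_SET = frozenset(
    {"Na", "K", "Ca", "Mg", "Mn", "Fe", "Co", "Cu", "Ni", "Zn"}
)

#: Fixed ion ordering used for feature blocks and metal profiles.
ION_ORDER: tuple[str, ...] = ("Ca", "Co", "Cu", "Fe", "K", "Mg", "Mn", "Na", "Ni", "Zn")

#: Contact distance cutoff in Å; the boundary is inclusive (<=).
DEFAULT_CUTOFF = 5.0

_HYDROGEN = frozenset({"H", "D"})


@dataclass(frozen=True)
class Atom:
    """A single atom of a polymer chain.

    ``residue_index`` is the 0-based position of the parent residue in the
    chain sequence, used to locate contact residues for k-mer extraction.
    """

    element: str
    coords: tuple[float, float, float]
    is_heavy: bool
    residue_index: int = -1

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("Atom element must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError("Atom coordinates must be finite")


@dataclass(frozen=True)
class MetalSite:
    """A metal-containing ligand reduced to its metal atoms.

    ``coords`` holds one (x, y, z) row per metal atom of the ligand, so a
    4Fe–4S cluster contributes a single Fe-class site with four positions.
    """

    ion: str
    ligand_code: str
    coords: tuple[tuple[float, float, float], ...]


@dataclass
class LigandMap:
    """Mapping from ligand chemistry to metal element classes.

    ``entries`` maps specific ligand component codes (e.g. heme ``HEM``)
    to an ion class; ``element_fallback`` maps bare metal element symbols,
    which also resolves the metal atoms inside otherwise unlisted
    multi-atom ligands.
    """

    entries: dict[str, str] = field(default_factory=dict)
    element_fallback: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls, ion_set: Iterable[str] = DEFAULT_ION_SET) -> "LigandMap":
        ions = set(ion_set)
        fallback = {ion: ion for ion in ions}
        # Common iron prosthetic groups; all belong to the Fe class.
        entries = {}
        if "Fe" in ions:
            for code in ("HEM", "HEC", "HEA", "HEB", "HDD", "SRM", "DHE",
                         "SF4", "FES", "F3S", "FS4", "CLF", "HFE"):
                entries[code] = "Fe"
        return cls(entries=entries, element_fallback=fallback)

    def ion_for(self, ligand_code: str, element: str) -> str | None:
        """Resolve the ion class for a metal atom, or None if unmapped."""
        if ligand_code in self.entries:
            return self.entries[ligand_code]
        return self.element_fallback.get(element)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LigandMap":
        """Read a 3-column TSV (ligand_code, element, ion_class).

        Rows with an empty or ``*`` ligand_code define element fallbacks.
        """
        entries: dict[str, str] = {}
        fallback: dict[str, str] = {}
        with open(path, newline="") as handle:
            for row in csv.reader(handle, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                code, element, ion = (cell.strip() for cell in row[:3])
                if code in ("", "*"):
                    fallback[element] = ion
                else:
                    entries[code] = ion
        return cls(entries=entries, element_fallback=fallback)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t")
            writer.writerow(["#ligand_code", "element", "ion_class"])
            for code, ion in sorted(self.entries.items()):
                writer.writerow([code, "", ion])
            for element, ion in sorted(self.element_fallback.items()):
                writer.writerow(["*", element, ion])


@dataclass
class ChainRecord:
    """A polymer chain: one-letter sequence plus (optionally) its atoms."""

    structure_id: str
    chain_id: str
    sequence: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("ChainRecord sequence must be non-empty")

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coords for a in self.atoms if a.is_heavy]
        return np.asarray(coords, dtype=float).reshape(-1, 3)


@dataclass
class ChainLabel:
    """Per-chain binding call with the supporting per-ion distances."""

    structure_id: str
    chain_id: str
    is_metal_binding: bool
    bound_ions: set[str] = field(default_factory=set)
    min_distance_per_ion: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Structure parsing


def parse_structure(path: str | Path) -> gemmi.Structure:
    """Read a PDB or mmCIF file (format chosen from the file contents)."""
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse structure file {path}: {exc}") from exc
    structure.setup_entities()
    return structure


def _is_amino_acid(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    return info is not None and info.is_amino_acid()


def _one_letter(residue_name: str) -> str:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _select_conformers(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: keep the highest-occupancy conformer
    per atom name (ties broken by file order)."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    return list(chosen.values())


def chain_records(structure: gemmi.Structure) -> list[ChainRecord]:
    """Extract one ChainRecord per polymer chain of the first model.

    Modified residues are mapped to their parent one-letter code where
    tabulated, else 'X'.  Non-amino-acid residues (ligands, waters) are
    not part of the chain record.
    """
    records: list[ChainRecord] = []
    if len(structure) == 0:
        return records
    model = structure[0]
    for chain in model:
        letters: list[str] = []
        atoms: list[Atom] = []
        for residue in chain:
            if not _is_amino_acid(residue.name):
                continue
            index = len(letters)
            letters.append(_one_letter(residue.name))
            for atom in _select_conformers(residue):
                element = atom.element.name
                atoms.append(
                    Atom(
                        element=element,
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        is_heavy=element not in _HYDROGEN,
                        residue_index=index,
                    )
                )
        if letters:
            records.append(
                ChainRecord(
                    structure_id=structure.name or "",
                    chain_id=chain.name,
                    sequence="".join(letters),
                    atoms=atoms,
                )
            )
    return records


def extract_metal_sites(
    structure: gemmi.Structure,
    ligand_map: LigandMap | None = None,
    ion_set: Iterable[str] = DEFAULT_ION_SET,
) -> list[MetalSite]:
    """Find metal-containing ligands and reduce each to its metal atoms.

    One MetalSite is emitted per ligand residue that carries at least one
    mapped metal atom; ligands whose class falls outside ``ion_set`` are
    excluded, and metal elements with no mapping are skipped with a
    logged warning.
    """
    ligand_map = ligand_map or LigandMap.default(ion_set)
    ions = set(ion_set)
    sites: list[MetalSite] = []
    if len(structure) == 0:
        return sites
    model = structure[0]
    for chain in model:
        for residue in chain:
            if _is_amino_acid(residue.name) or residue.is_water():
                continue
            metal_coords: list[tuple[float, float, float]] = []
            ion_class: str | None = None
            for atom in _select_conformers(residue):
                element = atom.element.name
                if not atom.element.is_metal:
                    continue
                mapped = ligand_map.ion_for(residue.name, element)
                if mapped is None:
                    logger.warning(
                        "unmapped metal element %s in ligand %s of %s; skipped",
                        element, residue.name, structure.name,
                    )
                    continue
                if mapped not in ions:
                    continue
                if ion_class is None:
                    ion_class = mapped
                if mapped == ion_class:
                    metal_coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
            if ion_class is not None and metal_coords:
                sites.append(
                    MetalSite(
                        ion=ion_class,
                        ligand_code=residue.name,
                        coords=tuple(metal_coords),
                    )
                )
    return sites


# ---------------------------------------------------------------------------
# Geometry


def min_heavy_atom_distance(chain: ChainRecord, site: MetalSite) -> float:
    """Minimum Euclidean distance (Å) between the chain's heavy atoms and
    the site's metal atoms.  Hydrogens and deuteriums are ignored."""
    if not chain.atoms:
        raise ValueError(
            f"chain {chain.chain_id} is a sequence-only record (no atoms)"
        )
    heavy = chain.heavy_coords()
    if heavy.shape[0] == 0:
        raise ValueError(f"chain {chain.chain_id} has no heavy atoms")
    metal = np.asarray(site.coords, dtype=float).reshape(-1, 3)
    return float(cdist(heavy, metal).min())


def contact_residue_indices(
    chain: ChainRecord, site: MetalSite, cutoff: float = DEFAULT_CUTOFF
) -> set[int]:
    """0-based indices of residues with a heavy atom within ``cutoff`` of
    any metal atom of the site (inclusive boundary)."""
    heavy = [a for a in chain.atoms if a.is_heavy]
    if not heavy:
        return set()
    coords = np.asarray([a.coords for a in heavy], dtype=float)
    metal = np.asarray(site.coords, dtype=float).reshape(-1, 3)
    dmin = cdist(coords, metal).min(axis=1)
    return {heavy[i].residue_index for i in np.nonzero(dmin <= cutoff)[0]}


def label_chains(
    structure: gemmi.Structure,
    ligand_map: LigandMap | None = None,
    ion_set: Iterable[str] = DEFAULT_ION_SET,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[ChainLabel]:
    """Apply the contact rule to every polymer chain of a structure.

    A chain is labeled binding for ion class *i* iff its minimum
    heavy-atom distance to some site of class *i* is <= ``cutoff``.
    Chains that fail the rule — including every chain of a metal-free
    structure — are labeled non-binding.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sites = extract_metal_sites(structure, ligand_map, ion_set)
    labels: list[ChainLabel] = []
    for chain in chain_records(structure):
        per_ion: dict[str, float] = {}
        for site in sites:
            d = min_heavy_atom_distance(chain, site)
            if site.ion not in per_ion or d < per_ion[site.ion]:
                per_ion[site.ion] = d
        bound = {ion for ion, d in per_ion.items() if d <= cutoff}
        labels.append(
            ChainLabel(
                structure_id=chain.structure_id,
                chain_id=chain.chain_id,
                is_metal_binding=bool(bound),
                bound_ions=bound,
                min_distance_per_ion=per_ion,
            )
        )
    return labels


# ---------------------------------------------------------------------------
# Label table I/O


def write_labels_tsv(labels: Sequence[ChainLabel], path: str | Path) -> None:
    ions = ION_ORDER
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(
            ["structure_id", "chain_id", "is_metal_binding", "bound_ions"]
            + [f"min_dist_{ion}" for ion in ions]
        )
        for label in labels:
            writer.writerow(
                [
                    label.structure_id,
                    label.chain_id,
                    int(label.is_metal_binding),
                    ",".join(sorted(label.bound_ions)),
                ]
                + [
                    f"{label.min_distance_per_ion[ion]:.3f}"
                    if ion in label.min_distance_per_ion
                    else ""
                    for ion in ions
                ]
            )


def read_labels_tsv(path: str | Path) -> list[ChainLabel]:
    labels: list[ChainLabel] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            bound = {s for s in row["bound_ions"].split(",") if s}
            per_ion = {
                key.removeprefix("min_dist_"): float(value)
                for key, value in row.items()
                if key.startswith("min_dist_") and value
            }
            labels.append(
                ChainLabel(
                    structure_id=row["structure_id"],
                    chain_id=row["chain_id"],
                    is_metal_binding=bool(int(row["is_metal_binding"])),
                    bound_ions=bound,
                    min_distance_per_ion=per_ion,
                )
            )
    return labels
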