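"""Alignment-free sequence features for metal-binding prediction.

Each sequence is described by a fixed-layout numeric vector with three
blocks: (i) amino-acid composition over the 20 canonical residues,
(ii) mean physicochemical properties, and (iii) per-ion counts of
metal-site 5-mers — short peptides observed, in labeled training
structures, centered on residues in direct contact with a metal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dataset import CANONICAL_AA
from .structure_labeling import (
    DEFAULT_CUTOFF,
    ION_ORDER,
    ChainLabel,
    ChainRecord,
    MetalSite,
    contact_residue_indices,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Physicochemical property tables (per canonical residue)

_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
# Net side-chain charge at pH 7; His carries a small positive fraction.
_NET_CHARGE = {aa: 0.0 for aa in CANONICAL_AA}
_NET_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1})
_POLAR = {aa: 0.0 for aa in CANONICAL_AA}
for _aa in "RNDCQEHKSTY":
    _POLAR[_aa] = 1.0
# Average free amino-acid molecular weights (Da).
_MOL_WEIGHT = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "Q": 146.15, "E": 147.13, "G": 75.07, "H": 155.16, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
}
_AROMATIC = {aa: 0.0 for aa in CANONICAL_AA}
for _aa in "FWYH":
    _AROMATIC[_aa] = 1.0
# Side-chain hydrogen-bond donor + acceptor counts (coarse).
_HBOND = {
    "A": 0.0, "R": 4.0, "N": 4.0, "D": 4.0, "C": 1.0, "Q": 4.0, "E": 4.0,
    "G": 0.0, "H": 2.0, "I": 0.0, "L": 0.0, "K": 2.0, "M": 0.0, "F": 0.0,
    "P": 0.0, "S": 3.0, "T": 3.0, "W": 1.0, "Y": 3.0, "V": 0.0,
}


@dataclass
class PropertyTable:
    """Named per-residue property scales; order of ``properties`` fixes
    the physchem feature order."""

    properties: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for name, table in self.properties.items():
            missing = set(CANONICAL_AA) - set(table)
            if missing:
                raise ValueError(f"property {name} missing residues {sorted(missing)}")

    @classmethod
    def default(cls) -> "PropertyTable":
        return cls(
            properties={
                "hydropathy": dict(_KYTE_DOOLITTLE),
                "net_charge": dict(_NET_CHARGE),
                "polarity": dict(_POLAR),
                "mol_weight": dict(_MOL_WEIGHT),
                "aromaticity": dict(_AROMATIC),
                "hbond_capacity": dict(_HBOND),
            }
        )

    @property
    def names(self) -> list[str]:
        return list(self.properties)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropertyTable":
        """Read a residue-by-property TSV (first column: residue)."""
        import csv

        with open(path, newline="") as handle:
            rows = list(csv.reader(handle, delimiter="\t"))
        header = rows[0][1:]
        props: dict[str, dict[str, float]] = {name: {} for name in header}
        for row in rows[1:]:
            aa = row[0].strip().upper()
            for name, value in zip(header, row[1:]):
                props[name][aa] = float(value)
        return cls(properties=props)

    def to_dict(self) -> dict:
        return {name: dict(table) for name, table in self.properties.items()}


# ---------------------------------------------------------------------------
# K-mer vocabulary


@dataclass
class KmerVocabulary:
    """Per-ion sets of metal-site k-mers learned from labeled structures."""

    k: int = 5
    per_ion: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.per_ion = {ion: frozenset(kmers) for ion, kmers in self.per_ion.items()}
        for ion, kmers in self.per_ion.items():
            for kmer in kmers:
                if len(kmer) != self.k or set(kmer) - set(CANONICAL_AA):
                    raise ValueError(f"invalid {self.k}-mer {kmer!r} for ion {ion}")

    @property
    def any_metal(self) -> frozenset[str]:
        out: set[str] = set()
        for kmers in self.per_ion.values():
            out |= kmers
        return frozenset(out)

    @property
    def ions(self) -> list[str]:
        return [ion for ion in ION_ORDER if ion in self.per_ion] + sorted(
            set(self.per_ion) - set(ION_ORDER)
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "provenance": self.provenance,
            "per_ion": {ion: sorted(kmers) for ion, kmers in self.per_ion.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "KmerVocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(
            k=payload["k"],
            per_ion={ion: frozenset(v) for ion, v in payload["per_ion"].items()},
            provenance=payload.get("provenance", ""),
        )


def build_kmer_vocabulary(
    labeled_chains: Sequence[tuple[ChainRecord, ChainLabel]],
    sites_by_chain: Mapping[tuple[str, str], Sequence[MetalSite]] | None = None,
    k: int = 5,
    flank: int = 2,
    cutoff: float = DEFAULT_CUTOFF,
    min_count: int = 1,
    provenance: str = "",
) -> KmerVocabulary:
    """Collect, per ion, the k-mers centered on metal-contact residues.

    A contact residue is one with a heavy atom within ``cutoff`` of a
    metal atom; the emitted window spans ``flank`` residues on each side
    (k = 2*flank + 1), and windows that run off the sequence or contain a
    non-canonical letter are dropped.  ``sites_by_chain`` maps
    (structure_id, chain_id) to that chain's metal sites; chains without
    an entry, or without atoms, are skipped with a warning.
    """
    if k != 2 * flank + 1:
        raise ValueError("k must equal 2*flank + 1")
    counts: dict[str, dict[str, int]] = {}
    sites_by_chain = sites_by_chain or {}
    for chain, label in labeled_chains:
        if not label.is_metal_binding:
            continue
        if not chain.atoms:
            logger.warning(
                "chain %s/%s has no atoms; skipped in vocabulary build",
                chain.structure_id, chain.chain_id,
            )
            continue
        sites = sites_by_chain.get((chain.structure_id, chain.chain_id), [])
        for site in sites:
            if site.ion not in label.bound_ions:
                continue
            for index in sorted(contact_residue_indices(chain, site, cutoff)):
                start = index - flank
                end = index + flank + 1
                if start < 0 or end > len(chain.sequence):
                    continue
                window = chain.sequence[start:end]
                if set(window) - set(CANONICAL_AA):
                    continue
                ion_counts = counts.setdefault(site.ion, {})
                ion_counts[window] = ion_counts.get(window, 0) + 1
    per_ion = {
        ion: frozenset(km for km, c in ion_counts.items() if c >= min_count)
        for ion, ion_counts in counts.items()
    }
    return KmerVocabulary(k=k, per_ion=per_ion, provenance=provenance)


# ---------------------------------------------------------------------------
# Feature schema


@dataclass(frozen=True)
class FeatureSchema:
    """Immutable ordered layout of the feature vector."""

    physchem_names: tuple[str, ...]
    ions: tuple[str, ...]
    with_tier1: bool = False

    @property
    def dimension(self) -> int:
        return 20 + len(self.physchem_names) + len(self.ions) + int(self.with_tier1)

    @property
    def feature_names(self) -> list[str]:
        names = [f"comp_{aa}" for aa in CANONICAL_AA]
        names += [f"physchem_{name}" for name in self.physchem_names]
        names += [f"kmer_{ion}" for ion in self.ions]
        if self.with_tier1:
            names.append("tier1_score")
        return names

    def block_slice(self, block: str) -> slice:
        p = len(self.physchem_names)
        i = len(self.ions)
        offsets = {
            "composition": slice(0, 20),
            "physchem": slice(20, 20 + p),
            "kmer": slice(20 + p, 20 + p + i),
        }
        if self.with_tier1:
            offsets["tier1"] = slice(20 + p + i, 20 + p + i + 1)
        return offsets[block]

    def with_tier1_score(self) -> "FeatureSchema":
        return FeatureSchema(self.physchem_names, self.ions, with_tier1=True)

    def digest(self) -> str:
        text = json.dumps(
            [self.physchem_names, self.ions, self.with_tier1], default=list
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @classmethod
    def for_model(
        cls, table: PropertyTable, vocab: KmerVocabulary
    ) -> "FeatureSchema":
        return cls(physchem_names=tuple(table.names), ions=tuple(vocab.ions))


# ---------------------------------------------------------------------------
# Feature computation

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


def aa_composition(seq: str) -> np.ndarray:
    """Fractions of the 20 canonical residues among canonical positions.

    Non-canonical letters are excluded from both numerator and
    denominator; a sequence with no canonical residues is an error.
    """
    if len(seq) < 1:
        raise ValueError("empty sequence")
    counts = np.zeros(20)
    for ch in seq.upper():
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence has no canonical residues")
    return counts / total


def physchem_features(seq: str, table: PropertyTable) -> np.ndarray:
    """Per property, the mean value over canonical residues."""
    comp = aa_composition(seq)
    out = np.empty(len(table.properties))
    for j, name in enumerate(table.names):
        scale = table.properties[name]
        values = np.array([scale[aa] for aa in CANONICAL_AA])
        out[j] = float(comp @ values)
    return out


def kmer_hit_counts(seq: str, vocab: KmerVocabulary) -> np.ndarray:
    """Per ion, the number of sequence windows found in that ion's k-mer
    set (overlapping windows all count)."""
    seq = seq.upper()
    k = vocab.k
    ions = vocab.ions
    counts = np.zeros(len(ions))
    if len(seq) < k:
        return counts
    windows = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    for j, ion in enumerate(ions):
        kmers = vocab.per_ion[ion]
        counts[j] = sum(1 for w in windows if w in kmers)
    return counts


def featurize(
    seq: str,
    schema: FeatureSchema,
    vocab: KmerVocabulary,
    table: PropertyTable,
) -> np.ndarray:
    """Concatenate the feature blocks in schema order (no tier-1 slot)."""
    if schema.with_tier1:
        raise ValueError("featurize produces base features; tier-1 score is "
                         "appended by the model layer")
    if tuple(vocab.ions) != schema.ions or tuple(table.names) != schema.physchem_names:
        raise ValueError("schema inconsistent with vocabulary/property table")
    vec = np.concatenate(
        [aa_composition(seq), physchem_features(seq, table), kmer_hit_counts(seq, vocab)]
    )
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature values")
    return vec


def featurize_many(
    seqs: Iterable[str],
    schema: FeatureSchema,
    vocab: KmerVocabulary,
    table: PropertyTable,
) -> np.ndarray:
    return np.vstack([featurize(s, schema, vocab, table) for s in seqs])
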