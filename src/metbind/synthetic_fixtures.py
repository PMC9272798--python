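"""Seeded synthetic structures, sequence sets, and reads.

The generators emulate the statistical structure the predictor relies
on: metal-binding sequences are enriched for short ion-specific
sequence patterns (planted 5-mers around hypothetical contact sites)
and show a compositional shift toward coordinating residues (C, H, D,
E), while non-binders are background-only.  Structure fixtures place a
single metal ion at an exactly controlled minimum distance from a
glycine chain laid out on a line, so the contact rule's geometry can
be verified analytically.  Everything is driven by a single seed and
reproduces byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .dataset import CANONICAL_AA, SequenceRecord
from .features import KmerVocabulary
from .structure_labeling import DEFAULT_CUTOFF, ChainLabel

_CA_SPACING = 3.8  # consecutive C-alpha distance on the line, Å


@dataclass
class SynthSpec:
    """Parameters of the synthetic data generator.

    Defaults describe the standard benchmark conditions used throughout
    the test-suite: two balanced classes of ~1000 sequences, three ion
    classes with disjoint planted 5-mers (two copies per positive), a
    mild compositional bias of positives toward coordinating residues,
    and sequence lengths uniform on 80-160 residues.
    """

    seed: int = 0
    n_pos: int = 1000
    n_neg: int = 1000
    length_range: tuple[int, int] = (80, 160)
    motifs: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "Zn": ("CHHCC",),
            "Fe": ("HEDEH",),
            "Cu": ("HMHCM",),
        }
    )
    motif_copies: int = 2
    composition_bias: float = 0.03  # added to C/H/D/E frequency in positives
    background_freqs: dict[str, float] | None = None
    # structure geometry
    n_residues: int = 8
    target_distance: float = 4.0
    structure_ion: str = "Zn"

    def __post_init__(self) -> None:
        for ion, motifs in self.motifs.items():
            for motif in motifs:
                if len(motif) != 5 or set(motif) - set(CANONICAL_AA):
                    raise ValueError(f"invalid motif {motif!r} for {ion}")
        if self.target_distance <= 0:
            raise ValueError("target distance must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthSpec":
        payload = json.loads(Path(path).read_text())
        payload["length_range"] = tuple(payload["length_range"])
        payload["motifs"] = {
            ion: tuple(motifs) for ion, motifs in payload["motifs"].items()
        }
        return cls(**payload)


def planted_vocabulary(spec: SynthSpec) -> KmerVocabulary:
    """The ground-truth k-mer vocabulary implied by the planted motifs."""
    return KmerVocabulary(
        k=5,
        per_ion={ion: frozenset(motifs) for ion, motifs in spec.motifs.items()},
        provenance=f"synthetic(seed={spec.seed})",
    )


# ---------------------------------------------------------------------------
# Structures


def synth_structure(
    target_distance: float,
    ion: str = "Zn",
    n_residues: int = 8,
    structure_id: str = "SYNTH",
    path: str | Path | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[gemmi.Structure, ChainLabel]:
    """Build a minimal structure with an exactly known metal distance.

    The chain is ``n_residues`` glycines whose C-alpha atoms sit on the
    x axis at 3.8 Å spacing; the metal is placed at (0, -d, 0), so its
    minimum heavy-atom distance is exactly ``d`` (every other atom is
    strictly farther).  Returns the structure and the label the contact
    rule must produce at the given cutoff.
    """
    if target_distance <= 0:
        raise ValueError("target distance must be positive")
    if n_residues < 1:
        raise ValueError("need at least one residue")
    structure = gemmi.Structure()
    structure.name = structure_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i in range(n_residues):
        residue = gemmi.Residue()
        residue.name = "GLY"
        residue.seqid = gemmi.SeqId(i + 1, " ")
        residue.het_flag = "A"
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(_CA_SPACING * i, 0.0, 0.0)
        atom.occ = 1.0
        atom.b_iso = 20.0
        residue.add_atom(atom)
        chain.add_residue(residue)
    metal_res = gemmi.Residue()
    metal_res.name = ion.upper()
    metal_res.seqid = gemmi.SeqId(n_residues + 1, " ")
    metal_res.het_flag = "H"
    metal = gemmi.Atom()
    metal.name = ion.upper()
    metal.element = gemmi.Element(ion)
    metal.pos = gemmi.Position(0.0, -target_distance, 0.0)
    metal.occ = 1.0
    metal.b_iso = 20.0
    metal_res.add_atom(metal)
    chain.add_residue(metal_res)
    model.add_chain(chain)
    structure.add_model(model)
    if path is not None:
        structure.write_pdb(str(path))
    binding = target_distance <= cutoff
    label = ChainLabel(
        structure_id=structure_id,
        chain_id="A",
        is_metal_binding=binding,
        bound_ions={ion} if binding else set(),
        min_distance_per_ion={ion: target_distance},
    )
    return structure, label


# ---------------------------------------------------------------------------
# Sequences

_AA_LIST = list(CANONICAL_AA)


def _background(spec: SynthSpec) -> np.ndarray:
    if spec.background_freqs:
        freqs = np.array([spec.background_freqs.get(aa, 0.0) for aa in _AA_LIST])
    else:
        freqs = np.full(20, 1 / 20)
    return freqs / freqs.sum()


def _positive_freqs(spec: SynthSpec) -> np.ndarray:
    freqs = _background(spec).copy()
    for aa in "CHDE":
        freqs[_AA_LIST.index(aa)] += spec.composition_bias
    return freqs / freqs.sum()


def _random_seq(rng: np.random.Generator, length: int, freqs: np.ndarray) -> list[str]:
    return list(rng.choice(_AA_LIST, size=length, p=freqs))


def synth_sequences(spec: SynthSpec) -> list[SequenceRecord]:
    """Generate the labeled benchmark sequence set.

    Positives cycle through the ions of ``spec.motifs``; each carries
    ``motif_copies`` non-overlapping planted copies of one of its ion's
    motifs plus the compositional shift.  Negatives are background-only
    (a planted motif can still occur by chance, at the background rate
    of roughly 20^-5 per position).
    """
    rng = np.random.default_rng(spec.seed)
    ions = list(spec.motifs)
    bg = _background(spec)
    pos_freqs = _positive_freqs(spec)
    lo, hi = spec.length_range
    records: list[SequenceRecord] = []
    for i in range(spec.n_pos):
        ion = ions[i % len(ions)]
        length = int(rng.integers(lo, hi + 1))
        letters = _random_seq(rng, length, pos_freqs)
        taken: list[tuple[int, int]] = []
        for _copy in range(spec.motif_copies):
            motif = str(rng.choice(spec.motifs[ion]))
            for _try in range(100):
                start = int(rng.integers(0, length - len(motif) + 1))
                if all(start + len(motif) <= s or start >= e for s, e in taken):
                    break
            taken.append((start, start + len(motif)))
            letters[start : start + len(motif)] = list(motif)
        records.append(
            SequenceRecord(
                id=f"pos{i:05d}",
                sequence="".join(letters),
                label=True,
                ion_labels={ion: True},
            )
        )
    for i in range(spec.n_neg):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            SequenceRecord(
                id=f"neg{i:05d}",
                sequence="".join(_random_seq(rng, length, bg)),
                label=False,
                ion_labels={},
            )
        )
    return records


# ---------------------------------------------------------------------------
# Reads

_BACK_TABLE: dict[str, list[str]] = {}


def _codon_choices(table_id: int = 11) -> dict[str, list[str]]:
    if not _BACK_TABLE:
        table = CodonTable.unambiguous_dna_by_id[table_id]
        for codon, aa in table.forward_table.items():
            _BACK_TABLE.setdefault(aa, []).append(codon)
        for choices in _BACK_TABLE.values():
            choices.sort()
    return _BACK_TABLE


@dataclass(frozen=True)
class SyntheticRead:
    id: str
    sequence: str
    quality: str
    source_id: str
    source_start_nt: int
    strand: str  # '+' or '-'


def reverse_translate(
    protein: str, rng: np.random.Generator, table_id: int = 11
) -> str:
    """Back-translate with uniformly random synonymous codons."""
    choices = _codon_choices(table_id)
    return "".join(str(rng.choice(choices[aa])) for aa in protein)


def synth_reads(
    proteins: Sequence[tuple[str, str]],
    n_reads: int = 500,
    read_length: int = 150,
    seed: int = 0,
    quality_char: str = "I",
) -> list[SyntheticRead]:
    """Sample fixed-length reads from reverse-translated proteins.

    Each read records its protein of origin, the 0-based nucleotide
    offset in that protein's coding sequence, and its strand (reads on
    '-' are reverse-complemented).  Proteins shorter than a read are
    never sampled.
    """
    rng = np.random.default_rng(seed)
    coding = [
        (pid, reverse_translate(seq, rng))
        for pid, seq in proteins
    ]
    usable = [(pid, cds) for pid, cds in coding if len(cds) >= read_length]
    if not usable:
        raise ValueError("no protein long enough for the requested read length")
    reads: list[SyntheticRead] = []
    for i in range(n_reads):
        pid, cds = usable[int(rng.integers(len(usable)))]
        start = int(rng.integers(0, len(cds) - read_length + 1))
        fragment = cds[start : start + read_length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = str(Seq(fragment).reverse_complement())
        reads.append(
            SyntheticRead(
                id=f"read{i:06d}",
                sequence=fragment,
                quality=quality_char * read_length,
                source_id=pid,
                source_start_nt=start,
                strand=strand,
            )
        )
    return reads


def write_fastq(reads: Sequence[SyntheticRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{read.quality}\n")


def records_to_fasta_text(records: Sequence[SequenceRecord]) -> str:
    return "".join(f">{r.id}\n{r.sequence}\n" for r in records)


def truth_table_rows(records: Sequence[SequenceRecord]) -> list[dict]:
    return [
        {
            "id": r.id,
            "label": int(r.label),
            "ions": ",".join(sorted(i for i, v in r.ion_labels.items() if v)),
        }
        for r in records
    ]
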