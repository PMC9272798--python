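"""Fragment and metagenomic-read screening.

Whole proteins are scanned as overlapping 50-residue fragments
(sliding window of one); nucleotide reads are translated in all six
reading frames with the bacterial codon table, split at stop codons,
and peptides of 15 or fewer residues are discarded.  Per-sample
results are summarized as a metal profile — the relative frequency of
positive per-ion calls over all evaluated peptides — and profiles are
compared by Euclidean distance in the fixed ion order
(Ca, Co, Cu, Fe, K, Mg, Mn, Na, Ni, Zn).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .model import ModelBundle, PredictionResult, predict
from .structure_labeling import ION_ORDER

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 50
DEFAULT_MIN_PEPTIDE = 16  # peptides of <= 15 residues are discarded
BACTERIAL_TABLE = 11

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class Fragment:
    parent_id: str
    start: int  # 0-based; fragment covers [start, start + window)
    sequence: str


@dataclass(frozen=True)
class TranslatedPeptide:
    read_id: str
    frame: int
    segment_index: int
    sequence: str

    def __post_init__(self) -> None:
        if "*" in self.sequence:
            raise ValueError("translated peptide contains a stop symbol")


@dataclass
class MetalProfile:
    """Relative frequencies of per-ion positive calls in one sample."""

    frequencies: dict[str, float]
    total_peptides: int
    ion_order: tuple[str, ...] = ION_ORDER

    def vector(self) -> np.ndarray:
        return np.array([self.frequencies.get(ion, 0.0) for ion in self.ion_order])


# ---------------------------------------------------------------------------
# Fragments


def fragment_sequence(
    seq: str, parent_id: str = "", window: int = DEFAULT_WINDOW, step: int = 1
) -> list[Fragment]:
    """Overlapping fixed-length windows; sequences shorter than the
    window yield no fragments (count = L - window + 1 at step 1)."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    return [
        Fragment(parent_id=parent_id, start=i, sequence=seq[i : i + window])
        for i in range(0, len(seq) - window + 1, step)
    ]


AggregationRule = Literal["max", "mean", "fraction_positive"]


def aggregate_fragment_scores(
    scores: Sequence[float],
    rule: AggregationRule = "max",
    cutoff: float = 0.5,
) -> float:
    """Reduce one parent's fragment scores to a single protein score."""
    if len(scores) == 0:
        raise ValueError("no fragment scores to aggregate")
    arr = np.asarray(scores, dtype=float)
    if rule == "max":
        return float(arr.max())
    if rule == "mean":
        return float(arr.mean())
    if rule == "fraction_positive":
        return float(np.mean(arr >= cutoff))
    raise ValueError(f"unknown aggregation rule {rule!r}")


# ---------------------------------------------------------------------------
# Six-frame translation


def six_frame_translate(
    read: str,
    read_id: str = "",
    codon_table: int = BACTERIAL_TABLE,
    min_len: int = DEFAULT_MIN_PEPTIDE,
) -> list[TranslatedPeptide]:
    """Translate a read in all six frames and keep stop-free peptides.

    Frames +1..+3 read the given strand at offsets 0..2; -1..-3 read the
    reverse complement the same way.  A trailing partial codon is
    treated as unknown and translates to 'X' (as do codons containing
    N), translations are split at stop codons, and segments shorter
    than ``min_len`` are discarded — so a stop-free 48 nt read yields
    six 16-residue peptides while a 45 nt read yields none.
    """
    read = read.upper().replace("U", "T")
    if not read:
        return []
    bad = set(read) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected nucleotides {sorted(bad)}")
    table = CodonTable.unambiguous_dna_by_id[codon_table]
    forward = table.forward_table
    stops = set(table.stop_codons)
    peptides: list[TranslatedPeptide] = []
    reverse = str(Seq(read).reverse_complement())
    for frame in FRAMES:
        strand = read if frame > 0 else reverse
        offset = abs(frame) - 1
        sub = strand[offset:]
        if len(sub) % 3:
            sub += "N" * (3 - len(sub) % 3)
        if not sub:
            continue
        codons = (sub[i : i + 3] for i in range(0, len(sub), 3))
        translation = "".join(
            "X" if "N" in c else ("*" if c in stops else forward[c])
            for c in codons
        )
        for index, segment in enumerate(translation.split("*")):
            if len(segment) >= min_len:
                peptides.append(
                    TranslatedPeptide(
                        read_id=read_id,
                        frame=frame,
                        segment_index=index,
                        sequence=segment,
                    )
                )
    return peptides


# ---------------------------------------------------------------------------
# Read / sequence input


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Iterate (id, sequence) from FASTA or FASTQ, gzip-transparent."""
    path = Path(path)
    name = path.name.removesuffix(".gz")
    fmt = "fastq" if name.endswith((".fq", ".fastq")) else "fasta"
    opener: Callable = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, fmt):
            yield record.id, str(record.seq).upper()


# ---------------------------------------------------------------------------
# Metal profiles


def metal_profile(
    predictions: Sequence[PredictionResult],
    tier1_gated: bool = False,
    metal_binding_only: bool = False,
) -> MetalProfile:
    """Per-ion relative frequency of positive calls.

    The denominator is the number of evaluated peptides by default; with
    ``metal_binding_only`` it is the number of peptides with at least one
    positive ion call.  With ``tier1_gated``, ion calls only count for
    peptides whose tier-1 call is positive.
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to profile")
    considered = [
        p for p in predictions if not tier1_gated or p.tier1_call
    ]
    counts = {ion: 0 for ion in ION_ORDER}
    n_any = 0
    for p in considered:
        any_call = False
        for ion, call in p.ion_calls.items():
            if call and ion in counts:
                counts[ion] += 1
                any_call = True
        n_any += int(any_call)
    denom = n_any if metal_binding_only else len(predictions)
    freqs = {
        ion: (counts[ion] / denom if denom else 0.0) for ion in ION_ORDER
    }
    return MetalProfile(frequencies=freqs, total_peptides=len(predictions))


def profile_distance(p: MetalProfile, q: MetalProfile) -> float:
    """Euclidean distance between two metal profiles (same ion order)."""
    if p.ion_order != q.ion_order:
        raise ValueError("profiles use different ion orders")
    return float(np.sqrt(np.sum((p.vector() - q.vector()) ** 2)))


# ---------------------------------------------------------------------------
# End-to-end screening helpers


def screen_fragments(
    proteins: Iterable[tuple[str, str]],
    bundle: ModelBundle,
    window: int = DEFAULT_WINDOW,
    step: int = 1,
    rule: AggregationRule = "max",
) -> tuple[list[PredictionResult], dict[str, float]]:
    """Predict every fragment of every (>= window)-residue protein and
    aggregate fragment tier-1 scores to a per-protein score."""
    fragments: list[tuple[str, str]] = []
    parents: list[str] = []
    for pid, seq in proteins:
        for frag in fragment_sequence(seq, pid, window, step):
            fragments.append((f"{pid}|{frag.start}", frag.sequence))
            parents.append(pid)
    results = predict(fragments, bundle)
    by_parent: dict[str, list[float]] = {}
    for parent, res in zip(parents, results):
        by_parent.setdefault(parent, []).append(res.tier1_score)
    aggregated = {
        pid: aggregate_fragment_scores(scores, rule, bundle.cutoff_tier1)
        for pid, scores in by_parent.items()
    }
    return results, aggregated


def screen_reads(
    reads: Iterable[tuple[str, str]],
    bundle: ModelBundle,
    codon_table: int = BACTERIAL_TABLE,
    min_len: int = DEFAULT_MIN_PEPTIDE,
    tier1_gated: bool = False,
) -> tuple[list[PredictionResult], MetalProfile]:
    """Translate reads in six frames, predict each peptide, and build
    the sample's metal profile."""
    peptides: list[tuple[str, str]] = []
    for rid, read in reads:
        for pep in six_frame_translate(read, rid, codon_table, min_len):
            peptides.append(
                (f"{rid}|{pep.frame:+d}|{pep.segment_index}", pep.sequence)
            )
    if not peptides:
        raise ValueError("no peptides of sufficient length after translation")
    results = predict(peptides, bundle)
    return results, metal_profile(results, tier1_gated=tier1_gated)
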