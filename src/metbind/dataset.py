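"""Redundancy reduction and cross-validation splits.

Labeled sequences are greedily clustered at a sequence-identity
threshold (default 70%), clusters are classed positive / negative /
mixed at a purity threshold (default: strictly more than 98% of members
from one class), and the retained pure clusters are partitioned into
cross-validation groups that keep all members of a cluster on the same
side of every train/test split.

Identity convention: the number of matched positions of a global
alignment, maximized over alignments (equivalently the longest common
subsequence), divided by the length of the shorter sequence.  This is
the largest identity any alignment can claim for the pair, computed
with zero gap and mismatch penalties; it is deterministic, symmetric
and well-suited to thresholding near high identity.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Extra letters tolerated in input sequences (ambiguity / rare residues).
EXTENDED_AA = CANONICAL_AA + "XBZUO"

ClusterClass = Literal["positive", "negative", "mixed"]


@dataclass
class SequenceRecord:
    """A sequence with its binary and per-ion metal-binding labels."""

    id: str
    sequence: str
    label: bool
    ion_labels: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set(EXTENDED_AA)
        if bad:
            raise ValueError(f"record {self.id}: unexpected letters {sorted(bad)}")
        if any(self.ion_labels.values()) and not self.label:
            raise ValueError(
                f"record {self.id}: ion label set but binary label is negative"
            )


@dataclass
class Cluster:
    representative: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if self.representative not in self.members:
            raise ValueError("representative must be a member")


@dataclass
class CVSplit:
    fold_id: int
    train_cluster_ids: set[str]
    test_cluster_ids: set[str]

    def __post_init__(self) -> None:
        if self.train_cluster_ids & self.test_cluster_ids:
            raise ValueError("train and test clusters overlap")


# ---------------------------------------------------------------------------
# Pairwise identity

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=0,
    extend_gap_score=0,
)


def pairwise_identity(a: str, b: str) -> float:
    """Alignment identity in [0, 1]: max matched positions over global
    alignments divided by the shorter sequence's length."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    matches = _aligner.score(a.upper(), b.upper())
    return float(matches) / min(len(a), len(b))


def _letter_counts(seq: str) -> Counter:
    return Counter(seq)


def _identity_upper_bound(ca: Counter, cb: Counter, min_len: int) -> float:
    """Cheap upper bound on pairwise_identity from letter multisets: a
    common subsequence cannot use a letter more often than it occurs in
    either sequence."""
    shared = sum(min(ca[x], cb[x]) for x in ca.keys() & cb.keys())
    return shared / min_len


# ---------------------------------------------------------------------------
# Greedy clustering


def greedy_cluster(
    records: Sequence[SequenceRecord], threshold: float = 0.70
) -> list[Cluster]:
    """Greedy length-descending clustering at an identity threshold.

    Records are visited longest-first (ties broken by id); each joins the
    first existing cluster whose *representative* has identity >= the
    threshold, else founds a new cluster.  Deterministic given the input
    set.  A letter-multiset bound prunes hopeless comparisons without
    changing the result.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    rep_counts: list[Counter] = []
    for record in ordered:
        seq = record.sequence.upper()
        counts = _letter_counts(seq)
        placed = False
        for i, rep in enumerate(rep_seqs):
            min_len = len(seq)  # reps are never shorter (length-descending)
            if _identity_upper_bound(counts, rep_counts[i], min_len) < threshold:
                continue
            if pairwise_identity(seq, rep) >= threshold:
                clusters[i].members.append(record.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=record.id, members=[record.id]))
            rep_seqs.append(seq)
            rep_counts.append(counts)
    return clusters


def deduplicate(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Drop exact duplicate sequences, keeping the first id in id order."""
    seen: dict[str, SequenceRecord] = {}
    for record in sorted(records, key=lambda r: r.id):
        key = record.sequence.upper()
        if key not in seen:
            seen[key] = record
    return sorted(seen.values(), key=lambda r: r.id)


# ---------------------------------------------------------------------------
# Cluster classes


def assign_cluster_class(
    cluster: Cluster,
    labels: Mapping[str, bool],
    purity: float = 0.98,
    ion: str | None = None,
    ion_labels: Mapping[str, Mapping[str, bool]] | None = None,
) -> ClusterClass:
    """Class a cluster positive / negative / mixed at a purity threshold.

    Positive iff strictly more than ``purity`` of members are positive;
    negative iff strictly more than ``purity`` are negative; else mixed.
    With ``ion`` given, per-ion labels are used instead of the binary
    label (a member is positive iff labeled for that ion).
    """
    if ion is not None:
        if ion_labels is None:
            raise ValueError("ion_labels required for per-ion classing")
        member_labels = [bool(ion_labels[m].get(ion, False)) for m in cluster.members]
    else:
        member_labels = [bool(labels[m]) for m in cluster.members]
    n = len(member_labels)
    pos_frac = sum(member_labels) / n
    if pos_frac > purity:
        return "positive"
    if (1 - pos_frac) > purity:
        return "negative"
    return "mixed"


# ---------------------------------------------------------------------------
# Cross-validation splits


def _partition_balanced(
    clusters: list[tuple[str, int]], k: int, rng: np.random.Generator
) -> list[list[str]]:
    """Partition (cluster_id, size) pairs into k groups of near-equal
    total sequence counts: shuffle, then assign largest-first to the
    currently lightest group."""
    order = list(clusters)
    rng.shuffle(order)
    order.sort(key=lambda item: -item[1])
    groups: list[list[str]] = [[] for _ in range(k)]
    loads = np.zeros(k)
    for cid, size in order:
        target = int(np.argmin(loads))
        groups[target].append(cid)
        loads[target] += size
    return groups


def make_cv_splits(
    clusters: Sequence[Cluster],
    classes: Mapping[str, ClusterClass],
    sizes: Mapping[str, int] | None = None,
    k: int = 10,
    seed: int = 0,
) -> list[CVSplit]:
    """Build k cluster-respecting folds with balanced classes.

    Mixed clusters are excluded (they are kept aside for testing, not
    used in training).  Positive and negative clusters are separately
    partitioned into k groups of near-equal sequence counts, then within
    each group negatives are down-sampled (seeded) until their sequence
    count does not exceed the positives'.  Fold i tests on group i and
    trains on the rest.
    """
    sizes = sizes or {c.representative: len(c.members) for c in clusters}
    pos = [(c.representative, sizes[c.representative]) for c in clusters
           if classes.get(c.representative) == "positive"]
    neg = [(c.representative, sizes[c.representative]) for c in clusters
           if classes.get(c.representative) == "negative"]
    if len(pos) < k or len(neg) < k:
        raise ValueError(
            f"need at least {k} positive and {k} negative clusters "
            f"(got {len(pos)} / {len(neg)})"
        )
    rng = np.random.default_rng(seed)
    pos_groups = _partition_balanced(pos, k, rng)
    neg_groups = _partition_balanced(neg, k, rng)
    size_of = dict(pos + neg)

    splits: list[CVSplit] = []
    balanced_groups: list[set[str]] = []
    for i in range(k):
        pos_count = sum(size_of[c] for c in pos_groups[i])
        kept_neg: list[str] = []
        neg_count = 0
        for cid in rng.permutation(neg_groups[i]):
            if neg_count >= pos_count:
                break
            kept_neg.append(str(cid))
            neg_count += size_of[str(cid)]
        balanced_groups.append(set(pos_groups[i]) | set(kept_neg))
    for i in range(k):
        test = balanced_groups[i]
        train = set().union(*(g for j, g in enumerate(balanced_groups) if j != i))
        splits.append(CVSplit(fold_id=i + 1, train_cluster_ids=train,
                              test_cluster_ids=test))
    return splits


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_clstr(clusters: Sequence[Cluster],
                lengths: Mapping[str, int], path: str | Path) -> None:
    """Write clusters in a .clstr-style format (header line per cluster,
    one member line each; the representative is marked with '*')."""
    with open(path, "w") as handle:
        for i, cluster in enumerate(clusters):
            handle.write(f">Cluster {i}\n")
            for j, member in enumerate(cluster.members):
                mark = "*" if member == cluster.representative else ""
                handle.write(f"{j}\t{lengths.get(member, 0)}aa, >{member}... {mark}\n")


def write_splits_json(splits: Sequence[CVSplit], path: str | Path) -> None:
    payload = {
        str(s.fold_id): {
            "train": sorted(s.train_cluster_ids),
            "test": sorted(s.test_cluster_ids),
        }
        for s in splits
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_splits_json(path: str | Path) -> list[CVSplit]:
    payload = json.loads(Path(path).read_text())
    return [
        CVSplit(fold_id=int(fold), train_cluster_ids=set(item["train"]),
                test_cluster_ids=set(item["test"]))
        for fold, item in sorted(payload.items(), key=lambda kv: int(kv[0]))
    ]
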