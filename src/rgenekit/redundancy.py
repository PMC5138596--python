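"""Greedy sequence-identity clustering for redundancy removal.

Mirrors the greedy incremental algorithm popularized by CD-HIT: sequences are
sorted by descending length and each is compared against the representatives
of the clusters formed so far; it joins the first cluster whose representative
identity meets the threshold, otherwise it founds a new cluster. The longest
member of each cluster (its founder) is the representative kept after
dereplication.

Identity between two sequences is the number of identical aligned residues in
a global alignment (match +1, mismatch 0, linear gap -1 — an
identity-maximizing scoring) divided by the shorter sequence's length, the
convention CD-HIT uses. No short-word prefilter is applied; the cost is
O(n_records x n_clusters x L^2), which is fine at desk scale.

Greedy clustering guarantees every removed sequence is >= threshold identical
to some representative; it does NOT guarantee all representative pairs fall
below the threshold (a sequence is only compared against earlier, longer
representatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align

from rgenekit.sequence_io import ProteinRecord


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Fraction of identical residues over the shorter sequence's length.

    Symmetric; 1.0 for identical sequences, 0.0 when no residue can be
    matched.
    """
    if a.sequence == b.sequence:
        return 1.0
    alignment = _ALIGNER.align(a.sequence, b.sequence)[0]
    identities = alignment.counts().identities
    return identities / min(a.length, b.length)


@dataclass
class Cluster:
    """One greedy cluster: its (longest) representative and all members."""

    representative: ProteinRecord
    members: list[ProteinRecord] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            self.members = [self.representative]
            self.identities.setdefault(self.representative.id, 1.0)

    def add(self, record: ProteinRecord, identity: float) -> None:
        self.members.append(record)
        self.identities[record.id] = identity

    def __len__(self) -> int:
        return len(self.members)


def cluster_greedy(
    records: list[ProteinRecord], threshold: float, seed: int | None = None
) -> list[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Records are processed longest first (length ties broken by id,
    lexicographic), so clustering is deterministic for a given input set; the
    ``seed`` argument is accepted for interface uniformity but unused.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    clusters: list[Cluster] = []
    for rec in ordered:
        for cluster in clusters:
            identity = pairwise_identity(rec, cluster.representative)
            if identity >= threshold:
                cluster.add(rec, identity)
                break
        else:
            clusters.append(Cluster(representative=rec))
    return clusters


def dereplicate(records: list[ProteinRecord], threshold: float = 0.70) -> list[ProteinRecord]:
    """Cluster at ``threshold`` and keep one representative per cluster."""
    return [c.representative for c in cluster_greedy(records, threshold)]


def write_cluster_report(clusters: list[Cluster], path: str | Path) -> None:
    """TSV report: cluster_id, representative_id, member_id, identity."""
    with open(path, "w") as fh:
        fh.write("cluster_id\trepresentative_id\tmember_id\tidentity\n")
        for ci, cluster in enumerate(clusters):
            for member in cluster.members:
                fh.write(
                    f"{ci}\t{cluster.representative.id}\t{member.id}\t"
                    f"{cluster.identities[member.id]:.4f}\n"
                )
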