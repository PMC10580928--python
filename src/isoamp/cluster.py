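"""Greedy centroid-led identity clustering of 16S sequences.

Isolate sequences are clustered at 99% identity into iOTUs and at 100%
identity into ziOTUs (zero-radius OTUs).  The algorithm is the classic greedy
centroid scheme: sequences are processed in decreasing length order (ties
broken by ascending id); each query joins the first existing centroid — in
centroid-creation order — whose pairwise identity reaches the threshold, and
otherwise founds a new cluster.  No k-mer accept/reject heuristics are used:
every query is compared exhaustively against the centroid list, which is
exact and affordable at desk scale (up to a few thousand sequences).

Identity is computed from an optimal semi-global alignment (free end gaps,
match +5 / mismatch -4 / gap open -10 / gap extend -1); terminal-gap columns
are excluded from the denominator, internal gap columns count as mismatching
columns, and ambiguity codes never count as matches (see ``_alignment``).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

from ._alignment import AlignmentError, semiglobal_identity
from .io import normalize_sequence

__all__ = [
    "Cluster",
    "ClusterSet",
    "pairwise_identity",
    "greedy_cluster",
    "nest_check",
]

_ACGT = frozenset("ACGT")


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in the optimal semi-global alignment.

    Symmetric and deterministic: the pair is canonically ordered (longer
    sequence first, ties lexicographic) before alignment so that
    ``pairwise_identity(a, b) == pairwise_identity(b, a)`` holds exactly.
    Returns a value in [0, 1].  Raises on empty input.
    """
    if not a or not b:
        raise AlignmentError("pairwise_identity requires non-empty sequences")
    a = normalize_sequence(a, context="pairwise_identity")
    b = normalize_sequence(b, context="pairwise_identity")
    if (len(a), a) < (len(b), b):
        a, b = b, a
    # exact containment shortcut: score 5*len(shorter) is the attainable
    # maximum and is reached only by an all-match core, so identity is 1
    if _ACGT.issuperset(b) and b in a:
        return 1.0
    matches, columns, _ = semiglobal_identity(a, b)
    return matches / columns


def _is_exact_containment(a: str, b: str) -> bool:
    """True iff the shorter sequence is an exact, unambiguous substring."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    return _ACGT.issuperset(short) and short in long_


@dataclasses.dataclass
class Cluster:
    """A centroid-led cluster; the centroid is the first member."""

    centroid_id: str
    member_ids: list[str]
    threshold: float
    identities: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cluster must have at least one member")
        if self.centroid_id not in self.member_ids:
            raise ValueError("centroid must be a member of its cluster")

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclasses.dataclass
class ClusterSet:
    """A partition of sequence ids into clusters at one identity threshold."""

    clusters: list[Cluster]
    threshold: float
    level_label: str = "custom"  # "iOTU", "ziOTU" or "custom"

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_ids(self) -> list[str]:
        return [m for c in self.clusters for m in c.member_ids]

    def assignment(self) -> dict[str, str]:
        """Map each member id to its centroid id."""
        return {m: c.centroid_id for c in self.clusters for m in c.member_ids}

    def centroid_ids(self) -> list[str]:
        return [c.centroid_id for c in self.clusters]

    def validate_partition(self, ids) -> None:
        members = self.member_ids()
        if len(members) != len(set(members)):
            raise ValueError("clusters overlap: duplicate member ids")
        if set(members) != set(ids):
            raise ValueError("clusters do not cover exactly the input ids")


def greedy_cluster(
    seqs: Mapping[str, str], threshold: float, *, level_label: str | None = None
) -> ClusterSet:
    """Greedy centroid clustering of ``seqs`` at ``threshold`` identity.

    Deterministic and invariant to the input mapping's ordering: the
    processing order (length descending, then id ascending) is recomputed
    internally.  At threshold 1.0 the identity test reduces to exact,
    unambiguous substring containment of the shorter sequence in the longer,
    which is used directly.

    Duplicate sequence strings are deduplicated internally: a repeated
    sequence always takes the same join/found decision as its first
    occurrence, so the result is unchanged while the alignment work shrinks
    to one comparison per unique sequence per centroid.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not seqs:
        raise ValueError("greedy_cluster requires at least one sequence")
    norm = {i: normalize_sequence(s, context=i) for i, s in seqs.items()}
    order = sorted(norm, key=lambda i: (-len(norm[i]), i))

    if level_label is None:
        level_label = (
            "ziOTU" if threshold == 1.0 else ("iOTU" if threshold == 0.99 else "custom")
        )

    clusters: list[Cluster] = []
    # decision cache per unique sequence string: (cluster index or None)
    decided: dict[str, tuple[int | None, float]] = {}
    pair_cache: dict[tuple[str, str], float] = {}

    def identity_to(seq: str, centroid_seq: str) -> float:
        key = (seq, centroid_seq)
        if key not in pair_cache:
            if threshold == 1.0:
                pair_cache[key] = 1.0 if _is_exact_containment(seq, centroid_seq) else 0.0
            else:
                pair_cache[key] = pairwise_identity(seq, centroid_seq)
        return pair_cache[key]

    centroid_seqs: list[str] = []
    for qid in order:
        q = norm[qid]
        if q in decided:
            idx, ident = decided[q]
            if idx is None:
                # its twin founded a cluster; this copy joins it at identity 1
                target = next(
                    k for k, c in enumerate(clusters) if norm[c.centroid_id] == q
                )
                clusters[target].member_ids.append(qid)
                clusters[target].identities[qid] = 1.0
            else:
                clusters[idx].member_ids.append(qid)
                clusters[idx].identities[qid] = ident
            continue
        joined = None
        ident = 0.0
        for k, cseq in enumerate(centroid_seqs):
            ident_k = identity_to(q, cseq)
            if ident_k >= threshold:
                joined, ident = k, ident_k
                break
        if joined is None:
            clusters.append(
                Cluster(
                    centroid_id=qid,
                    member_ids=[qid],
                    threshold=threshold,
                    identities={qid: 1.0},
                )
            )
            centroid_seqs.append(q)
            decided[q] = (None, 1.0)
        else:
            clusters[joined].member_ids.append(qid)
            clusters[joined].identities[qid] = ident
            decided[q] = (joined, ident)

    out = ClusterSet(clusters=clusters, threshold=threshold, level_label=level_label)
    out.validate_partition(norm)
    return out


def nest_check(fine: ClusterSet, coarse: ClusterSet) -> tuple[bool, list[dict]]:
    """Audit consistency between a fine (e.g. ziOTU) and coarse (iOTU) level.

    Returns ``(ok, report)`` where ``ok`` is True iff the fine level has at
    least as many clusters as the coarse level, and ``report`` lists fine
    clusters whose members are split across several coarse clusters.  Greedy
    clustering does not guarantee strict nesting, so splits are reported,
    not enforced.
    """
    fine_ids = set(fine.member_ids())
    coarse_ids = set(coarse.member_ids())
    if fine_ids != coarse_ids:
        raise ValueError("nest_check requires both cluster sets over the same ids")
    coarse_of = coarse.assignment()
    report = []
    for c in fine.clusters:
        parents = sorted({coarse_of[m] for m in c.member_ids})
        if len(parents) > 1:
            report.append(
                {"fine_centroid": c.centroid_id, "coarse_centroids": parents}
            )
    return fine.n_clusters >= coarse.n_clusters, report
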