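"""Redundancy reduction and per-column consensus/conservation.

Sequences are clustered greedily at an identity threshold (default 70%),
in the style of CD-HIT: sequences sorted by length descending, each one
joining the first centroid it matches at or above the threshold under
global alignment, identity counted over the shorter sequence's length.
Consensus and conservation are then computed per alignment column: the
consensus residue is the most frequent non-gap residue (alphabetical
tie-break) and its conservation score is that residue's frequency among
the column's non-gap rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import pandas as pd

from .alignment import (GAP_EXTEND_DEFAULT, GAP_OPEN_DEFAULT,
                        SubstitutionMatrix, blosum62, needleman_wunsch)
from .io_formats import DomainRecord, ThemeAlignment

IDENTITY_THRESHOLD_DEFAULT = 0.70


@dataclass(frozen=True)
class SequenceCluster:
    centroid_id: str
    member_ids: tuple[str, ...]


def pair_identity(a: str, b: str, matrix: SubstitutionMatrix | None = None,
                  gap_open: float = GAP_OPEN_DEFAULT,
                  gap_extend: float = GAP_EXTEND_DEFAULT) -> float:
    """Global-alignment identity, normalised by the shorter sequence."""
    res = needleman_wunsch(a, b, matrix or blosum62(), gap_open, gap_extend)
    matches = sum(1 for i, j in res.aligned_pairs
                  if i >= 0 and j >= 0 and a[i] == b[j])
    return matches / min(len(a), len(b))


def cluster_sequences(seqs: list[DomainRecord],
                      identity_threshold: float = IDENTITY_THRESHOLD_DEFAULT,
                      matrix: SubstitutionMatrix | None = None,
                      gap_open: float = GAP_OPEN_DEFAULT,
                      gap_extend: float = GAP_EXTEND_DEFAULT) -> list[SequenceCluster]:
    """Greedy length-sorted incremental clustering at an identity threshold."""
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity threshold must be in (0, 1]")
    order = sorted(seqs, key=lambda d: (-len(d.sequence), d.id))
    centroids: list[DomainRecord] = []
    members: list[list[str]] = []
    for d in order:
        for ci, c in enumerate(centroids):
            if pair_identity(c.sequence, d.sequence, matrix,
                             gap_open, gap_extend) >= identity_threshold:
                members[ci].append(d.id)
                break
        else:
            centroids.append(d)
            members.append([d.id])
    return [SequenceCluster(c.id, tuple(m)) for c, m in zip(centroids, members)]


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column consensus residues and their conservation scores."""

    consensus: str
    scores: tuple[float, ...]
    compositions: tuple[tuple[tuple[str, int], ...], ...] = ()

    def __post_init__(self):
        if len(self.consensus) != len(self.scores):
            raise ValueError("consensus/scores length mismatch")
        if any(not 0.0 <= s <= 1.0 for s in self.scores):
            raise ValueError("conservation scores must lie in [0,1]")


def consensus_profile(msa: ThemeAlignment) -> ConservationProfile:
    """Most frequent non-gap residue per column plus its frequency."""
    consensus = []
    scores = []
    comps = []
    for c in range(msa.width):
        col = [row[c] for row in msa.rows if row[c] != "-"]
        counts = Counter(col)
        # most frequent residue; alphabetical on ties
        best = min(counts, key=lambda r: (-counts[r], r))
        consensus.append(best)
        scores.append(counts[best] / len(col))
        comps.append(tuple(sorted(counts.items())))
    return ConservationProfile("".join(consensus), tuple(scores), tuple(comps))


def conservation_table(profile: ConservationProfile) -> pd.DataFrame:
    """Human-facing table: 1-based columns, consensus, score, composition."""
    rows = []
    for i, (res, score) in enumerate(zip(profile.consensus, profile.scores)):
        comp = profile.compositions[i] if profile.compositions else ()
        rows.append({
            "column_index": i + 1,
            "consensus_residue": res,
            "score": score,
            "column_composition": ",".join(f"{r}:{n}" for r, n in comp),
        })
    return pd.DataFrame(rows, columns=["column_index", "consensus_residue",
                                       "score", "column_composition"])
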