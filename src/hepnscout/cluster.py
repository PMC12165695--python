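"""Discretized-geometry encoding, greedy clustering and two-stage search.

The search strategy mirrors structure-database practice: a database of CA
traces is encoded into a coarse per-residue geometry alphabet, clustered
greedily around representatives with a fast k-mer prefilter, and queried in
two stages — rank representatives by the prefilter, align the top ones
sensitively, then expand the clusters whose representative passes the hit
rule and align every member. The reduced search space is what makes the
slow, sensitive alignment stage affordable.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .structio import Structure
from .superpose import StructAlignment, align_structures, alignment_zscore

__all__ = [
    "GeometryString",
    "ClusterSet",
    "HitRule",
    "encode_geometry",
    "prefilter_similarity",
    "greedy_cluster",
    "two_stage_search",
]

# pseudo-dihedral windows (degrees) for the three-state alphabet
HELIX_RANGE = (30.0, 80.0)
EXTENDED_MIN_ABS = 140.0
DEFAULT_KMER = 3


@dataclass(frozen=True)
class GeometryString:
    """Three-state geometry string over {H, E, C}, one state per residue
    window; length is residue count minus 3 (undefined at chain ends)."""

    structure_id: str
    states: str

    def __post_init__(self) -> None:
        if set(self.states) - set("HEC"):
            raise ValueError("geometry states must be drawn from {H, E, C}")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class ClusterSet:
    """Greedy clustering result: (representative_id, member_ids) per cluster.

    Every structure belongs to exactly one cluster; a representative is a
    member of its own cluster; every member's prefilter similarity to its
    representative is >= threshold.
    """

    clusters: list[tuple[str, list[str]]]
    threshold: float
    similarities: dict[str, float] = field(default_factory=dict)

    @property
    def representative_ids(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def members_of(self, rep_id: str) -> list[str]:
        for rep, members in self.clusters:
            if rep == rep_id:
                return members
        raise KeyError(rep_id)


def _pseudo_dihedrals(coords: np.ndarray) -> np.ndarray:
    """Dihedral angle (degrees, (-180, 180]) over CA quadruples i-1..i+2."""
    b0 = coords[1:-2] - coords[:-3]
    b1 = coords[2:-1] - coords[1:-2]
    b2 = coords[3:] - coords[2:-1]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    # sign follows the standard convention: right-handed helix ~ +50 degrees
    return -np.degrees(np.arctan2(y, x))


def encode_geometry(s: Structure) -> GeometryString:
    """Encode a CA trace into the {H, E, C} geometry alphabet.

    The state of residue i is derived from the CA pseudo-dihedral over
    residues (i-1, i, i+1, i+2): helix-like for angles in [30, 80] degrees,
    extended-like for |angle| > 140 degrees, coil otherwise. The first and
    the last two residues carry no state.
    """
    if len(s) < 4:
        raise ValueError(f"{s.id}: need >= 4 residues to encode geometry")
    theta = _pseudo_dihedrals(s.coords)
    states = np.full(theta.shape, "C")
    states[(theta >= HELIX_RANGE[0]) & (theta <= HELIX_RANGE[1])] = "H"
    states[np.abs(theta) > EXTENDED_MIN_ABS] = "E"
    return GeometryString(structure_id=s.id, states="".join(states))


def _kmer_counts(states: str, k: int) -> Counter:
    return Counter(states[i : i + k] for i in range(len(states) - k + 1))


def prefilter_similarity(g1: GeometryString, g2: GeometryString, k: int = DEFAULT_KMER) -> float:
    """Cosine similarity of geometry k-mer count vectors (default k = 3)."""
    if len(g1) < k or len(g2) < k:
        warnings.warn("geometry string shorter than k; similarity reported as 0")
        return 0.0
    c1, c2 = _kmer_counts(g1.states, k), _kmer_counts(g2.states, k)
    dot = sum(c1[w] * c2[w] for w in c1.keys() & c2.keys())
    n1 = np.sqrt(sum(v * v for v in c1.values()))
    n2 = np.sqrt(sum(v * v for v in c2.values()))
    return float(dot / (n1 * n2))


def greedy_cluster(
    db: list[Structure], threshold: float = 0.8, k: int = DEFAULT_KMER
) -> ClusterSet:
    """Greedy incremental clustering around representatives.

    Structures are visited longest-first (ties broken by id); each joins the
    first existing representative whose prefilter similarity reaches the
    threshold, otherwise founds a new cluster. Membership is therefore a
    function of (length, id) order, not of input order.
    """
    if not db:
        raise ValueError("empty structure database")
    ordered = sorted(db, key=lambda s: (-len(s), s.id))
    geos = {s.id: encode_geometry(s) if len(s) >= 4 else None for s in ordered}
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    sims: dict[str, float] = {}
    for s in ordered:
        g = geos[s.id]
        placed = False
        if g is not None:
            for rep in reps:
                grep = geos[rep]
                if grep is None:
                    continue
                sim = prefilter_similarity(g, grep, k)
                if sim >= threshold:
                    members[rep].append(s.id)
                    sims[s.id] = sim
                    placed = True
                    break
        if not placed:
            reps.append(s.id)
            members[s.id] = [s.id]
            sims[s.id] = 1.0
    return ClusterSet(
        clusters=[(rep, members[rep]) for rep in reps],
        threshold=threshold,
        similarities=sims,
    )


@dataclass
class HitRule:
    """Hit thresholds for the sensitive stage.

    A target is a hit when tm_query >= tm_min, or — if a Z-score threshold
    is set — when its shuffle-null Z-score reaches z_min. The Z-score is
    computed lazily (only for alignments failing the TM cut) because it
    costs n_null extra alignments.
    """

    tm_min: float = 0.5
    z_min: float | None = 8.0
    z_null: int = 20
    seed: int = 0

    def passes(self, aln: StructAlignment, query: Structure, target: Structure) -> bool:
        if aln.tm_query >= self.tm_min:
            return True
        if self.z_min is None:
            return False
        if aln.zscore is None:
            aln.zscore = alignment_zscore(query, target, n_null=self.z_null, seed=self.seed)
        return aln.zscore >= self.z_min


def two_stage_search(
    query: Structure,
    clusters: ClusterSet,
    structures: dict[str, Structure],
    top_k: int = 50,
    hit_rule: HitRule | None = None,
    k: int = DEFAULT_KMER,
) -> list[StructAlignment]:
    """Prefilter-then-align search over a clustered structure database.

    Stage 1 ranks cluster representatives by geometry-k-mer prefilter
    similarity to the query; stage 2 aligns the top_k representatives
    sensitively; stage 3 expands every cluster whose representative passes
    the hit rule and aligns all its members. Hits are returned sorted by
    tm_query descending (ties by target id).
    """
    if not clusters.clusters:
        return []
    hit_rule = hit_rule or HitRule()
    qg = encode_geometry(query)
    ranked = sorted(
        clusters.representative_ids,
        key=lambda rid: (-prefilter_similarity(qg, encode_geometry(structures[rid]), k), rid),
    )
    hits: dict[str, StructAlignment] = {}
    for rid in ranked[:top_k]:
        rep_aln = align_structures(query, structures[rid])
        if not hit_rule.passes(rep_aln, query, structures[rid]):
            continue
        hits[rid] = rep_aln
        for mid in clusters.members_of(rid):
            if mid in hits:
                continue
            aln = align_structures(query, structures[mid])
            if hit_rule.passes(aln, query, structures[mid]):
                hits[mid] = aln
    return sorted(hits.values(), key=lambda h: (-h.tm_query, h.target_id))
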