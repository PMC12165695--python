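"""Synthetic fixtures: toy structures, perturbations, two-domain chimeras
with planted Rx4H motifs, and genomes with planted CRISPR loci.

This module is the test bed standing in for predicted-structure databases
and real genomes. Every generator is seeded and records exact ground truth
(coordinates, labels, distances) so each detector in the package can be
scored without ambiguity. Two identifiability guarantees follow from that
requirement:

* array boundaries — the columns immediately flanking planted repeat
  instances are resampled until no flanking column is conserved across
  instances, otherwise the true boundary would be informationally
  indistinguishable from the repeat;
* ORF neighborhoods — chance open reading frames in the random background
  at or above the caller's minimum length are disrupted, otherwise
  "nearest ORF" ground truth would be ambiguous.

Background sequence is i.i.d. uniform over ACGT (no GC model); false-call
behaviour on that background is itself a tested property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.spatial.distance import cdist

from .crispr import CrisprArray, Orf, find_orfs
from .hepn import HEPNDimerCall, HEPNMotif, SITE_THRESHOLD
from .structio import Structure

__all__ = [
    "ArraySpec",
    "OrfSpec",
    "GenomeSpec",
    "GenomeTruth",
    "make_helix",
    "make_extended",
    "perturb",
    "make_domain",
    "make_chimera",
    "default_protein",
    "encode_protein",
    "plant_genome",
]

# most-frequent-codon encoding table; A/R/H chosen so that poly-Ala proteins
# with planted R/H motifs contain no internal ATG on either strand (CAT, the
# reverse complement of ATG, never occurs in GCG/CGT/CAC codon runs)
CODON = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAC", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}


def make_helix(
    n: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    sequence: str | None = None,
    id: str = "helix",
) -> Structure:
    """Ideal alpha-helical CA trace.

    Defaults give the canonical ~3.8 A consecutive CA-CA distance
    (1.5 A rise, 100 degrees twist, 2.3 A radius).
    """
    if n < 4:
        raise ValueError("helix needs >= 4 residues")
    i = np.arange(n)
    theta = np.radians(twist) * i
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * i]
    )
    seq = sequence or "A" * n
    if len(seq) != n:
        raise ValueError("sequence length must equal n")
    return Structure(id=id, seq_indices=np.arange(1, n + 1), sequence=seq, coords=coords)


def make_extended(
    n: int, sequence: str | None = None, id: str = "extended"
) -> Structure:
    """Planar zigzag (beta-strand-like) CA trace, CA-CA distance ~3.8 A."""
    if n < 4:
        raise ValueError("extended chain needs >= 4 residues")
    i = np.arange(n)
    coords = np.column_stack([3.68 * i, 0.95 * (i % 2), np.zeros(n)])
    seq = sequence or "A" * n
    if len(seq) != n:
        raise ValueError("sequence length must equal n")
    return Structure(id=id, seq_indices=np.arange(1, n + 1), sequence=seq, coords=coords)


def perturb(s: Structure, sigma: float, seed: int, id: str | None = None) -> Structure:
    """Add i.i.d. Gaussian noise (sd ``sigma`` A per coordinate) to every CA."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=s.coords.shape) if sigma > 0 else 0.0
    return Structure(
        id=id or f"{s.id}_p{seed}",
        seq_indices=s.seq_indices.copy(),
        sequence=s.sequence,
        coords=s.coords + noise,
    )


def make_domain(
    blocks: str = "HE",
    helix_len: int = 18,
    ext_len: int = 12,
    motif: bool = True,
    id: str = "domain",
) -> Structure:
    """A toy HEPN-like domain: secondary-structure blocks laid end to end.

    ``blocks`` is a string over {H, E} giving the block order ("HE" is the
    canonical topology, "EH" its circular permutation). The Rx4H motif, if
    planted, sits inside the (first) helix block.
    """
    if set(blocks) - set("HE") or not blocks:
        raise ValueError("blocks must be a non-empty string over {H, E}")
    parts: list[Structure] = []
    cursor = np.zeros(3)
    helix_start_res = None
    n_before = 0
    for b in blocks:
        part = make_helix(helix_len) if b == "H" else make_extended(ext_len)
        if b == "H" and helix_start_res is None:
            helix_start_res = n_before + 1
        shift = cursor - part.coords[0]
        parts.append(part.transformed(np.eye(3), shift))
        cursor = parts[-1].coords[-1] + np.array([4.5, 0.0, 0.0])
        n_before += len(part)
    coords = np.vstack([p.coords for p in parts])
    n = coords.shape[0]
    seq = list("A" * n)
    if motif:
        if helix_start_res is None:
            raise ValueError("cannot plant a motif without a helix block")
        r = helix_start_res + 9  # 1-based; R..H fits inside the 18-residue helix
        seq[r - 1] = "R"
        seq[r + 4] = "H"
    return Structure(
        id=id, seq_indices=np.arange(1, n + 1), sequence="".join(seq), coords=coords
    )


_DIRECTIONS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (-1, 1, 1),
]


def make_chimera(
    order: tuple[str, str] = ("HE", "HE"),
    his_distance: float = 8.0,
    domainA: Structure | None = None,
    domainB: Structure | None = None,
    id: str = "chimera",
    min_separation: float = 2.5,
) -> tuple[Structure, HEPNDimerCall]:
    """Two-domain protein with planted Rx4H motifs at a stated His-His
    CA distance, plus the exact ground-truth dimer call.

    The second domain is rigidly placed so that the two catalytic-histidine
    CA atoms sit ``his_distance`` A apart, choosing the first placement
    direction that keeps the domains from clashing. The ground-truth call
    records motif positions, the realized His-His distance, the domain
    spans (the true domain extents) and the block-order label
    ("canonical" when both domains match the "HE" reference).
    """
    d1 = domainA or make_domain(order[0], id=f"{id}_d1")
    d2 = domainB or make_domain(order[1], id=f"{id}_d2")
    h1 = d1.sequence.index("H") + 1
    h2 = d2.sequence.index("H") + 1
    his1 = d1.coords[h1 - 1]
    placed = None
    for dvec in _DIRECTIONS:
        u = np.asarray(dvec, float)
        u /= np.linalg.norm(u)
        shift = his1 + u * his_distance - d2.coords[h2 - 1]
        cand = d2.coords + shift
        if cdist(d1.coords, cand).min() >= min_separation:
            placed = cand
            break
    if placed is None:
        raise ValueError("impossible placement: domains clash in every direction")
    n1, n2 = len(d1), len(d2)
    coords = np.vstack([d1.coords, placed])
    seq = d1.sequence + d2.sequence
    s = Structure(
        id=id, seq_indices=np.arange(1, n1 + n2 + 1), sequence=seq, coords=coords
    )
    r1 = d1.sequence.index("R") + 1
    r2 = d2.sequence.index("R") + 1 + n1
    actual = float(np.linalg.norm(coords[h1 - 1] - coords[h2 - 1 + n1]))
    truth = HEPNDimerCall(
        structure_id=id,
        motif1=HEPNMotif(r_pos=r1, h_pos=r1 + 5, context=seq[max(0, r1 - 6) : r1 + 10]),
        motif2=HEPNMotif(r_pos=r2, h_pos=r2 + 5, context=seq[max(0, r2 - 6) : r2 + 10]),
        his_ca_distance=actual,
        composite_site=actual <= SITE_THRESHOLD,
        hepn1_span=(1, n1),
        hepn2_span=(n1 + 1, n1 + n2),
        segment_order="canonical" if tuple(order) == ("HE", "HE") else "rearranged",
    )
    return s, truth


def default_protein(aa_len: int = 450, r_positions: tuple[int, ...] = (127, 363)) -> str:
    """Poly-alanine protein (leading Met) with Rx4H motifs planted so that
    the arginines sit at the given 1-based positions."""
    seq = ["A"] * aa_len
    seq[0] = "M"
    for r in r_positions:
        if not (2 <= r and r + 5 <= aa_len):
            raise ValueError(f"motif at {r} does not fit in {aa_len} residues")
        seq[r - 1] = "R"
        seq[r + 4] = "H"
    return "".join(seq)


ALA_CODONS = ("GCG", "GCC", "GCT")  # GCA excluded: "..CA|T.." would spell a
                                    # reverse-strand ATG at a stop junction


def encode_protein(protein: str, rng: np.random.Generator | None = None) -> str:
    """Coding sequence from the codon table, plus a TAA stop.

    With an rng, alanine codons are drawn from GCG/GCC/GCT so that
    poly-alanine stretches do not encode as a tandem nucleotide repeat
    (which a CRISPR-array finder would rightly flag); other residues use
    their single table codon.
    """
    if not protein or protein[0] != "M":
        raise ValueError("protein must start with Met")
    if rng is None:
        return "".join(CODON[aa] for aa in protein) + "TAA"
    codons = [
        ALA_CODONS[rng.integers(3)] if aa == "A" else CODON[aa] for aa in protein
    ]
    return "".join(codons) + "TAA"


@dataclass(frozen=True)
class ArraySpec:
    start: int
    n_repeats: int = 4
    repeat_len: int = 36
    spacer_len: int = 30

    @property
    def length(self) -> int:
        return self.n_repeats * self.repeat_len + (self.n_repeats - 1) * self.spacer_len


@dataclass(frozen=True)
class OrfSpec:
    start: int
    protein: str | None = None   # default: 450 aa with motifs at R127/R363
    strand: str = "+"


@dataclass
class GenomeSpec:
    """Everything needed to generate one synthetic contig, seeded."""

    seed: int
    contig_id: str = "synthetic_contig"
    length: int = 10000
    arrays: list[ArraySpec] = field(default_factory=list)
    orfs: list[OrfSpec] = field(default_factory=list)
    scrub_min_aa: int = 100


@dataclass
class GenomeTruth:
    """Exact planted coordinates; arrays/ORFs reuse the detector types."""

    arrays: list[CrisprArray]
    orfs: list[Orf]
    proteins: dict[str, str]   # Orf.id -> protein sequence


def _reserved_intervals(spec: GenomeSpec) -> list[tuple[int, int]]:
    ivals = []
    for a in spec.arrays:
        ivals.append((a.start - 1, a.start + a.length + 1))  # flank columns reserved
    for o in spec.orfs:
        protein = o.protein or default_protein()
        ivals.append((o.start, o.start + 3 * (len(protein) + 1)))
    return ivals


def _fix_array_boundaries(
    seq: list[str], spec: ArraySpec, rng: np.random.Generator
) -> bool:
    """Resample flanking columns until neither is conserved across repeat
    instances (modal fraction < 0.75); returns True if bases changed."""
    starts = [
        spec.start + i * (spec.repeat_len + spec.spacer_len)
        for i in range(spec.n_repeats)
    ]
    changed = False
    for offset in (-1, spec.repeat_len):
        cols = [s + offset for s in starts if 0 <= s + offset < len(seq)]
        bases = [seq[c] for c in cols]
        modal = max(bases.count(b) for b in set(bases))
        # no base may flank more than two instances: even a partial seed
        # chain (>= 3 instances) then cannot extend across the boundary
        if modal > 2:
            pattern = list("ACGTACGT")[: len(cols)]
            order = rng.permutation(len(cols))
            for c, k in zip(cols, order):
                if seq[c] != pattern[k]:
                    seq[c] = pattern[k]
                    changed = True
    return changed


def _scrub_background_orfs(
    seq: list[str], planted: list[tuple[int, int]], planted_orfs: set, min_aa: int
) -> bool:
    """Insert stop codons into chance ORFs outside planted features."""
    found = find_orfs("".join(seq), min_aa=min_aa)
    changed = False
    for orf in found:
        if (orf.span, orf.strand) in planted_orfs:
            continue
        # pick the first in-frame codon (skipping the start codon) fully
        # outside every planted interval and stop it
        span_len = orf.span[1] - orf.span[0]
        broke = False
        for ci in range(1, span_len // 3 - 1):
            if orf.strand == "+":
                lo = orf.span[0] + 3 * ci
            else:
                lo = orf.span[1] - 3 * (ci + 1)
            hi = lo + 3
            if any(lo < pe and ps < hi for ps, pe in planted):
                continue
            stop = "TAA" if orf.strand == "+" else "TTA"
            seq[lo:hi] = list(stop)
            changed = broke = True
            break
        if not broke:
            # every internal codon overlaps a planted feature (a run-through
            # ORF in an alternate frame of a planted gene); kill its start
            # codon instead, if that lies in background
            lo = orf.span[0] if orf.strand == "+" else orf.span[1] - 3
            hi = lo + 3
            if not any(lo < pe and ps < hi for ps, pe in planted):
                seq[lo:hi] = list("CCC" if orf.strand == "+" else "GGG")
                changed = True
    return changed


def plant_genome(spec: GenomeSpec) -> tuple[SeqRecord, GenomeTruth]:
    """Generate a synthetic contig with planted CRISPR arrays and ORFs.

    Background is i.i.d. uniform ACGT; planted arrays use identical repeat
    copies with random spacers; planted ORFs encode their proteins with the
    most-frequent-codon table. Ground truth carries exact 0-based half-open
    coordinates. Same spec and seed give a byte-identical sequence.
    """
    rng = np.random.default_rng(spec.seed)
    reserved = sorted(_reserved_intervals(spec))
    for (a, b), (c, d) in zip(reserved, reserved[1:]):
        if c < b:
            raise ValueError("planted features overlap")
    if reserved and (reserved[0][0] < 0 or reserved[-1][1] > spec.length):
        raise ValueError("planted features do not fit in the contig")

    seq = list(rng.choice(list("ACGT"), size=spec.length))

    truth_orfs: list[Orf] = []
    proteins: dict[str, str] = {}
    planted_orf_keys = set()
    for ospec in spec.orfs:
        protein = ospec.protein or default_protein()
        nt = encode_protein(protein, rng)
        if ospec.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        seq[ospec.start : ospec.start + len(nt)] = list(nt)
        span = (ospec.start, ospec.start + len(nt))
        orf = Orf(spec.contig_id, span, ospec.strand, len(protein))
        truth_orfs.append(orf)
        proteins[orf.id] = protein
        planted_orf_keys.add((span, ospec.strand))

    array_repeats: dict[int, str] = {}
    for ai, aspec in enumerate(spec.arrays):
        repeat = "".join(rng.choice(list("ACGT"), size=aspec.repeat_len))
        array_repeats[ai] = repeat
        pos = aspec.start
        spacers_drawn: list[str] = []
        for i in range(aspec.n_repeats):
            seq[pos : pos + aspec.repeat_len] = list(repeat)
            pos += aspec.repeat_len
            if i < aspec.n_repeats - 1:
                # spacers must be mutually diverse so the array is
                # unambiguously distinguishable from a tandem repeat
                for _ in range(50):
                    spacer = "".join(rng.choice(list("ACGT"), size=aspec.spacer_len))
                    if all(
                        sum(a == b for a, b in zip(spacer, prev)) / aspec.spacer_len
                        <= 0.55
                        for prev in spacers_drawn
                    ):
                        break
                else:
                    raise RuntimeError("failed to draw diverse spacers")
                spacers_drawn.append(spacer)
                seq[pos : pos + aspec.spacer_len] = list(spacer)
                pos += aspec.spacer_len

    planted = [iv for iv in reserved]
    for _ in range(100):
        changed = _scrub_background_orfs(seq, planted, planted_orf_keys, spec.scrub_min_aa)
        for aspec in spec.arrays:
            changed |= _fix_array_boundaries(seq, aspec, rng)
        if not changed:
            break
    else:
        raise RuntimeError("genome generation did not converge")

    truth_arrays: list[CrisprArray] = []
    text = "".join(seq)
    for ai, aspec in enumerate(spec.arrays):
        period = aspec.repeat_len + aspec.spacer_len
        reps, spcs = [], []
        for i in range(aspec.n_repeats):
            s = aspec.start + i * period
            reps.append(((s, s + aspec.repeat_len), text[s : s + aspec.repeat_len]))
            if i < aspec.n_repeats - 1:
                sp = (s + aspec.repeat_len, s + period)
                spcs.append((sp, text[sp[0] : sp[1]]))
        truth_arrays.append(
            CrisprArray(
                contig_id=spec.contig_id,
                span=(aspec.start, aspec.start + aspec.length),
                repeats=reps,
                spacers=spcs,
                repeat_consensus=array_repeats[ai],
            )
        )

    record = SeqRecord(Seq(text), id=spec.contig_id, description="synthetic")
    return record, GenomeTruth(arrays=truth_arrays, orfs=truth_orfs, proteins=proteins)
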