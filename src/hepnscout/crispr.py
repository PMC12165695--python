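"""CRISPR array detection, ORF calling, locus association and crRNA
processing arithmetic.

Array finding is seed-and-extend ("CRT-style"): an exact 8-mer recurring at
array-like periods seeds a chain of candidate repeat instances, whose
boundaries are then extended column-by-column while the per-column base
agreement across instances stays at or above 0.75, and validated against
repeat/spacer length envelopes. This is deterministic and well suited to
the high-identity repeats of conserved arrays; degenerate-repeat arrays are
out of scope.

The processing arithmetic interprets 5'-label assays of pre-crRNA
maturation for the spacer-before-repeat crRNA architecture: a 5' label at
the spacer's 5' end that ends up on a fragment of length f after cleavage
of a spacer of length s implies a cut s - f nt upstream of the
spacer-repeat junction, a mature spacer of s - f nt, and a mature crRNA of
(s - f) + repeat_length nt.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hepn import HEPNDimerCall

__all__ = [
    "ArrayParams",
    "CrisprArray",
    "Orf",
    "LocusCall",
    "SpacerHit",
    "ProcessingCall",
    "find_orfs",
    "orf_protein",
    "find_crispr_arrays",
    "associate_arrays_to_genes",
    "spacer_target_search",
    "infer_cleavage_offset",
    "mature_crrna_length",
    "write_gff3",
    "read_gff3",
    "write_bed",
    "read_bed",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ArrayParams:
    """Detection envelopes for CRISPR arrays.

    Defaults follow common CRISPR-detection practice; the envelope admits
    the 36 nt repeat / 30 nt spacer architecture of compact type VI loci.
    """

    kmer: int = 8
    window: int = 200          # max bp between successive seed occurrences
    min_repeats: int = 3
    repeat_len: tuple[int, int] = (23, 47)
    spacer_len: tuple[int, int] = (15, 60)
    agreement: float = 0.75    # per-column modal-base fraction for extension
    spacer_identity_max: float = 0.6  # spacers must be diverse, unlike the
                                      # pseudo-spacers of tandem repeats

    @property
    def min_period(self) -> int:
        return self.repeat_len[0] + self.spacer_len[0]

    @property
    def max_period(self) -> int:
        return min(self.window, self.repeat_len[1] + self.spacer_len[1])


@dataclass
class CrisprArray:
    """A repeat-spacer array; all intervals 0-based half-open, ascending."""

    contig_id: str
    span: tuple[int, int]
    repeats: list[tuple[tuple[int, int], str]]
    spacers: list[tuple[tuple[int, int], str]]
    repeat_consensus: str

    def __post_init__(self) -> None:
        ivals = []
        for i, (rep, spc) in enumerate(zip(self.repeats, self.spacers + [None])):
            ivals.append(rep[0])
            if spc is not None:
                ivals.append(spc[0])
        for (a, b), (c, d) in zip(ivals, ivals[1:]):
            if not (a < b == c < d):
                raise ValueError("repeat/spacer intervals must alternate contiguously")
        if len(self.repeats) != len(self.spacers) + 1:
            raise ValueError("an array has one more repeat than spacers")

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


@dataclass(frozen=True)
class Orf:
    """An open reading frame; span is 0-based half-open and includes the
    stop codon, so aa_length = span/3 - 1 (start Met counted, stop not)."""

    contig_id: str
    span: tuple[int, int]
    strand: str
    aa_length: int

    def __post_init__(self) -> None:
        length = self.span[1] - self.span[0]
        if length % 3 != 0:
            raise ValueError("ORF span must be divisible by 3")
        if self.aa_length != length // 3 - 1:
            raise ValueError("aa_length inconsistent with span")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def id(self) -> str:
        return f"{self.contig_id}:{self.span[0]}-{self.span[1]}({self.strand})"


@dataclass
class LocusCall:
    """An array paired with its nearest ORF; a Cas13-like candidate locus
    requires proximity and an intramolecular HEPN dimer on the protein."""

    array: CrisprArray
    orf: Orf
    distance_bp: int
    hepn_dimer: HEPNDimerCall | None
    cas13_candidate: bool


@dataclass(frozen=True)
class SpacerHit:
    spacer_id: str
    target_id: str
    strand: str
    position: int      # 0-based start of the match on the forward target
    mismatches: int


@dataclass(frozen=True)
class ProcessingCall:
    """crRNA processing arithmetic for the spacer-before-repeat architecture."""

    spacer_len: int
    repeat_len: int
    fragment_len: int
    offset_upstream_of_repeat: int
    mature_spacer_len: int
    mature_crrna_len: int

    def __post_init__(self) -> None:
        if min(
            self.spacer_len, self.repeat_len, self.fragment_len,
            self.offset_upstream_of_repeat, self.mature_spacer_len,
            self.mature_crrna_len,
        ) < 0:
            raise ValueError("all lengths must be non-negative")
        if self.offset_upstream_of_repeat != self.spacer_len - self.fragment_len:
            raise ValueError("offset must equal spacer_len - fragment_len")
        if self.mature_crrna_len != self.mature_spacer_len + self.repeat_len:
            raise ValueError("mature crRNA length must be spacer + repeat")


def _as_str(contig: SeqRecord | str) -> tuple[str, str]:
    if isinstance(contig, SeqRecord):
        return contig.id, str(contig.seq).upper()
    return "contig", str(contig).upper()


def find_orfs(contig: SeqRecord | str, min_aa: int = 100) -> list[Orf]:
    """ORFs (ATG to stop, standard code) of at least ``min_aa`` residues on
    both strands, one per terminated segment (leftmost ATG), sorted by start.
    """
    cid, seq = _as_str(contig)
    L = len(seq)
    orfs: list[Orf] = []

    def scan(s: str, strand: str) -> None:
        for frame in range(3):
            start = None
            for p in range(frame, len(s) - 2, 3):
                codon = s[p : p + 3]
                if codon in _STOPS:
                    if start is not None:
                        aa = (p + 3 - start) // 3 - 1
                        if aa >= min_aa:
                            if strand == "+":
                                span = (start, p + 3)
                            else:
                                span = (L - (p + 3), L - start)
                            orfs.append(Orf(cid, span, strand, aa))
                        start = None
                elif codon == "ATG" and start is None:
                    start = p

    scan(seq, "+")
    scan(str(Seq(seq).reverse_complement()), "-")
    return sorted(orfs, key=lambda o: (o.span, o.strand))


def orf_protein(contig: SeqRecord | str, orf: Orf) -> str:
    """Translated protein of an ORF (stop stripped)."""
    _, seq = _as_str(contig)
    sub = seq[orf.span[0] : orf.span[1]]
    if orf.strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return str(Seq(sub).translate()).rstrip("*")


def _longest_chain(
    start: int, occs: list[int], min_per: int, max_per: int, memo: dict[int, list[int]]
) -> list[int]:
    if start in memo:
        return memo[start]
    best = [start]
    for q in occs:
        if q <= start + min_per - 1:
            continue
        if q > start + max_per:
            break
        cand = [start] + _longest_chain(q, occs, min_per, max_per, memo)
        if len(cand) > len(best):
            best = cand
    memo[start] = best
    return best


def _column_agreement(seq: str, cols: list[int]) -> float:
    bases = [seq[c] for c in cols if 0 <= c < len(seq)]
    if len(bases) < len(cols):
        return 0.0
    return max(Counter(bases).values()) / len(bases)


def find_crispr_arrays(
    contig: SeqRecord | str, params: ArrayParams | None = None
) -> list[CrisprArray]:
    """Seed-and-extend CRISPR array detection.

    Exact k-mer seeds recurring at array-like periods are chained (longest
    chain wins), boundaries are extended while per-column agreement across
    instances meets the threshold, and the result is validated against the
    repeat/spacer envelopes. Returns maximal non-overlapping arrays in
    coordinate order; deterministic.
    """
    params = params or ArrayParams()
    cid, seq = _as_str(contig)
    L = len(seq)
    k = params.kmer
    if L < params.min_repeats * params.min_period:
        return []

    positions: dict[str, list[int]] = {}
    for p in range(L - k + 1):
        positions.setdefault(seq[p : p + k], []).append(p)

    arrays: list[CrisprArray] = []
    resume = 0
    p = 0
    while p <= L - k:
        if p < resume:
            p = resume
            continue
        occs = positions[seq[p : p + k]]
        if len(occs) < params.min_repeats:
            p += 1
            continue
        chain = _longest_chain(p, occs, params.min_period, params.max_period, {})
        if len(chain) < params.min_repeats:
            p += 1
            continue
        array = _build_array(cid, seq, chain, params)
        if array is None:
            p += 1
            continue
        arrays.append(array)
        resume = array.span[1]
        p = resume
    return arrays


def _build_array(
    cid: str, seq: str, anchors: list[int], params: ArrayParams
) -> CrisprArray | None:
    k, rmax = params.kmer, params.repeat_len[1]
    # extend right from the seed, then left, while columns agree
    ext_r = 0
    while k + ext_r < rmax and _column_agreement(seq, [a + k + ext_r for a in anchors]) >= params.agreement:
        ext_r += 1
    ext_l = 0
    while (
        k + ext_r + ext_l < rmax
        and _column_agreement(seq, [a - ext_l - 1 for a in anchors]) >= params.agreement
    ):
        ext_l += 1
    rlen = k + ext_r + ext_l
    if not (params.repeat_len[0] <= rlen <= rmax):
        return None
    starts = [a - ext_l for a in anchors]
    if starts[0] < 0 or starts[-1] + rlen > len(seq):
        return None
    # validate spacer gaps; trim trailing instances if a gap breaks the envelope
    valid = [starts[0]]
    for s in starts[1:]:
        gap = s - (valid[-1] + rlen)
        if params.spacer_len[0] <= gap <= params.spacer_len[1]:
            valid.append(s)
        else:
            break
    if len(valid) < params.min_repeats:
        return None
    repeats = [((s, s + rlen), seq[s : s + rlen]) for s in valid]
    spacers = [
        ((a + rlen, b), seq[a + rlen : b]) for a, b in zip(valid, valid[1:])
    ]
    cols = list(zip(*(r[1] for r in repeats)))
    consensus = "".join(sorted(Counter(c).items(), key=lambda kv: (-kv[1], kv[0]))[0][0] for c in cols)
    # a chance seed occurrence in flanking sequence can ride along as a fake
    # leading/trailing instance; drop end instances that do not resemble the
    # consensus and rebuild from the surviving anchors
    def _identity(rep_seq: str) -> float:
        return sum(a == b for a, b in zip(rep_seq, consensus)) / rlen

    keep = list(range(len(valid)))
    while keep and _identity(repeats[keep[0]][1]) < params.agreement:
        keep.pop(0)
    while keep and _identity(repeats[keep[-1]][1]) < params.agreement:
        keep.pop()
    if len(keep) < len(valid):
        if len(keep) < params.min_repeats:
            return None
        offset = valid[0] - anchors[0]  # anchors sit at a fixed offset in the repeat
        surviving = [valid[i] - offset for i in keep]
        return _build_array(cid, seq, surviving, params)
    # true spacers are diverse; self-similar "spacers" indicate a tandem
    # repeat (e.g. low-complexity or coding-sequence periodicity), not CRISPR
    if len(spacers) >= 2:
        idents = []
        for i in range(len(spacers)):
            for j in range(i + 1, len(spacers)):
                s1, s2 = spacers[i][1], spacers[j][1]
                n = min(len(s1), len(s2))
                idents.append(sum(a == b for a, b in zip(s1[:n], s2[:n])) / n)
        if sum(idents) / len(idents) > params.spacer_identity_max:
            return None
    return CrisprArray(
        contig_id=cid,
        span=(valid[0], valid[-1] + rlen),
        repeats=repeats,
        spacers=spacers,
        repeat_consensus=consensus,
    )


def associate_arrays_to_genes(
    arrays: list[CrisprArray],
    orfs: list[Orf],
    hepn_calls: dict[str, HEPNDimerCall] | None = None,
    max_distance: int = 3000,
) -> list[LocusCall]:
    """Pair each array with its nearest ORF (edge-to-edge distance).

    A locus is a Cas13-like candidate when the nearest ORF lies within
    ``max_distance`` bp and carries an intramolecular HEPN dimer
    (``hepn_calls`` maps Orf.id to its dimer call).
    """
    hepn_calls = hepn_calls or {}
    calls: list[LocusCall] = []
    for array in arrays:
        candidates = [o for o in orfs if o.contig_id == array.contig_id]
        if not candidates:
            continue
        def edge_distance(o: Orf) -> int:
            if o.span[1] <= array.span[0]:
                return array.span[0] - o.span[1]
            if array.span[1] <= o.span[0]:
                return o.span[0] - array.span[1]
            return 0
        nearest = min(candidates, key=lambda o: (edge_distance(o), o.span[0]))
        dimer = hepn_calls.get(nearest.id)
        calls.append(
            LocusCall(
                array=array,
                orf=nearest,
                distance_bp=edge_distance(nearest),
                hepn_dimer=dimer,
                cas13_candidate=(
                    edge_distance(nearest) <= max_distance
                    and dimer is not None
                    and dimer.composite_site
                ),
            )
        )
    return calls


def _hamming_positions(pattern: str, text: str, max_mm: int) -> list[tuple[int, int]]:
    m, n = len(pattern), len(text)
    if m > n:
        return []
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mism = (windows != p).sum(axis=1)
    return [(int(i), int(mm)) for i, mm in enumerate(mism) if mm <= max_mm]


def spacer_target_search(
    spacers: list[SeqRecord],
    targets: list[SeqRecord],
    max_mismatch: int = 2,
) -> list[SpacerHit]:
    """All Hamming matches (no indels) of each spacer on both target strands.

    Positions are 0-based starts on the forward target; strand '-' means the
    reverse complement of the spacer matched the forward strand there.
    """
    hits: list[SpacerHit] = []
    for sp in spacers:
        sps = str(sp.seq).upper()
        if len(sps) < 15:
            raise ValueError(f"spacer {sp.id} shorter than 15 nt")
        rc = str(Seq(sps).reverse_complement())
        for tg in targets:
            text = str(tg.seq).upper()
            for pos, mm in _hamming_positions(sps, text, max_mismatch):
                hits.append(SpacerHit(sp.id, tg.id, "+", pos, mm))
            for pos, mm in _hamming_positions(rc, text, max_mismatch):
                hits.append(SpacerHit(sp.id, tg.id, "-", pos, mm))
    return sorted(hits, key=lambda h: (h.spacer_id, h.target_id, h.position, h.strand))


def infer_cleavage_offset(
    spacer_len: int, fragment_len: int, repeat_len: int = 36
) -> ProcessingCall:
    """Cleavage-site arithmetic for a 5'-labeled spacer-repeat crRNA.

    The label sits at the spacer's 5' end and the spacer precedes the
    repeat, so a labeled product of ``fragment_len`` nt places the cut
    ``spacer_len - fragment_len`` nt upstream of the spacer-repeat
    junction; the mature spacer is what remains of the spacer, and the
    mature crRNA adds the full repeat.
    """
    if spacer_len < 0 or fragment_len < 0:
        raise ValueError("lengths must be non-negative")
    if fragment_len > spacer_len:
        raise ValueError(
            "fragment longer than spacer: the 5' label would lie in the repeat"
        )
    offset = spacer_len - fragment_len
    return ProcessingCall(
        spacer_len=spacer_len,
        repeat_len=repeat_len,
        fragment_len=fragment_len,
        offset_upstream_of_repeat=offset,
        mature_spacer_len=offset,
        mature_crrna_len=offset + repeat_len,
    )


def mature_crrna_length(repeat_len: int, mature_spacer_len: int) -> int:
    """Length of the mature single-RNA guide: spacer remnant plus repeat."""
    if repeat_len < 0 or mature_spacer_len < 0:
        raise ValueError("lengths must be non-negative")
    return repeat_len + mature_spacer_len


# ---------------------------------------------------------------------------
# interval serialization (GFF3 / BED); all in-memory coordinates are 0-based
# half-open, GFF3 on disk is 1-based inclusive


def write_gff3(
    arrays: list[CrisprArray], orfs: list[Orf], path: str | Path
) -> None:
    lines = ["##gff-version 3"]
    for i, a in enumerate(arrays, 1):
        aid = f"array{i}"
        lines.append(
            f"{a.contig_id}\thepnscout\trepeat_region\t{a.span[0] + 1}\t{a.span[1]}\t.\t.\t.\t"
            f"ID={aid};consensus={a.repeat_consensus}"
        )
        for j, ((s, e), _seq) in enumerate(a.repeats, 1):
            lines.append(
                f"{a.contig_id}\thepnscout\trepeat_unit\t{s + 1}\t{e}\t.\t.\t.\t"
                f"ID={aid}.r{j};Parent={aid}"
            )
    for o in orfs:
        lines.append(
            f"{o.contig_id}\thepnscout\tCDS\t{o.span[0] + 1}\t{o.span[1]}\t.\t{o.strand}\t0\t"
            f"ID={o.id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[tuple[str, str, tuple[int, int], str]]:
    """(contig, feature_type, 0-based half-open span, strand) per feature."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        out.append((f[0], f[2], (int(f[3]) - 1, int(f[4])), f[6]))
    return out


def write_bed(
    intervals: list[tuple[str, int, int, str]], path: str | Path
) -> None:
    """(contig, start, end, name) rows; BED is natively 0-based half-open."""
    Path(path).write_text(
        "\n".join(f"{c}\t{s}\t{e}\t{n}" for c, s, e, n in intervals) + "\n"
    )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if line:
            c, s, e, n = line.split("\t")[:4]
            out.append((c, int(s), int(e), n))
    return out
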