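"""Rx4H motif scanning and intramolecular HEPN-dimer calling.

HEPN ribonuclease domains carry an R-x(4)-H catalytic motif: an arginine,
four arbitrary residues, a histidine, both catalytic. The defining feature
of Cas13-like effectors is a pair of HEPN domains within one polypeptide
whose two Rx4H loops juxtapose to form a single composite active site. On a
CA-only model that juxtaposition is proxied by the distance between the two
catalytic-histidine CA atoms: a pair of motifs whose histidines sit within
the site threshold (default 12 A) is called an intramolecular dimer.

Domain rearrangement relative to a canonical HEPN topology is classified by
comparing the linear order of secondary-structure blocks (from the geometry
alphabet) within each domain span against a reference block order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cluster import encode_geometry
from .structio import Structure

__all__ = [
    "HEPNMotif",
    "HEPNDimerCall",
    "scan_rx4h",
    "detect_intramolecular_dimer",
    "classify_segment_order",
    "split_domains",
    "geometry_blocks",
    "write_dimer_tsv",
    "write_span_bed",
]

RX4H = re.compile(r"(?=R.{4}H)")
SITE_THRESHOLD = 12.0       # A between catalytic-His CA atoms
MIN_SPAN_FOR_BLOCKS = 8     # residues needed to derive a block order
MIN_BLOCK_LEN = 3           # geometry states per secondary-structure block


@dataclass(frozen=True)
class HEPNMotif:
    """One R-x(4)-H match; positions are 1-based, h_pos = r_pos + 5."""

    r_pos: int
    h_pos: int
    context: str

    def __post_init__(self) -> None:
        if self.h_pos != self.r_pos + 5:
            raise ValueError("Rx4H motif requires h_pos = r_pos + 5")


@dataclass
class HEPNDimerCall:
    """A motif pair forming (or failing to form) a composite active site.

    Spans are 1-based inclusive residue intervals covering the two putative
    HEPN domains, split at the midpoint between the motifs.
    """

    structure_id: str
    motif1: HEPNMotif
    motif2: HEPNMotif
    his_ca_distance: float
    composite_site: bool
    hepn1_span: tuple[int, int]
    hepn2_span: tuple[int, int]
    segment_order: str | None = None

    def __post_init__(self) -> None:
        if self.motif1.r_pos >= self.motif2.r_pos:
            raise ValueError("motif1 must precede motif2")
        s1, s2 = self.hepn1_span, self.hepn2_span
        if not (s1[0] <= s1[1] < s2[0] <= s2[1]):
            raise ValueError("spans must be ordered and disjoint")


def scan_rx4h(seq: str) -> list[HEPNMotif]:
    """All (possibly overlapping) R-x(4)-H matches, ascending by position.

    Coordinates are 1-based, matching the R127/H132 convention used for
    catalytic-residue mutants.
    """
    seq = seq.upper()
    motifs = []
    for m in RX4H.finditer(seq):
        r = m.start() + 1
        lo, hi = max(0, m.start() - 5), min(len(seq), m.start() + 11)
        motifs.append(HEPNMotif(r_pos=r, h_pos=r + 5, context=seq[lo:hi]))
    return motifs


def detect_intramolecular_dimer(
    s: Structure, site_threshold: float = SITE_THRESHOLD
) -> HEPNDimerCall | None:
    """Call an intramolecular HEPN dimer from motif-pair geometry.

    Among all Rx4H motif pairs, the pair with the minimum catalytic-His CA
    distance is taken; a call is returned only when that distance is within
    the site threshold. Fewer than two motifs, or no pair within threshold,
    yields None (not an error). The chain is split into the two domain
    spans at the midpoint between motif1's histidine and motif2's arginine.
    """
    motifs = scan_rx4h(s.sequence)
    if len(motifs) < 2:
        return None
    best: tuple[float, HEPNMotif, HEPNMotif] | None = None
    for i, m1 in enumerate(motifs):
        for m2 in motifs[i + 1 :]:
            if m2.r_pos <= m1.h_pos:
                continue  # overlapping motifs cannot be two domains
            d = float(
                np.linalg.norm(s.coords[m1.h_pos - 1] - s.coords[m2.h_pos - 1])
            )
            if best is None or d < best[0]:
                best = (d, m1, m2)
    if best is None or best[0] > site_threshold:
        return None
    d, m1, m2 = best
    mid = (m1.h_pos + m2.r_pos) // 2
    return HEPNDimerCall(
        structure_id=s.id,
        motif1=m1,
        motif2=m2,
        his_ca_distance=d,
        composite_site=True,
        hepn1_span=(1, mid),
        hepn2_span=(mid + 1, len(s)),
    )


def geometry_blocks(s: Structure, min_block: int = MIN_BLOCK_LEN) -> str:
    """Linear order of secondary-structure blocks in a (sub)structure.

    Coil states are dropped; runs of H or E shorter than ``min_block``
    states are treated as encoding noise and ignored. Returns a string like
    "HE" (one letter per block).
    """
    states = encode_geometry(s).states
    blocks = []
    run_char, run_len = "", 0
    for c in states + "$":
        if c == run_char:
            run_len += 1
            continue
        if run_char in "HE" and run_len >= min_block:
            if not blocks or blocks[-1] != run_char:
                blocks.append(run_char)
        run_char, run_len = c, 1
    return "".join(blocks)


def classify_segment_order(
    s: Structure,
    call: HEPNDimerCall,
    reference: tuple[str, str] = ("HE", "HE"),
) -> str:
    """Label a dimer call "canonical" or "rearranged" by block order.

    The geometry-block order within each domain span is compared against
    the canonical reference descriptor (one block string per domain).
    Spans too short to derive blocks give "undetermined". The label is
    stored on the call and returned.
    """
    spans = (call.hepn1_span, call.hepn2_span)
    orders = []
    for lo, hi in spans:
        if hi - lo + 1 < MIN_SPAN_FOR_BLOCKS:
            call.segment_order = "undetermined"
            return call.segment_order
        blocks = geometry_blocks(s.subset(lo, hi))
        if not blocks:
            call.segment_order = "undetermined"
            return call.segment_order
        orders.append(blocks)
    label = "canonical" if (orders[0], orders[1]) == tuple(reference) else "rearranged"
    call.segment_order = label
    return label


def split_domains(s: Structure, call: HEPNDimerCall) -> tuple[Structure, Structure]:
    """Cut the chain into its two HEPN-domain spans for use as new queries.

    Coordinates are unchanged; ids get "_HEPN1"/"_HEPN2" suffixes. Splitting
    a remote hit into its individual domains and re-searching with each is
    how shared structural ancestry of the two domains is probed.
    """
    d1 = s.subset(*call.hepn1_span, new_id=f"{s.id}_HEPN1")
    d2 = s.subset(*call.hepn2_span, new_id=f"{s.id}_HEPN2")
    return d1, d2


def write_dimer_tsv(calls: list[HEPNDimerCall], path: str | Path) -> None:
    """Dimer calls as TSV; motif positions 1-based."""
    lines = [
        "structure_id\tr1_pos\th1_pos\tr2_pos\th2_pos\this_ca_distance\t"
        "composite_site\tsegment_order\thepn1_start\thepn1_end\thepn2_start\thepn2_end"
    ]
    for c in calls:
        lines.append(
            f"{c.structure_id}\t{c.motif1.r_pos}\t{c.motif1.h_pos}\t"
            f"{c.motif2.r_pos}\t{c.motif2.h_pos}\t{c.his_ca_distance:.3f}\t"
            f"{c.composite_site}\t{c.segment_order or 'unclassified'}\t"
            f"{c.hepn1_span[0]}\t{c.hepn1_span[1]}\t{c.hepn2_span[0]}\t{c.hepn2_span[1]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_span_bed(calls: list[HEPNDimerCall], path: str | Path) -> None:
    """Domain spans as BED (0-based half-open residue intervals)."""
    lines = []
    for c in calls:
        for name, (lo, hi) in (("HEPN1", c.hepn1_span), ("HEPN2", c.hepn2_span)):
            lines.append(f"{c.structure_id}\t{lo - 1}\t{hi}\t{name}")
    Path(path).write_text("\n".join(lines) + "\n")
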