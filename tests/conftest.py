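"""Shared fixtures: toy structure families, a clustered search database and
the planted end-to-end discovery scenario.

Expensive fixtures are session-scoped so unit, integration and acceptance
tests reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from hepnscout.hepn import detect_intramolecular_dimer, split_domains
from hepnscout.pipeline import DiscoveryConfig, run_discovery
from hepnscout.structio import Structure
from hepnscout.synth import (
    ArraySpec,
    GenomeSpec,
    OrfSpec,
    make_chimera,
    make_domain,
    make_extended,
    make_helix,
    perturb,
    plant_genome,
)


def random_additive_matrix(rng: np.random.Generator, n: int):
    """Distances generated from a random binary tree with branch lengths
    U(0.1, 2); the generating tree is the oracle (an additive metric
    corresponds to exactly one tree)."""
    from skbio import DistanceMatrix

    clusters = [{f"T{i}": 0.0} for i in range(n)]
    dist: dict[tuple[str, str], float] = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        b1, b2 = rng.uniform(0.1, 2.0, 2)
        c1, c2 = clusters[i], clusters[j]
        for l1, d1 in c1.items():
            for l2, d2 in c2.items():
                dist[tuple(sorted((l1, l2)))] = d1 + b1 + d2 + b2
        merged = {l: d + b1 for l, d in c1.items()}
        merged.update({l: d + b2 for l, d in c2.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    labels = [f"T{i}" for i in range(n)]
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            m[a, b] = m[b, a] = dist[tuple(sorted((labels[a], labels[b])))]
    return DistanceMatrix(m, labels)


def strip_motifs(s: Structure, new_id: str) -> Structure:
    """Same fold, catalytic residues mutated out (decoy for the dimer filter)."""
    return Structure(
        id=new_id,
        seq_indices=s.seq_indices.copy(),
        sequence=s.sequence.replace("R", "A").replace("H", "A"),
        coords=s.coords.copy(),
    )


def set_residue(s: Structure, pos: int, aa: str) -> Structure:
    seq = list(s.sequence)
    seq[pos - 1] = aa
    return Structure(
        id=s.id, seq_indices=s.seq_indices.copy(), sequence="".join(seq), coords=s.coords.copy()
    )


@pytest.fixture(scope="session")
def helix20() -> Structure:
    return make_helix(20, id="helix20")


@pytest.fixture(scope="session")
def extended20() -> Structure:
    return make_extended(20, id="extended20")


@pytest.fixture(scope="session")
def helix40() -> Structure:
    return make_helix(40, id="helix40")


@pytest.fixture(scope="session")
def db60() -> tuple[list[Structure], Structure]:
    """30-structure database (three 60-residue fold families) plus a query
    belonging to the first family. Used for search-equivalence checks."""
    base, _ = make_chimera(("EH", "EH"), his_distance=8.0, id="fam_a_base")
    hel = make_helix(60, id="fam_b_base")
    ext = make_extended(60, id="fam_c_base")
    db: list[Structure] = []
    for i in range(10):
        db.append(perturb(base, 0.4, seed=200 + i, id=f"fam_a{i + 1}"))
    for i in range(10):
        db.append(perturb(hel, 0.4, seed=300 + i, id=f"fam_b{i + 1}"))
    for i in range(10):
        db.append(perturb(ext, 0.4, seed=400 + i, id=f"fam_c{i + 1}"))
    query = perturb(base, 0.3, seed=999, id="query60")
    return db, query


@pytest.fixture(scope="session")
def discovery_fixture() -> dict:
    """Planted end-to-end scenario: a 30-structure database whose chimera
    family contains three motif-bearing (rearranged) dimer proteins, and
    three genomes each encoding one of them next to a planted array."""
    dA = make_domain("EH", helix_len=30, ext_len=20, id="dA")
    dB = make_domain("EH", helix_len=30, ext_len=20, id="dB")
    base, _ = make_chimera(("EH", "EH"), his_distance=8.0, domainA=dA, domainB=dB, id="base")
    db: list[Structure] = []
    positives: list[Structure] = []
    for i in range(3):
        p = set_residue(perturb(base, 0.4, seed=100 + i, id=f"cas_pos{i + 1}"), 3, "STV"[i])
        positives.append(p)
        db.append(p)
    for i in range(7):
        db.append(strip_motifs(perturb(base, 0.4, seed=200 + i, id=f"fam_a{i + 1}"), f"fam_a{i + 1}"))
    hel = make_helix(100, id="hel")
    ext = make_extended(100, id="ext")
    for i in range(10):
        db.append(perturb(hel, 0.4, seed=300 + i, id=f"fam_b{i + 1}"))
    for i in range(10):
        db.append(perturb(ext, 0.4, seed=400 + i, id=f"fam_c{i + 1}"))
    query = perturb(base, 0.3, seed=999, id="query_hepn_dimer")
    genomes = []
    truths = []
    for i, p in enumerate(positives):
        rec, gt = plant_genome(
            GenomeSpec(
                seed=50 + i,
                length=6000,
                contig_id=f"g{i + 1}",
                arrays=[ArraySpec(start=1000)],
                orfs=[OrfSpec(start=1800, protein="M" + p.sequence)],
            )
        )
        genomes.append(rec)
        truths.append(gt)
    return {
        "base": base,
        "db": db,
        "query": query,
        "positives": positives,
        "genomes": genomes,
        "truths": truths,
        "config": DiscoveryConfig(),
    }


@pytest.fixture(scope="session")
def discovery_report(discovery_fixture):
    return run_discovery(
        [discovery_fixture["query"]],
        discovery_fixture["db"],
        discovery_fixture["genomes"],
        discovery_fixture["config"],
    )


@pytest.fixture(scope="session")
def split_domain_report(discovery_fixture):
    """The shared-hits strategy: search with the two isolated domains of a
    planted dimer protein as separate queries."""
    base = discovery_fixture["base"]
    call = detect_intramolecular_dimer(base)
    d1, d2 = split_domains(base, call)
    return run_discovery([d1, d2], discovery_fixture["db"], None, discovery_fixture["config"])
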