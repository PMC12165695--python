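"""CRISPR array detection and effector-locus association.

Generates a synthetic genome with one planted repeat-spacer array (4 x 36 nt
identical repeats, 30 nt random spacers) near an ORF encoding a planted
HEPN-dimer protein, then recovers both and calls the locus a Cas13-like
candidate (array within 3 kb of a dimer-bearing gene).
"""

from hepnscout.crispr import associate_arrays_to_genes, find_crispr_arrays, find_orfs
from hepnscout.hepn import detect_intramolecular_dimer
from hepnscout.synth import ArraySpec, GenomeSpec, OrfSpec, make_chimera, plant_genome

effector, _ = make_chimera(("EH", "EH"), his_distance=8.0, id="effector")
protein = "M" + effector.sequence
genome, truth = plant_genome(
    GenomeSpec(
        seed=42,
        length=8000,
        orfs=[OrfSpec(start=1000, protein=protein)],
        arrays=[ArraySpec(start=2000)],
        scrub_min_aa=50,
    )
)

arrays = find_crispr_arrays(genome)
orfs = find_orfs(genome, min_aa=50)
a = arrays[0]
print(f"array at {a.span}: {a.n_repeats} repeats of {len(a.repeat_consensus)} nt, "
      f"consensus {a.repeat_consensus[:12]}...")
print(f"spacer lengths: {[s[0][1] - s[0][0] for s in a.spacers]}")
print(f"ORF at {orfs[0].span} ({orfs[0].strand}), {orfs[0].aa_length} aa")

call = detect_intramolecular_dimer(effector)
(locus,) = associate_arrays_to_genes(arrays, orfs, {orfs[0].id: call})
print(f"array-to-gene distance: {locus.distance_bp} bp "
      f"-> cas13_candidate: {locus.cas13_candidate}")
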