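"""Link predicted TA loci to mobile genetic elements.

Plants a prophage around one locus, an insertion sequence 1 kb from
another, and a third locus on a plasmid, then computes the association
links: an MGE is TA-associated when it harbours a locus, or (for
ISs/transposons only) when the edge-to-edge gap is under 5 kb.  A plasmid
counts as an MGE for every locus it carries.
"""

from taloci.mge_association import associate, plasmid_mges
from taloci.pipeline import predict_loci
from taloci.synthetic_data import PlantedLocus, PlantedMGE, SimulationPlan, generate

plan = SimulationPlan(
    seed=23,
    replicons=[(70_000, "chromosome", "linear"), (15_000, "plasmid", "circular")],
    planted_loci=[
        PlantedLocus("II", distance=30),
        PlantedLocus("IV", distance=80),
        PlantedLocus("II", family="vapBC", distance=40, replicon=1),
    ],
    planted_mges=[
        PlantedMGE("prophage", "harbored", anchor_locus=0),
        PlantedMGE("IS_transposon", "gap", anchor_locus=1, gap_bp=1000),
    ],
)
genome, refs, mges, _ = generate(plan)
loci = predict_loci(genome, refs)
all_mges = mges + plasmid_mges(genome)  # plasmid replicons are MGEs themselves
links = associate(loci, all_mges)

print(f"{len(loci)} loci, {len(all_mges)} MGEs, {len(links)} TA-MGE links")
for link in links:
    mge = next(m for m in all_mges if m.mge_id == link.mge_id)
    print(f"  {link.locus_id:40} {mge.mge_class:13} {link.link_kind:12} gap={link.gap}")
# Each (locus, MGE) pair is its own link; a harboured locus has gap 0, a
# flanking IS reports its distance in bp (always < 5000).
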