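"""Flanking-gene synteny: conservation classes, colinearity, contiguity.

Builds small locus profiles for four species (one per lineage) sharing
five universally conserved neighbours, scores pairwise colinearity by the
longest common subsequence of shared gene names, and shows the
interrupted-locus report on a stickleback-style profile whose family
cluster is split by two interposed genes.
"""

from tprfam import (
    LocusProfile,
    colinearity_score,
    conservation_classes,
    locus_contiguity,
)

CORE = ["FAS", "ACTA2", "CH25H"]
DOWN = ["SLC16A12", "PANK1"]


def profile(species, lineage, extra_up, extra_down, focal):
    genes = [(n, "+", False) for n in CORE + extra_up]
    genes += [(f, "+", True) for f in focal]
    genes += [(n, "+", False) for n in DOWN + extra_down]
    return LocusProfile(species, lineage, "chr1", tuple(genes))


profiles = [
    profile("human", "mammal", ["MGENE1"], [], ["IFIT2", "IFIT3", "IFIT1", "IFIT5"]),
    profile("chicken", "bird_reptile", [], ["BGENE1"], ["IFITA"]),
    profile("frog", "amphibian", [], [], ["IFITX", "IFITY"]),
    profile("zebrafish", "fish", ["FGENE1"], [], ["IFIT12A", "IFIT12B"]),
]

print("conservation classes of surrounding genes:")
for c in conservation_classes(profiles):
    print(f"  {c.gene_name:10s} -> {c.class_label}")

print("\npairwise colinearity (shared, order-conserved):")
for i, a in enumerate(profiles):
    for b in profiles[i + 1 :]:
        shared, ordered = colinearity_score(a, b)
        print(f"  {a.species:9s} vs {b.species:9s}: shared={shared} ordered={ordered}")

stickleback = LocusProfile(
    "stickleback", "fish", "groupVIII",
    (
        ("UP1", "+", False),
        ("IFITA", "+", True),
        ("LOC10015032", "-", False),
        ("LOC793795", "+", False),
        ("IFITB", "+", True),
        ("PANK1", "-", False),
    ),
)
status, interrupting = locus_contiguity(stickleback)
print(f"\nstickleback-style locus: {status}, interrupted by {interrupting}")
print(
    "\nThe five red-class genes are conserved across all lineages; the "
    "interrupted locus shows a family cluster split by unrelated genes."
)
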