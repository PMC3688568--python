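"""Map ISRE elements in a promoter relative to the transcription start.

Builds a 1-kb promoter with two exact-consensus ISRE instances planted
150 bp (forward) and 600 bp (reverse) upstream of the TSS, scans both
strands, and prints each hit's distance, orientation and proximal call
(proximal = within 200 bp upstream, the family's typical arrangement).
"""

import numpy as np

from tprfam import ISRE_CONSENSUS, annotate_promoter, parse_pattern, summarize_promoters
from tprfam.promoters import PromoterRecord
from tprfam.simulate import gen_promoter_with_isre

pattern = parse_pattern(ISRE_CONSENSUS, "dna", name="ISRE")
rng = np.random.default_rng(11)
seq, tss, truth = gen_promoter_with_isre(1000, [(150, "+"), (600, "-")], rng)

promoter = PromoterRecord("IFIT_like_gene", seq, tss)
annotations = annotate_promoter(promoter, pattern)
print("hit  upstream_bp  orientation  proximal(<=200bp)")
for a in annotations:
    print(
        f"[{a.hit.start}, {a.hit.end})  {a.upstream_distance:11d}  "
        f"{a.orientation:>11s}  {str(a.proximal):>8s}"
    )

table = summarize_promoters({"IFIT_like_gene": annotations})
print("\nper-gene summary (n_isre, n_proximal, min_distance):")
print(table.to_string(index=False))
print(
    "\nThe proximal element sits where interferon-inducible promoters "
    "typically keep their ISREs; the 600-bp element is distal."
)
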