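"""Promoter annotation of ISRE hits relative to the transcription start site.

Interferon-inducible genes of this family typically carry two or more ISRE
motifs within ~200 bp upstream of the TSS, in the same orientation;
distal elements (several hundred bp upstream) occur but are the exception.
This module maps full-consensus ISRE hits onto promoter coordinates and
classifies each as proximal or distal.

Conventions: ``upstream_distance`` is measured from the motif *start* to
the TSS (``tss_index - hit.start``); positive distances are upstream of
the TSS.  A hit is proximal iff ``0 < upstream_distance <= proximal_cutoff``
(default 200 bp).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from tprfam.patterns import DegeneratePattern, MotifHit, scan_isre

__all__ = [
    "PromoterRecord",
    "IsreAnnotation",
    "annotate_promoter",
    "summarize_promoters",
]

DEFAULT_PROXIMAL_CUTOFF = 200


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter sequence with the TSS position marked.

    ``tss_index`` is the 0-based position of the transcription start within
    ``seq``; a record holding only upstream sequence has
    ``tss_index == len(seq)``.
    """

    gene_id: str
    seq: str
    tss_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.tss_index <= len(self.seq)):
            raise ValueError(
                f"tss_index {self.tss_index} outside promoter of length "
                f"{len(self.seq)} ({self.gene_id})"
            )


@dataclass(frozen=True)
class IsreAnnotation:
    """One ISRE hit placed relative to the TSS."""

    hit: MotifHit
    upstream_distance: int
    proximal: bool
    orientation: str

    @property
    def gene_id(self) -> str:
        return self.hit.seq_id


def annotate_promoter(
    promoter: PromoterRecord,
    pattern: DegeneratePattern,
    proximal_cutoff: int = DEFAULT_PROXIMAL_CUTOFF,
    strands: str = "both",
) -> list[IsreAnnotation]:
    """Scan a promoter for ISRE instances and place each relative to the TSS.

    The full supplied sequence is scanned (no implicit truncation).  Hits
    downstream of the TSS get a negative ``upstream_distance`` and are
    never proximal.  Annotations are sorted by increasing distance.
    """
    hits = scan_isre(promoter.seq, pattern, strands=strands, seq_id=promoter.gene_id)
    annotations = []
    for h in hits:
        dist = promoter.tss_index - h.start
        annotations.append(
            IsreAnnotation(
                hit=h,
                upstream_distance=dist,
                proximal=0 < dist <= proximal_cutoff,
                orientation=h.strand,
            )
        )
    return sorted(annotations, key=lambda a: (a.upstream_distance, a.orientation))


def summarize_promoters(
    annotations_by_gene: dict[str, list[IsreAnnotation]],
) -> pd.DataFrame:
    """One row per gene: hit counts, proximal counts, nearest distance,
    orientations.  Genes with zero hits appear with ``n_isre = 0`` and a
    missing ``min_distance`` (the family's promoters without a typical
    ISRE are part of the result, not dropped)."""
    rows = []
    for gene_id in sorted(annotations_by_gene):
        anns = annotations_by_gene[gene_id]
        upstream = [a.upstream_distance for a in anns if a.upstream_distance > 0]
        rows.append(
            {
                "gene_id": gene_id,
                "n_isre": len(anns),
                "n_proximal": sum(a.proximal for a in anns),
                "min_distance": min(upstream) if upstream else pd.NA,
                "orientations": ",".join(a.orientation for a in anns),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "n_isre", "n_proximal", "min_distance", "orientations"],
    )
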