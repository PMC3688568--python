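"""Exon/intron structure classification and retrogene flagging.

The canonical gene of this family has two exons: a first exon whose coding
portion is exactly 5 nt — the ATG start codon plus the first two
nucleotides of the second codon (the rest of the first exon is 5' UTR) —
and a second exon encoding the remainder of the protein.  Departures from
that plan (single-exon genes, 3-exon genes, genes with five or more exons)
are classified here, and intronless genes that additionally lack the
conserved neighbouring genes of the ancestral locus are flagged as
retrogene candidates (a retrotransposed mRNA copy lands at a new locus
without its parent's introns or neighbours; an intronless gene that still
shows locus synteny is better explained by segmental duplication).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from tprfam.synteny import LocusProfile

__all__ = [
    "GeneModel",
    "structure_class",
    "canonical_first_exon",
    "retrogene_candidate",
    "read_gene_models_gff3",
    "structure_table",
]

CANONICAL_FIRST_EXON_CODING_NT = 5  # ATG + first 2 nt of codon 2
MANY_EXON_MIN = 5

_CLASS_BY_COUNT = {1: "one_exon", 2: "two_exon", 3: "three_exon", 4: "four_exon"}


@dataclass(frozen=True)
class GeneModel:
    """Exon coordinates plus the CDS start.

    ``exons`` are 0-based half-open intervals on the forward strand,
    listed in transcription order (ascending for '+' genes, descending
    for '-' genes).  ``cds_start`` is the forward-strand coordinate of the
    base pairing with the A of the ATG (for '-' genes that is the highest
    coordinate of the CDS).
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon interval [{s}, {e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"exons of {self.gene_id} not in transcription order"
            )
        if not any(s <= self.cds_start < e for s, e in self.exons):
            raise ValueError(
                f"cds_start {self.cds_start} outside exons of {self.gene_id}"
            )

    @property
    def exon_count(self) -> int:
        return len(self.exons)


def structure_class(g: GeneModel) -> tuple[str, int]:
    """Exon/intron class label plus the raw exon count.

    Counts 1–4 map to literal labels (``one_exon`` … ``four_exon``);
    5 exons and above fall in the residual ``many_exon`` category.  The
    raw count is always returned alongside, so alternative binnings stay
    recoverable.
    """
    n = g.exon_count
    label = _CLASS_BY_COUNT.get(n, "many_exon") if n < MANY_EXON_MIN else "many_exon"
    return label, n


def canonical_first_exon(g: GeneModel) -> bool:
    """True iff exon 1's coding portion is exactly 5 nt (ATG + 2 nt).

    Requires >= 2 exons; returns False when the CDS does not start in the
    first (transcription-order) exon.
    """
    if g.exon_count < 2:
        raise ValueError(
            f"canonical_first_exon needs >= 2 exons, {g.gene_id} has {g.exon_count}"
        )
    s, e = g.exons[0]
    if not (s <= g.cds_start < e):
        return False
    if g.strand == "+":
        coding = e - g.cds_start
    else:
        coding = g.cds_start - s + 1
    return coding == CANONICAL_FIRST_EXON_CODING_NT


def retrogene_candidate(
    g: GeneModel,
    profile: LocusProfile | None,
    conserved_neighbor_names: set[str],
) -> bool:
    """Flag a retrotransposition candidate.

    True iff the gene is intronless (one exon) AND its locus shows no
    synteny with the ancestral neighbourhood — either no flanking profile
    is available or the profile shares no gene with
    ``conserved_neighbor_names``.  An intronless gene whose neighbourhood
    still carries conserved markers is not flagged.
    """
    if g.exon_count != 1:
        return False
    if profile is None:
        return True
    return not (set(profile.nonfocal_names()) & set(conserved_neighbor_names))


# ---------------------------------------------------------------------------
# I/O

def read_gene_models_gff3(path) -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon/CDS features) from a GFF3 file.

    One model per gene; the first mRNA's exons are used.  GFF3 is 1-based
    inclusive; coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        exons = [
            (f.start - 1, f.end)
            for f in db.children(parent, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start - 1, f.end)
            for f in db.children(parent, featuretype="CDS", order_by="start")
        ]
        if not exons or not cds:
            continue
        strand = gene.strand
        if strand == "+":
            exons_tx = tuple(sorted(exons))
            cds_start = min(s for s, _ in cds)
        else:
            exons_tx = tuple(sorted(exons, reverse=True))
            cds_start = max(e for _, e in cds) - 1
        models.append(
            GeneModel(
                gene_id=gene.id,
                strand=strand,
                exons=exons_tx,
                cds_start=cds_start,
            )
        )
    return models


def structure_table(
    models: Iterable[GeneModel],
    profiles: dict[str, LocusProfile] | None = None,
    conserved_neighbor_names: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene summary: exon count, class, first-exon canonicality,
    retrogene flag."""
    profiles = profiles or {}
    conserved = conserved_neighbor_names or set()
    rows = []
    for g in models:
        label, n = structure_class(g)
        rows.append(
            {
                "gene_id": g.gene_id,
                "exon_count": n,
                "class": label,
                "canonical_first_exon": (
                    canonical_first_exon(g) if n >= 2 else False
                ),
                "retrogene_candidate": retrogene_candidate(
                    g, profiles.get(g.gene_id), conserved
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "exon_count",
            "class",
            "canonical_first_exon",
            "retrogene_candidate",
        ],
    )
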