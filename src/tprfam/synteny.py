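"""Flanking-gene synteny and colinearity comparison across species.

A :class:`LocusProfile` is the ordered list of genes around a focal
family locus in one species.  Cross-species comparison asks three
questions: which surrounding genes are conserved in which lineages
(conservation classes), how well is gene *order* preserved between two
species (colinearity, scored by the longest common subsequence of shared
gene names), and is the focal family cluster itself contiguous or
interrupted by unrelated genes — as in the stickleback locus, which is
split by two interposed genes.

Duplicate gene names within one profile are disambiguated by occurrence
index before the LCS, so a name appearing twice contributes at most twice.
Orientation is ignored by the colinearity score and analysed separately
for focal genes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

__all__ = [
    "LocusProfile",
    "ConservationClass",
    "conservation_classes",
    "colinearity_score",
    "locus_contiguity",
    "orientation_uniformity",
    "read_profiles_tsv",
    "profiles_to_tsv",
]


@dataclass(frozen=True)
class LocusProfile:
    """Ordered flanking-gene list around a focal family locus.

    ``genes`` is a tuple of ``(gene_name, orientation, is_focal)`` in
    chromosomal order; at least one focal family gene must be present.
    """

    species: str
    lineage: str
    chrom: str
    genes: tuple[tuple[str, str, bool], ...]

    def __post_init__(self) -> None:
        if not any(f for _, _, f in self.genes):
            raise ValueError(
                f"profile {self.species}/{self.chrom} has no focal family gene"
            )
        for name, orient, _ in self.genes:
            if not name:
                raise ValueError("empty gene name in profile")
            if orient not in ("+", "-"):
                raise ValueError(f"bad orientation {orient!r} for {name}")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.genes)

    @property
    def focal_indices(self) -> tuple[int, ...]:
        return tuple(i for i, (_, _, f) in enumerate(self.genes) if f)

    def nonfocal_names(self) -> tuple[str, ...]:
        return tuple(name for name, _, f in self.genes if not f)


@dataclass(frozen=True)
class ConservationClass:
    """A surrounding gene and the lineages it is seen in."""

    gene_name: str
    present_in: frozenset[str]
    class_label: str


def default_class_scheme(present_in: frozenset[str], all_lineages: frozenset[str]) -> str:
    """Label a lineage-presence set: ``all_lineages`` when seen everywhere,
    ``<lineage>_only`` for a single lineage, otherwise the sorted lineage
    list joined with '+'."""
    if present_in == all_lineages:
        return "all_lineages"
    if len(present_in) == 1:
        return f"{next(iter(present_in))}_only"
    return "+".join(sorted(present_in))


def conservation_classes(
    profiles: Sequence[LocusProfile],
    scheme: Callable[[frozenset[str], frozenset[str]], str] = default_class_scheme,
) -> list[ConservationClass]:
    """Classify every non-focal surrounding gene by lineage presence.

    Each observed gene name receives exactly one class (the classes
    partition the name universe); output is ordered by gene name.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to compare conservation")
    all_lineages = frozenset(p.lineage for p in profiles)
    presence: dict[str, set[str]] = {}
    for p in profiles:
        for name in p.nonfocal_names():
            presence.setdefault(name, set()).add(p.lineage)
    return [
        ConservationClass(
            gene_name=name,
            present_in=frozenset(lineages),
            class_label=scheme(frozenset(lineages), all_lineages),
        )
        for name, lineages in sorted(presence.items())
    ]


def _disambiguated(names: Iterable[str]) -> list[tuple[str, int]]:
    seen: dict[str, int] = {}
    out = []
    for n in names:
        k = seen.get(n, 0)
        out.append((n, k))
        seen[n] = k + 1
    return out


def _lcs_length(a: Sequence, b: Sequence) -> int:
    # classic O(len(a)*len(b)) DP, single rolling row
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        curr = [0]
        for j, y in enumerate(b, start=1):
            if x == y:
                curr.append(prev[j - 1] + 1)
            else:
                curr.append(max(prev[j], curr[-1]))
        prev = curr
    return prev[-1]


def colinearity_score(a: LocusProfile, b: LocusProfile) -> tuple[int, int]:
    """Shared-gene count and order conservation between two profiles.

    Returns ``(shared_genes, ordered_shared)`` where ``shared_genes`` is
    the size of the (occurrence-disambiguated) name intersection and
    ``ordered_shared`` the longest common subsequence of the two shared
    orderings.  Symmetric; ``ordered_shared <= shared_genes``.
    """
    da = _disambiguated(a.gene_names)
    db = _disambiguated(b.gene_names)
    shared = set(da) & set(db)
    fa = [x for x in da if x in shared]
    fb = [x for x in db if x in shared]
    return len(shared), _lcs_length(fa, fb)


def locus_contiguity(p: LocusProfile) -> tuple[str, tuple[str, ...]]:
    """Is the focal family cluster one uninterrupted run?

    Returns ``("contiguous", ())`` when the focal genes form a single run,
    otherwise ``("interrupted", names)`` where ``names`` are the non-focal
    genes lying strictly between the first and last focal gene.
    """
    focal = p.focal_indices
    first, last = focal[0], focal[-1]
    interrupting = tuple(
        name
        for i, (name, _, is_focal) in enumerate(p.genes)
        if first < i < last and not is_focal
    )
    if interrupting:
        return "interrupted", interrupting
    return "contiguous", ()


def orientation_uniformity(p: LocusProfile) -> list[bool]:
    """Per contiguous focal run: do all its genes share one orientation?

    Focal genes cluster in runs (separated by non-focal genes); family
    clusters typically keep one transcriptional orientation per run.
    """
    runs: list[list[str]] = []
    current: list[str] = []
    for name, orient, is_focal in p.genes:
        if is_focal:
            current.append(orient)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    return [len(set(run)) == 1 for run in runs]


# ---------------------------------------------------------------------------
# I/O

def read_profiles_tsv(path) -> list[LocusProfile]:
    """Read LocusProfiles from a TSV with columns species, lineage, chrom,
    rank, gene_name, orientation, is_focal (one row per gene)."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (species, lineage, chrom), grp in df.groupby(
        ["species", "lineage", "chrom"], sort=True
    ):
        grp = grp.sort_values("rank")
        genes = tuple(
            (str(r.gene_name), str(r.orientation), bool(r.is_focal))
            for r in grp.itertuples()
        )
        profiles.append(
            LocusProfile(
                species=str(species), lineage=str(lineage), chrom=str(chrom), genes=genes
            )
        )
    return profiles


def profiles_to_tsv(profiles: Sequence[LocusProfile], path) -> None:
    rows = []
    for p in profiles:
        for rank, (name, orient, focal) in enumerate(p.genes):
            rows.append(
                {
                    "species": p.species,
                    "lineage": p.lineage,
                    "chrom": p.chrom,
                    "rank": rank,
                    "gene_name": name,
                    "orientation": orient,
                    "is_focal": focal,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
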