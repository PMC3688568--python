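"""Synthetic data with known ground truth for every pipeline stage.

Real analyses of this gene family run on public genome assemblies; desk
testing instead uses generated inputs whose truth is known exactly:

* proteins with planted TPR units at controlled key-site match counts
  (:func:`gen_protein_with_tpr`),
* promoters with planted ISRE instances at controlled TSS distances and
  orientations (:func:`gen_promoter_with_isre`),
* a gene-family birth–death simulation along a species tree
  (:func:`simulate_family`): genes duplicate in place (tandem, same
  orientation, occasionally translocated or retrotransposed to an
  unlinked locus), are lost, and their sequences diverge by per-site
  substitution; divergent outgroup sequences and outgroup-derived decoys
  are appended; flanking-gene orders are rearranged by adjacent
  transpositions; every family gene gets the canonical two-exon model
  except retrocopies, which are intronless.

Lineage-specific expansion is emulated by putting most duplications on
post-split branches: with the default species tree (fish, amphibian,
bird/reptile, mammal; long inter-lineage stems) each lineage's genes form
a clean monophyletic clade in the true — and, in the clean-signal regime,
the reconstructed — gene tree.

Everything is driven by ``numpy.random.default_rng``; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from tprfam.genestruct import GeneModel
from tprfam.patterns import (
    DegeneratePattern,
    ISRE_CONSENSUS,
    TPR_CONSENSUS,
    call_tpr_motifs,
    parse_pattern,
    reverse_complement,
    scan_isre,
)
from tprfam.phylo import AlignedSet
from tprfam.synteny import LocusProfile

__all__ = [
    "SimulationSpec",
    "PlantedMotif",
    "gen_protein_with_tpr",
    "gen_promoter_with_isre",
    "FamilySimulation",
    "simulate_family",
    "trivial_align",
    "DEFAULT_SPECIES_TREE",
    "DEFAULT_LINEAGES",
    "write_family_outputs",
]

AA = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"

#: Default species tree: four vertebrate lineages, two species each, with
#: long inter-lineage stems (clean phylogenetic signal) and short terminal
#: branches.  Branch lengths are expected substitutions per site.
DEFAULT_SPECIES_TREE = (
    "((fish1:0.1,fish2:0.1):0.5,"
    "((amph1:0.1,amph2:0.1):0.45,"
    "((bird1:0.1,bird2:0.1):0.35,(mam1:0.1,mam2:0.1):0.35):0.2):0.1);"
)

DEFAULT_LINEAGES = {
    "fish1": "fish",
    "fish2": "fish",
    "amph1": "amphibian",
    "amph2": "amphibian",
    "bird1": "bird_reptile",
    "bird2": "bird_reptile",
    "mam1": "mammal",
    "mam2": "mammal",
}

#: Ancestral flanking-gene names around the family locus (five of them
#: conserved in every lineage in the motivating comparison).
DEFAULT_UPSTREAM = ("FAS", "ACTA2", "CH25H", "UPG4", "UPG5", "UPG6")
DEFAULT_DOWNSTREAM = ("SLC16A12", "PANK1", "DWG3", "DWG4")


@dataclass
class SimulationSpec:
    """Parameters of the family simulation (defaults = study conditions).

    Rates are per gene per unit branch length (expected substitutions per
    site); ``substitution_rate`` scales the per-site Poisson substitution
    process, so a branch of length ``t`` substitutes each site with
    probability ``1 - exp(-substitution_rate * t)``.
    """

    seed: int = 0
    species_tree: str = DEFAULT_SPECIES_TREE
    lineages: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LINEAGES))
    duplication_rate: float = 1.5
    loss_rate: float = 0.2
    #: where birth-death events may occur: "lineage" restricts them to
    #: branches whose descendant species all belong to one lineage (pure
    #: lineage-specific expansion, the headline regime), "terminal" to
    #: terminal branches only (species-specific expansion), "all" allows
    #: pre-split duplications too
    duplication_scope: str = "lineage"
    root_length: int = 1000
    substitution_rate: float = 1.0
    outgroup_divergence: float = 1.2
    n_outgroup: int = 2
    n_decoys: int = 0
    decoy_divergence: float = 0.25
    n_flanking_upstream: tuple[str, ...] = DEFAULT_UPSTREAM
    n_flanking_downstream: tuple[str, ...] = DEFAULT_DOWNSTREAM
    flanking_retention: float = 0.8
    transposition_rate: float = 1.0
    translocation_prob: float = 0.05
    retro_prob: float = 0.03
    promoter_length: int = 1000
    isre_plants: tuple[tuple[int, str], ...] = ((150, "+"), (600, "+"))
    tpr_plants: tuple[tuple[int, int], ...] = ((10, 8), (60, 6), (110, 5))


@dataclass(frozen=True)
class PlantedMotif:
    """Ground truth for one planted motif instance."""

    start: int
    end: int
    strand: str
    key_sites_matched: int


# ---------------------------------------------------------------------------
# planted TPR proteins

def _instantiate_tpr_window(
    pattern: DegeneratePattern, n_match: int, rng: np.random.Generator
) -> str:
    """A window satisfying exactly ``n_match`` of the pattern's key sites."""
    key_idx = [i for i, el in enumerate(pattern.elements) if el.is_key]
    matched = set(rng.choice(len(key_idx), size=n_match, replace=False).tolist())
    chars: list[str] = []
    ki = 0
    for el in pattern.elements:
        if el.kind == "residue_class":
            allowed = sorted(el.allowed)
            if el.is_key:
                if ki in matched:
                    chars.append(allowed[rng.integers(len(allowed))])
                else:
                    forbidden = el.allowed
                    pool = [a for a in AA if a not in forbidden]
                    chars.append(pool[rng.integers(len(pool))])
                ki += 1
            else:
                chars.append(allowed[rng.integers(len(allowed))])
        elif el.kind == "wildcard_run":
            chars.extend(AA[i] for i in rng.integers(len(AA), size=el.length))
        else:
            raise ValueError("TPR planting needs a fixed-span pattern")
    return "".join(chars)


def gen_protein_with_tpr(
    length: int,
    plants: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    pattern: DegeneratePattern | None = None,
    threshold: int = 4,
    max_tries: int = 1000,
) -> tuple[str, list[PlantedMotif]]:
    """A random protein with TPR units planted at known positions.

    ``plants`` is a sequence of ``(position, key_sites_matched)``.  The
    background is uniform over the 20 amino acids, with whole-background
    rejection sampling guaranteeing that *no window other than a planted
    one* reaches the calling threshold — so scanner output on the result
    equals the planted truth exactly.  Planted windows must not overlap.
    """
    if pattern is None:
        pattern = parse_pattern(TPR_CONSENSUS, "protein", name="TPR")
    span = pattern.min_span
    plants = sorted(plants)
    for (p1, _), (p2, _) in zip(plants, plants[1:]):
        if p2 < p1 + span:
            raise ValueError(f"overlapping plants at {p1} and {p2}")
    if plants and (plants[0][0] < 0 or plants[-1][0] + span > length):
        raise ValueError("plant outside sequence")
    for _, k in plants:
        if not 0 <= k <= pattern.key_site_count:
            raise ValueError(f"key-site count {k} out of range")

    planted_starts = {p for p, _ in plants}
    for _ in range(max_tries):
        windows = [(p, _instantiate_tpr_window(pattern, k, rng)) for p, k in plants]
        chars = [AA[i] for i in rng.integers(len(AA), size=length)]
        for p, w in windows:
            chars[p : p + span] = w
        seq = "".join(chars)
        candidates = call_tpr_motifs(
            seq, pattern, threshold=threshold, resolve_overlaps=False
        )
        if all(c.start in planted_starts for c in candidates):
            truth = [
                PlantedMotif(p, p + span, "n/a", k) for p, k in plants
            ]
            return seq, truth
    raise RuntimeError(
        f"could not generate clean background in {max_tries} tries "
        f"(length {length}, {len(plants)} plants)"
    )


# ---------------------------------------------------------------------------
# planted ISRE promoters

def _instantiate_consensus(
    pattern: DegeneratePattern, rng: np.random.Generator
) -> str:
    chars: list[str] = []
    for el in pattern.elements:
        if el.kind == "residue_class":
            allowed = sorted(el.allowed)
            chars.append(allowed[rng.integers(len(allowed))])
        elif el.kind == "wildcard_run":
            chars.extend(DNA[i] for i in rng.integers(len(DNA), size=el.length))
        else:
            glen = int(rng.integers(el.min_len, el.max_len + 1))
            chars.extend(DNA[i] for i in rng.integers(len(DNA), size=glen))
    return "".join(chars)


def gen_promoter_with_isre(
    promoter_length: int,
    plants: Sequence[tuple[int, str]],
    rng: np.random.Generator,
    tss_index: int | None = None,
    pattern: DegeneratePattern | None = None,
    max_tries: int = 1000,
) -> tuple[str, int, list[PlantedMotif]]:
    """A random promoter with exact-consensus ISRE instances planted at
    known TSS distances.

    ``plants`` is a sequence of ``(upstream_distance, orientation)``; the
    motif start sits ``upstream_distance`` bp before the TSS.  Rejection
    sampling guarantees the scanned hit set equals the planted set (no
    accidental background consensus match on either strand).
    """
    if pattern is None:
        pattern = parse_pattern(ISRE_CONSENSUS, "dna", name="ISRE")
    tss = promoter_length if tss_index is None else tss_index
    if not 0 <= tss <= promoter_length:
        raise ValueError("tss_index outside promoter")
    placements = []
    for dist, orient in plants:
        if orient not in ("+", "-"):
            raise ValueError(f"bad orientation {orient!r}")
        start = tss - dist
        if start < 0 or start + pattern.max_span > promoter_length:
            raise ValueError(f"impossible placement at distance {dist}")
        placements.append((start, orient))
    starts = sorted(p[0] for p in placements)
    for s1, s2 in zip(starts, starts[1:]):
        if s2 < s1 + pattern.max_span:
            raise ValueError("overlapping ISRE plants")

    for _ in range(max_tries):
        chars = [DNA[i] for i in rng.integers(len(DNA), size=promoter_length)]
        truth = []
        for start, orient in placements:
            inst = _instantiate_consensus(pattern, rng)
            if orient == "-":
                inst = reverse_complement(inst)
            chars[start : start + len(inst)] = inst
            truth.append(PlantedMotif(start, start + len(inst), orient, 0))
        seq = "".join(chars)
        hits = scan_isre(seq, pattern, strands="both")
        if {(h.start, h.strand) for h in hits} == {
            (t.start, t.strand) for t in truth
        }:
            truth = [
                PlantedMotif(t.start, t.end, t.strand, pattern.key_site_count)
                for t in truth
            ]
            return seq, tss, sorted(truth, key=lambda t: t.start)
    raise RuntimeError(f"could not generate clean promoter in {max_tries} tries")


# ---------------------------------------------------------------------------
# family evolution

def _mutate(seq: str, t: float, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution: each site changes with prob 1-exp(-rate*t),
    uniformly to one of the other 19 residues."""
    if t <= 0 or rate <= 0:
        return seq
    p = 1.0 - np.exp(-rate * t)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < p
    idx = np.flatnonzero(hit)
    for i in idx:
        current = arr[i].decode()
        pool = AA.replace(current, "")
        arr[i] = pool[rng.integers(len(pool))]
    return arr.tobytes().decode()


class _GNode:
    """Mutable gene-tree node used during simulation."""

    __slots__ = ("length", "children", "name", "event")

    def __init__(self, length: float = 0.0, event: str = "") -> None:
        self.length = length
        self.children: list[_GNode] = []
        self.name: str | None = None
        self.event = event

    def newick(self) -> str:
        if not self.children:
            return f"{self.name or 'lost'}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        tag = self.event or ""
        return f"({inner}){tag}:{self.length:.6f}"


class _GeneCopy:
    """One gene copy in a genome: sequence, tree node, locus bookkeeping."""

    __slots__ = ("seq", "node", "chrom", "retro")

    def __init__(self, seq: str, node: _GNode, chrom: int, retro: bool) -> None:
        self.seq = seq
        self.node = node
        self.chrom = chrom
        self.retro = retro


@dataclass
class FamilySimulation:
    """Everything :func:`simulate_family` produced, truth included."""

    sequences: dict[str, str]
    gene_tree_newick: str
    lineage_map: dict[str, str]
    profiles: list[LocusProfile]
    gene_models: list[GeneModel]
    outgroup_labels: list[str]
    decoy_labels: list[str]
    family_labels: list[str]
    retro_labels: list[str]
    truth: dict

    def aligned(self, include: Sequence[str] | None = None) -> AlignedSet:
        """Gap-free alignment of the (equal-length) simulated proteins."""
        labels = list(include) if include is not None else sorted(self.sequences)
        return AlignedSet(
            labels=labels,
            rows=[self.sequences[l] for l in labels],
            lineage_map={l: self.lineage_map[l] for l in labels},
        )


def _evolve_genome_branch(
    genome: list[_GeneCopy],
    t: float,
    spec: SimulationSpec,
    rng: np.random.Generator,
    next_chrom: list[int],
    allow_events: bool = True,
) -> list[_GeneCopy]:
    """Birth–death + substitution along one species-tree branch.

    Duplications copy a gene in place, inserting the copy adjacent with
    the same orientation; with small probabilities the copy instead
    translocates to a fresh chromosome or retrotransposes (translocation
    plus loss of introns).  Event order and times follow a genome-level
    Poisson process, so tandem order is maintained exactly.
    """
    elapsed = 0.0
    genome = list(genome)
    while genome and allow_events:
        per_gene = spec.duplication_rate + spec.loss_rate
        total = per_gene * len(genome)
        if total <= 0:
            break
        tau = rng.exponential(1.0 / total)
        if elapsed + tau >= t:
            break
        elapsed += tau
        for g in genome:
            g.seq = _mutate(g.seq, tau, spec.substitution_rate, rng)
            g.node.length += tau
        gi = int(rng.integers(len(genome)))
        g = genome[gi]
        if rng.random() < spec.duplication_rate / per_gene:
            left, right = _GNode(event=""), _GNode(event="")
            g.node.children = [left, right]
            g.node.event = "dup"
            roll = rng.random()
            retro = roll < spec.retro_prob
            transloc = (not retro) and roll < spec.retro_prob + spec.translocation_prob
            if retro or transloc:
                chrom = next_chrom[0]
                next_chrom[0] += 1
            else:
                chrom = g.chrom
            copy = _GeneCopy(g.seq, right, chrom, retro or g.retro)
            genome[gi] = _GeneCopy(g.seq, left, g.chrom, g.retro)
            if retro or transloc:
                genome.append(copy)
            else:
                genome.insert(gi + 1, copy)
        else:
            g.node.event = "loss"
            genome.pop(gi)
    dt = t - elapsed
    for g in genome:
        g.seq = _mutate(g.seq, dt, spec.substitution_rate, rng)
        g.node.length += dt
    return genome


def _prune_gene_tree(node: _GNode) -> bool:
    """Drop extinct subtrees; splice unary nodes.  Returns survival."""
    if not node.children:
        return node.name is not None
    node.children = [c for c in node.children if _prune_gene_tree(c)]
    if not node.children:
        return False
    if len(node.children) == 1:
        child = node.children[0]
        node.length += child.length
        node.children = child.children
        node.name = child.name
        if child.event and child.event != "loss":
            node.event = child.event
    return True


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AA[i] for i in rng.integers(len(AA), size=length))


def simulate_family(spec: SimulationSpec, max_tries: int = 50) -> FamilySimulation:
    """Simulate gene-family evolution along the species tree.

    Returns sequences, the true (pruned) gene tree, lineage assignments,
    per-species locus profiles with transposition-rearranged flanking
    orders, gene models (two-exon canonical; retrocopies intronless), and
    a truth dictionary.  If the family goes extinct in any species the
    replicate is discarded and regenerated from a spawned sub-seed
    (recorded in ``truth['regenerated']``).
    """
    import dendropy

    sp_tree = dendropy.Tree.get(data=spec.species_tree, schema="newick")
    species = [lf.taxon.label for lf in sp_tree.leaf_node_iter()]
    missing = [s for s in species if s not in spec.lineages]
    if missing:
        raise ValueError(f"species without lineage tag: {missing}")

    for attempt in range(max_tries):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(attempt,))
        )
        result = _simulate_once(spec, sp_tree, species, rng)
        if result is not None:
            result.truth["regenerated"] = attempt
            return result
    raise RuntimeError(
        f"family went extinct in all {max_tries} attempts; lower loss_rate"
    )


def _simulate_once(
    spec: SimulationSpec,
    sp_tree,
    species: list[str],
    rng: np.random.Generator,
) -> FamilySimulation | None:
    root_seq = _random_protein(spec.root_length, rng)
    gene_root = _GNode()
    next_chrom = [2]  # chromosome 1 is the ancestral locus
    species_genomes: dict[str, list[_GeneCopy]] = {}

    def branch_lineages(node) -> set[str]:
        return {spec.lineages[lf.taxon.label] for lf in node.leaf_iter()}

    def descend(sp_node, incoming: list[_GeneCopy]) -> None:
        for child in sp_node.child_nodes():
            t = child.edge.length or 0.0
            if spec.duplication_scope == "all":
                allow = True
            elif spec.duplication_scope == "lineage":
                allow = len(branch_lineages(child)) == 1
            elif spec.duplication_scope == "terminal":
                allow = child.is_leaf()
            else:
                raise ValueError(
                    f"unknown duplication_scope {spec.duplication_scope!r}"
                )
            branch_in: list[_GeneCopy] = []
            for g in incoming:
                stem = _GNode()
                g.node.children.append(stem)
                branch_in.append(_GeneCopy(g.seq, stem, g.chrom, g.retro))
            genome = _evolve_genome_branch(
                branch_in, t, spec, rng, next_chrom, allow_events=allow
            )
            if child.is_leaf():
                species_genomes[child.taxon.label] = genome
            else:
                descend(child, genome)

    root_copy = _GeneCopy(root_seq, gene_root, 1, False)
    descend(sp_tree.seed_node, [root_copy])

    if any(len(g) == 0 for g in species_genomes.values()):
        return None

    sequences: dict[str, str] = {}
    lineage_map: dict[str, str] = {}
    retro_labels: list[str] = []
    family_labels: list[str] = []
    gene_locus: dict[str, tuple[str, int]] = {}  # label -> (species, chrom)
    species_orders: dict[str, dict[int, list[str]]] = {}

    for sp in species:
        genome = species_genomes[sp]
        by_chrom: dict[int, list[str]] = {}
        for i, g in enumerate(genome, start=1):
            label = f"{sp}_g{i}"
            g.node.name = label
            sequences[label] = g.seq
            lineage_map[label] = spec.lineages[sp]
            family_labels.append(label)
            if g.retro:
                retro_labels.append(label)
            gene_locus[label] = (sp, g.chrom)
            by_chrom.setdefault(g.chrom, []).append(label)
        species_orders[sp] = by_chrom

    # outgroup + decoys from a long separate branch
    og_anc = _mutate(root_seq, spec.outgroup_divergence, spec.substitution_rate, rng)
    outgroup_labels = []
    for i in range(1, spec.n_outgroup + 1):
        label = f"outgroup_{i}"
        sequences[label] = _mutate(og_anc, 0.05, spec.substitution_rate, rng)
        lineage_map[label] = "outgroup"
        outgroup_labels.append(label)
    decoy_labels = []
    for i in range(1, spec.n_decoys + 1):
        label = f"decoy_{i}"
        sequences[label] = _mutate(
            og_anc, spec.decoy_divergence, spec.substitution_rate, rng
        )
        lineage_map[label] = "outgroup"
        decoy_labels.append(label)

    _prune_gene_tree(gene_root)
    gene_tree_newick = f"({gene_root.newick()});" if gene_root.children else ";"

    # flanking-gene presence per lineage, then per-species profiles
    lineages = sorted(set(spec.lineages.values()))
    retention: dict[str, dict[str, bool]] = {}
    for name in spec.n_flanking_upstream + spec.n_flanking_downstream:
        retention[name] = {
            lin: bool(rng.random() < spec.flanking_retention) for lin in lineages
        }
    # five ancestral markers conserved everywhere
    for name in ("FAS", "ACTA2", "CH25H", "SLC16A12", "PANK1"):
        if name in retention:
            retention[name] = {lin: True for lin in lineages}

    profiles: list[LocusProfile] = []
    truth_orders: dict[str, dict] = {}
    novel_counter = [1]

    for sp in species:
        lin = spec.lineages[sp]
        for chrom, gene_labels in sorted(species_orders[sp].items()):
            retro_chrom = all(l in retro_labels for l in gene_labels)
            if chrom == 1:
                up = [n for n in spec.n_flanking_upstream if retention[n][lin]]
                down = [n for n in spec.n_flanking_downstream if retention[n][lin]]
            elif retro_chrom:
                up = [f"NOV{novel_counter[0]}", f"NOV{novel_counter[0] + 1}"]
                down = [f"NOV{novel_counter[0] + 2}"]
                novel_counter[0] += 3
            else:
                # translocated segment keeps a couple of ancestral markers
                carried = [
                    n
                    for n in spec.n_flanking_downstream
                    if retention[n][lin]
                ][:2]
                up = [f"NOV{novel_counter[0]}"]
                down = carried + [f"NOV{novel_counter[0] + 1}"]
                novel_counter[0] += 2
            genes = (
                [(n, "+" if rng.random() < 0.5 else "-", False) for n in up]
                + [(g, "+", True) for g in gene_labels]
                + [(n, "+" if rng.random() < 0.5 else "-", False) for n in down]
            )
            pre_order = [g[0] for g in genes]
            n_swaps = int(rng.poisson(spec.transposition_rate))
            applied = 0
            for _ in range(n_swaps):
                if len(genes) < 2:
                    break
                i = int(rng.integers(len(genes) - 1))
                if genes[i][2] or genes[i + 1][2]:
                    continue  # keep the focal cluster intact
                genes[i], genes[i + 1] = genes[i + 1], genes[i]
                applied += 1
            profiles.append(
                LocusProfile(
                    species=sp, lineage=lin, chrom=f"chr{chrom}", genes=tuple(genes)
                )
            )
            truth_orders[f"{sp}/chr{chrom}"] = {
                "pre": pre_order,
                "post": [g[0] for g in genes],
                "swaps_applied": applied,
            }

    # gene models: canonical two-exon unless retrocopy
    gene_models: list[GeneModel] = []
    for sp in species:
        offset = 1000
        for chrom, gene_labels in sorted(species_orders[sp].items()):
            for label in gene_labels:
                cds_len = 3 * len(sequences[label]) + 3
                if label in retro_labels:
                    exons = ((offset, offset + 200 + cds_len),)
                    cds_start = offset + 100
                else:
                    # exon 1: 5' UTR then ATG + 2 nt (coding portion 5 nt)
                    e1 = (offset, offset + 105)
                    cds_start = offset + 100
                    e2 = (offset + 605, offset + 605 + cds_len - 5 + 50)
                    exons = (e1, e2)
                gene_models.append(
                    GeneModel(
                        gene_id=label, strand="+", exons=exons, cds_start=cds_start
                    )
                )
                offset += 10_000

    truth = {
        "species_tree": spec.species_tree,
        "gene_counts": {sp: len(species_genomes[sp]) for sp in species},
        "retro_labels": sorted(retro_labels),
        "gene_locus": {k: list(v) for k, v in gene_locus.items()},
        "flanking_retention": {
            name: retention[name] for name in sorted(retention)
        },
        "orders": truth_orders,
    }
    return FamilySimulation(
        sequences=sequences,
        gene_tree_newick=gene_tree_newick,
        lineage_map=lineage_map,
        profiles=profiles,
        gene_models=gene_models,
        outgroup_labels=outgroup_labels,
        decoy_labels=decoy_labels,
        family_labels=sorted(family_labels),
        retro_labels=sorted(retro_labels),
        truth=truth,
    )


def trivial_align(sequences: dict[str, str], lineage_map=None) -> AlignedSet:
    """Gap-free 'alignment' of equal-length sequences (the simulator emits
    no indels, so columns already correspond)."""
    labels = sorted(sequences)
    return AlignedSet(
        labels=labels,
        rows=[sequences[l] for l in labels],
        lineage_map=lineage_map,
    )


# ---------------------------------------------------------------------------
# file emission

def write_family_outputs(sim: FamilySimulation, outdir) -> dict[str, Path]:
    """Write FASTA / Newick / lineage TSV / profiles TSV / GFF3 / truth JSON."""
    from tprfam.synteny import profiles_to_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    fasta = outdir / "family.fasta"
    with open(fasta, "w") as fh:
        for label in sorted(sim.sequences):
            fh.write(f">{label}\n{sim.sequences[label]}\n")
    paths["fasta"] = fasta

    newick = outdir / "gene_tree.nwk"
    newick.write_text(sim.gene_tree_newick + "\n")
    paths["newick"] = newick

    lineage = outdir / "lineages.tsv"
    with open(lineage, "w") as fh:
        fh.write("label\tlineage\n")
        for label in sorted(sim.lineage_map):
            fh.write(f"{label}\t{sim.lineage_map[label]}\n")
    paths["lineages"] = lineage

    prof = outdir / "profiles.tsv"
    profiles_to_tsv(sim.profiles, prof)
    paths["profiles"] = prof

    gff = outdir / "models.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sim.gene_models:
            lo = min(s for s, _ in g.exons) + 1
            hi = max(e for _, e in g.exons)
            fh.write(
                f"chr1\tsim\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"chr1\tsim\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), start=1):
                fh.write(
                    f"chr1\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}.t1\n"
                )
            if g.strand == "+":
                cds_lo, cds_hi = g.cds_start + 1, max(e for _, e in g.exons)
            else:
                cds_lo, cds_hi = min(s for s, _ in g.exons) + 1, g.cds_start + 1
            fh.write(
                f"chr1\tsim\tCDS\t{cds_lo}\t{cds_hi}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
            )
    paths["gff3"] = gff

    truth = outdir / "truth.json"
    truth.write_text(json.dumps(sim.truth, indent=1, sort_keys=True))
    paths["truth"] = truth
    return paths
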