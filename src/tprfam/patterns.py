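"""Degenerate consensus patterns and motif scanning.

A consensus pattern is an ordered mixture of three element kinds:

``residue_class``
    a constrained position with an allowed-symbol set.  Bracketed classes
    (``[WLF]`` or ``(G/A/T)``) are *key sites* — the positions the calling
    rule counts.  Bare letters are single-symbol constrained positions that
    are checked but not counted as key sites.
``wildcard_run``
    a fixed-length unconstrained stretch: ``X(8)`` in protein patterns,
    ``N(3)`` in DNA patterns.
``variable_gap``
    an unconstrained stretch of variable length, ``N(1-2)``.

Two scanning modes are provided.  Protein TPR units are called with a
key-site threshold: a window is a candidate when *more than* ``threshold``
of the key sites match (strictly greater, so the default threshold of 4
requires >= 5 of the 8 TPR key sites).  DNA elements such as the ISRE are
called on a full-consensus match: every constrained position must match for
some choice of gap lengths.

Coordinates are 0-based, half-open, on the forward strand throughout.
Ambiguity handling is deliberately strict: ``N`` in a DNA sequence and
``X`` in a protein sequence never satisfy a constrained position.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

__all__ = [
    "TPR_CONSENSUS",
    "ISRE_CONSENSUS",
    "PROTEIN_ALPHABET",
    "DNA_ALPHABET",
    "MotifPatternError",
    "PatternElement",
    "DegeneratePattern",
    "MotifHit",
    "WindowEval",
    "parse_pattern",
    "match_at",
    "call_tpr_motifs",
    "scan_isre",
    "brute_force_scan",
    "reverse_complement",
    "hits_to_bed",
]

#: The 34-aa TPR repeat unit's degenerate consensus.  The eight bracketed
#: classes are the key sites used by the calling rule; the fixed wildcard
#: runs bring the scanned span to 29 aa (the consensus does not constrain
#: the C-terminal tail of the repeat unit).
TPR_CONSENSUS = "[WLF]-X(2)-[LIM]-[GAS]-X(2)-[YLF]-X(8)-[ASE]-X(3)-[FYL]-X(2)-[ASL]-X(4)-[PKE]"

#: The interferon-stimulated response element consensus.  The two GAAA
#: cores are literal (non-key) constrained positions; the flanking
#: degenerate classes are bracketed, and the spacer may be 1 or 2 nt.
ISRE_CONSENSUS = "(G/A/T)GAAAN(1-2)GAAA(G/C)(A/T/C)"

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Alphabet = Literal["protein", "dna"]


class MotifPatternError(ValueError):
    """Raised for malformed consensus strings or alphabet violations."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case-insensitive)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PatternElement:
    """One element of a degenerate consensus pattern."""

    kind: Literal["residue_class", "wildcard_run", "variable_gap"]
    allowed: frozenset[str] = frozenset()
    length: int = 1
    min_len: int = 1
    max_len: int = 1
    is_key: bool = False

    def __post_init__(self) -> None:
        if self.kind == "residue_class":
            if not self.allowed:
                raise MotifPatternError("residue_class with empty allowed set")
        elif self.kind == "wildcard_run":
            if self.length < 1:
                raise MotifPatternError("wildcard_run length must be >= 1")
            if self.is_key:
                raise MotifPatternError("only residue_class elements can be key sites")
        elif self.kind == "variable_gap":
            if not (1 <= self.min_len <= self.max_len):
                raise MotifPatternError(
                    f"variable_gap needs 1 <= min_len <= max_len, got "
                    f"({self.min_len}, {self.max_len})"
                )
            if self.is_key:
                raise MotifPatternError("only residue_class elements can be key sites")
        else:  # pragma: no cover - dataclass guards the literal
            raise MotifPatternError(f"unknown element kind {self.kind!r}")

    @property
    def span_range(self) -> tuple[int, int]:
        if self.kind == "residue_class":
            return (1, 1)
        if self.kind == "wildcard_run":
            return (self.length, self.length)
        return (self.min_len, self.max_len)


@dataclass(frozen=True)
class DegeneratePattern:
    """A parsed degenerate consensus: ordered elements plus alphabet."""

    elements: tuple[PatternElement, ...]
    alphabet: Alphabet
    name: str = "pattern"

    def __post_init__(self) -> None:
        if not self.elements:
            raise MotifPatternError("empty pattern")
        symbols = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        for el in self.elements:
            if el.kind == "residue_class" and not el.allowed <= symbols:
                bad = "".join(sorted(el.allowed - symbols))
                raise MotifPatternError(
                    f"symbols {bad!r} not in {self.alphabet} alphabet"
                )

    @property
    def key_site_count(self) -> int:
        return sum(1 for el in self.elements if el.is_key)

    @property
    def nonkey_site_count(self) -> int:
        return sum(
            1 for el in self.elements if el.kind == "residue_class" and not el.is_key
        )

    @property
    def min_span(self) -> int:
        return sum(el.span_range[0] for el in self.elements)

    @property
    def max_span(self) -> int:
        return sum(el.span_range[1] for el in self.elements)

    @property
    def variable_gaps(self) -> tuple[PatternElement, ...]:
        return tuple(el for el in self.elements if el.kind == "variable_gap")

    @property
    def fixed_span(self) -> bool:
        return self.min_span == self.max_span

    def gap_choices(self) -> Iterator[tuple[int, ...]]:
        """Every assignment of lengths to the variable gaps, in order."""
        ranges = [
            range(el.min_len, el.max_len + 1)
            for el in self.elements
            if el.kind == "variable_gap"
        ]
        return itertools.product(*ranges)


@dataclass(frozen=True, order=True)
class MotifHit:
    """A scanner call on one sequence.

    ``start``/``end`` are 0-based half-open forward-strand coordinates,
    ``strand`` is ``'+'``/``'-'`` for DNA scans and ``'n/a'`` for protein
    scans.  ``consensus_matched`` counts matching non-key constrained
    positions (reported, never filtered on).
    """

    seq_id: str
    start: int
    end: int
    strand: str
    key_sites_matched: int
    consensus_matched: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad hit interval [{self.start}, {self.end})")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowEval:
    """Result of evaluating a pattern window at one position."""

    key_matched: int
    key_total: int
    nonkey_matched: int
    nonkey_total: int
    span: int

    @property
    def full_match(self) -> bool:
        return (
            self.key_matched == self.key_total
            and self.nonkey_matched == self.nonkey_total
        )


# ---------------------------------------------------------------------------
# parsing

_TOKEN_RE = re.compile(
    r"""
    \[(?P<brack>[A-Z]+)\]                       # [WLF]
  | \((?P<slash>[A-Z](?:/[A-Z])+)\)             # (G/A/T)
  | (?P<wild>[XN])\((?P<lo>\d+)(?:-(?P<hi>\d+))?\)   # X(2), N(3), N(1-2)
  | (?P<single>[A-Z])                           # bare letter
    """,
    re.VERBOSE,
)


def parse_pattern(
    text: str, alphabet: Alphabet, name: str | None = None
) -> DegeneratePattern:
    """Parse a degenerate consensus string.

    Dialect: bracketed classes ``[ABC]`` or ``(A/B/C)`` (marked as key
    sites), fixed wildcards ``X(n)`` (protein) / ``N(n)`` (DNA), variable
    gaps ``N(a-b)`` (DNA), bare letters as literal non-key positions,
    optional ``-`` separators, case-insensitive.

    Note that in protein patterns ``N`` is the literal asparagine and only
    ``X`` is a wildcard; in DNA patterns ``N`` is the wildcard/gap symbol.

    Raises :class:`MotifPatternError` naming the offending token on
    malformed input, symbols outside the alphabet, or an empty pattern.
    """
    if alphabet not in ("protein", "dna"):
        raise MotifPatternError(f"unknown alphabet {alphabet!r}")
    # strip separator dashes, but not the '-' inside N(a-b)
    cleaned = text.upper().replace(" ", "")
    cleaned = re.sub(r"(?<!\d)-|-(?!\d)", "", cleaned)
    if not cleaned:
        raise MotifPatternError("empty pattern")

    wildcard_symbol = "X" if alphabet == "protein" else "N"
    elements: list[PatternElement] = []
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN_RE.match(cleaned, pos)
        if m is None:
            raise MotifPatternError(
                f"malformed pattern near {cleaned[pos:pos + 8]!r} (offset {pos})"
            )
        if m.group("brack") or m.group("slash"):
            symbols = m.group("brack") or m.group("slash").replace("/", "")
            elements.append(
                PatternElement(
                    kind="residue_class", allowed=frozenset(symbols), is_key=True
                )
            )
        elif m.group("wild"):
            sym = m.group("wild")
            if sym != wildcard_symbol:
                if sym in (PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET):
                    raise MotifPatternError(
                        f"{sym}(n) is not a wildcard in the {alphabet} alphabet"
                    )
                raise MotifPatternError(f"unexpected wildcard symbol {sym!r}")
            lo = int(m.group("lo"))
            hi = m.group("hi")
            if hi is None:
                elements.append(PatternElement(kind="wildcard_run", length=lo))
            else:
                elements.append(
                    PatternElement(kind="variable_gap", min_len=lo, max_len=int(hi))
                )
        else:
            sym = m.group("single")
            if sym == wildcard_symbol:
                elements.append(PatternElement(kind="wildcard_run", length=1))
            else:
                elements.append(
                    PatternElement(kind="residue_class", allowed=frozenset(sym))
                )
        pos = m.end()

    if name is None:
        name = "tpr" if alphabet == "protein" else "motif"
    return DegeneratePattern(tuple(elements), alphabet, name)


# ---------------------------------------------------------------------------
# window evaluation

def _validate_sequence(seq: str, alphabet: Alphabet) -> str:
    seq = seq.upper()
    if alphabet == "dna":
        bad = set(seq) - (DNA_ALPHABET | {"N"})
        if bad:
            raise ValueError(
                f"non-nucleotide symbols {''.join(sorted(bad))!r} in DNA sequence"
            )
    else:
        bad = set(seq) - (PROTEIN_ALPHABET | {"X"})
        if bad:
            raise ValueError(
                f"non-amino-acid symbols {''.join(sorted(bad))!r} in protein sequence"
            )
    return seq


def match_at(
    seq: str,
    pattern: DegeneratePattern,
    pos: int,
    gap_choice: Sequence[int] = (),
) -> WindowEval:
    """Evaluate ``pattern`` against the window of ``seq`` starting at ``pos``.

    ``gap_choice`` assigns one length per variable gap, in pattern order.
    Key-site and non-key constrained positions are counted separately.
    Raises ``IndexError`` when the window would run past the sequence end
    and ``ValueError`` on a bad gap assignment.
    """
    gaps = list(gap_choice)
    n_gaps = len(pattern.variable_gaps)
    if len(gaps) != n_gaps:
        raise ValueError(f"expected {n_gaps} gap lengths, got {len(gaps)}")
    span = 0
    gi = 0
    for el in pattern.elements:
        if el.kind == "variable_gap":
            if not (el.min_len <= gaps[gi] <= el.max_len):
                raise ValueError(
                    f"gap length {gaps[gi]} outside [{el.min_len}, {el.max_len}]"
                )
            span += gaps[gi]
            gi += 1
        else:
            span += el.span_range[0]
    if pos < 0 or pos + span > len(seq):
        raise IndexError(
            f"window [{pos}, {pos + span}) outside sequence of length {len(seq)}"
        )

    key_matched = nonkey_matched = 0
    offset = pos
    gi = 0
    for el in pattern.elements:
        if el.kind == "residue_class":
            if seq[offset] in el.allowed:
                if el.is_key:
                    key_matched += 1
                else:
                    nonkey_matched += 1
            offset += 1
        elif el.kind == "wildcard_run":
            offset += el.length
        else:
            offset += gaps[gi]
            gi += 1
    return WindowEval(
        key_matched=key_matched,
        key_total=pattern.key_site_count,
        nonkey_matched=nonkey_matched,
        nonkey_total=pattern.nonkey_site_count,
        span=span,
    )


# ---------------------------------------------------------------------------
# protein TPR calling

def _resolve_overlaps(candidates: list[MotifHit]) -> list[MotifHit]:
    """Greedy overlap resolution: repeatedly keep the candidate with the
    highest key-site count (ties to the leftmost start) and drop everything
    overlapping it.  TPR units are tandem, non-overlapping repeats, so at
    most one call survives per repeat-unit footprint."""
    remaining = sorted(candidates, key=lambda h: (-h.key_sites_matched, h.start))
    kept: list[MotifHit] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            h for h in remaining if h.end <= best.start or h.start >= best.end
        ]
    return sorted(kept, key=lambda h: h.start)


def call_tpr_motifs(
    seq: str,
    pattern: DegeneratePattern,
    threshold: int = 4,
    seq_id: str = "seq",
    secondary_threshold: int | None = None,
    resolve_overlaps: bool = True,
) -> list[MotifHit]:
    """Call TPR-like repeat units in a protein sequence.

    A window is a candidate iff strictly more than ``threshold`` key sites
    match (>= 5 of 8 under the default).  ``secondary_threshold``, off by
    default, additionally requires strictly more than that many non-key
    constrained positions to match; the consensus used here has no non-key
    positions, so the knob only matters for patterns that do.

    Overlapping candidates are resolved greedily (highest key-site count,
    ties to the leftmost start); hits are returned sorted by start.
    """
    if pattern.alphabet != "protein":
        raise MotifPatternError(
            f"call_tpr_motifs needs a protein pattern, got {pattern.alphabet}"
        )
    if not pattern.fixed_span:
        raise MotifPatternError("key-site threshold calling needs a fixed-span pattern")
    if threshold >= pattern.key_site_count:
        raise ValueError(
            f"threshold {threshold} must be < key-site count {pattern.key_site_count}"
        )
    seq = _validate_sequence(seq, "protein")
    span = pattern.min_span
    candidates: list[MotifHit] = []
    for pos in range(0, len(seq) - span + 1):
        ev = match_at(seq, pattern, pos)
        if ev.key_matched <= threshold:
            continue
        if secondary_threshold is not None and ev.nonkey_matched <= secondary_threshold:
            continue
        candidates.append(
            MotifHit(
                seq_id=seq_id,
                start=pos,
                end=pos + span,
                strand="n/a",
                key_sites_matched=ev.key_matched,
                consensus_matched=ev.nonkey_matched,
            )
        )
    return _resolve_overlaps(candidates) if resolve_overlaps else candidates


# ---------------------------------------------------------------------------
# DNA full-consensus scanning

def _full_matches_forward(
    seq: str, pattern: DegeneratePattern, seq_id: str, strand: str
) -> list[MotifHit]:
    """All full-consensus matches on the given string; at each start only
    the shortest matching span is kept."""
    hits: list[MotifHit] = []
    gap_choices = sorted(pattern.gap_choices(), key=sum)
    for pos in range(len(seq)):
        for gaps in gap_choices:
            span = pattern.min_span + sum(gaps) - sum(
                g.min_len for g in pattern.variable_gaps
            )
            if pos + span > len(seq):
                continue
            ev = match_at(seq, pattern, pos, gaps)
            if ev.full_match:
                hits.append(
                    MotifHit(
                        seq_id=seq_id,
                        start=pos,
                        end=pos + ev.span,
                        strand=strand,
                        key_sites_matched=ev.key_matched,
                        consensus_matched=ev.nonkey_matched,
                    )
                )
                break  # shortest span at this start wins
    return hits


def scan_isre(
    seq: str,
    pattern: DegeneratePattern,
    strands: Literal["forward", "both"] = "both",
    seq_id: str = "seq",
) -> list[MotifHit]:
    """Scan DNA for full-consensus matches of an ISRE-style pattern.

    A hit requires every constrained position to match for some gap-length
    choice; at a given start, overlapping gap choices collapse to the
    shortest span.  With ``strands='both'`` the reverse strand is scanned
    via the reverse complement and reported in forward-strand coordinates
    with ``strand='-'``.  ``N`` in the sequence never matches a constrained
    position.
    """
    if pattern.alphabet != "dna":
        raise MotifPatternError(
            f"scan_isre needs a dna pattern, got {pattern.alphabet}"
        )
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    seq = _validate_sequence(seq, "dna")
    hits = _full_matches_forward(seq, pattern, seq_id, "+")
    if strands == "both":
        rc = reverse_complement(seq)
        for h in _full_matches_forward(rc, pattern, seq_id, "-"):
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    start=len(seq) - h.end,
                    end=len(seq) - h.start,
                    strand="-",
                    key_sites_matched=h.key_sites_matched,
                    consensus_matched=h.consensus_matched,
                )
            )
    return sorted(hits, key=lambda h: (h.start, h.end, h.strand))


# ---------------------------------------------------------------------------
# brute-force oracle

def brute_force_scan(
    seq: str,
    pattern: DegeneratePattern,
    threshold: int = 4,
    strands: Literal["forward", "both"] = "both",
    seq_id: str = "seq",
) -> list[MotifHit]:
    """Exhaustive reference scanner: every position x every gap assignment,
    evaluated symbol by symbol with no shortcuts.  Semantics mirror
    :func:`call_tpr_motifs` (protein patterns) / :func:`scan_isre` (DNA
    patterns); intended as the independent oracle in tests.
    """
    seq = _validate_sequence(seq, pattern.alphabet)

    def windows(s: str) -> Iterator[tuple[int, int, int, int, bool]]:
        # (start, end, key_matched, nonkey_matched, full) for every
        # position x gap assignment, shortest gap sums first.
        for pos in range(len(s) + 1):
            for gaps in sorted(pattern.gap_choices(), key=sum):
                cursor = pos
                key = nonkey = 0
                key_total = nonkey_total = 0
                ok = True
                gi = 0
                for el in pattern.elements:
                    if el.kind == "residue_class":
                        key_total += el.is_key
                        nonkey_total += not el.is_key
                        if cursor >= len(s):
                            ok = False
                            break
                        hit = False
                        for sym in el.allowed:
                            if s[cursor] == sym:
                                hit = True
                        if hit:
                            if el.is_key:
                                key += 1
                            else:
                                nonkey += 1
                        cursor += 1
                    elif el.kind == "wildcard_run":
                        cursor += el.length
                    else:
                        cursor += gaps[gi]
                        gi += 1
                if not ok or cursor > len(s):
                    continue
                full = key == key_total and nonkey == nonkey_total
                yield pos, cursor, key, nonkey, full

    if pattern.alphabet == "protein":
        candidates = [
            MotifHit(seq_id, start, end, "n/a", key, nonkey)
            for start, end, key, nonkey, _ in windows(seq)
            if key > threshold
        ]
        # same greedy selection, re-derived naively
        chosen: list[MotifHit] = []
        pool = list(candidates)
        while pool:
            best = pool[0]
            for h in pool[1:]:
                if h.key_sites_matched > best.key_sites_matched or (
                    h.key_sites_matched == best.key_sites_matched
                    and h.start < best.start
                ):
                    best = h
            chosen.append(best)
            pool = [h for h in pool if h.end <= best.start or h.start >= best.end]
        return sorted(chosen, key=lambda h: h.start)

    hits: list[MotifHit] = []
    seen_starts: set[tuple[int, str]] = set()
    for start, end, key, nonkey, full in windows(seq):
        if full and (start, "+") not in seen_starts:
            hits.append(MotifHit(seq_id, start, end, "+", key, nonkey))
            seen_starts.add((start, "+"))
    if strands == "both":
        rc = reverse_complement(seq)
        seen_rc: set[int] = set()
        for start, end, key, nonkey, full in windows(rc):
            if full and start not in seen_rc:
                hits.append(
                    MotifHit(seq_id, len(seq) - end, len(seq) - start, "-", key, nonkey)
                )
                seen_rc.add(start)
    return sorted(hits, key=lambda h: (h.start, h.end, h.strand))


# ---------------------------------------------------------------------------
# output helpers

def hits_to_bed(hits: Iterable[MotifHit], pattern_name: str) -> str:
    """Render hits as BED6 text (name = pattern name, score = key sites)."""
    lines = []
    for h in hits:
        strand = h.strand if h.strand in ("+", "-") else "."
        lines.append(
            f"{h.seq_id}\t{h.start}\t{h.end}\t{pattern_name}\t"
            f"{h.key_sites_matched}\t{strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
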