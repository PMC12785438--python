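"""Bioactive-peptide candidate identification by reduced-alphabet homology.

A detected peptide is called a bioactive candidate when it reaches at least
80% sequence homology to a catalogued bioactive peptide, counting
conservative substitutions as matches. Homology is scored as the longest
common subsequence (LCS) of the two sequences under a residue-equivalence
relation, normalised by the longer sequence's length:

    homology_pct = 100 * LCS_equiv(query, reference) / max(|query|, |reference|)

The LCS is order-preserving and gap-tolerant, the score is symmetric, and it
equals 100 exactly when the two sequences have equal length and are
positionwise equivalent. The default equivalence classes are the three
physicochemical groups {V, I, L}, {D, E} and {R, K}; the threshold is
inclusive (a score of exactly 80.0 passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import AMINO_ACIDS, BioactiveEntry, validate_sequence

#: Inclusive percent-homology cutoff for calling a bioactive candidate.
DEFAULT_THRESHOLD = 80.0


@dataclass(frozen=True)
class SubstitutionGroups:
    """Disjoint residue sets whose members count as equivalent matches."""

    groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.groups:
            if not group <= AMINO_ACIDS:
                raise ValueError(f"non-standard residues in group {sorted(group)}")
            if group & seen:
                raise ValueError("substitution groups must be pairwise disjoint")
            seen |= group

    @classmethod
    def from_strings(cls, specs: Iterable[str]) -> "SubstitutionGroups":
        """Parse groups from strings like ``["VIL", "DE", "RK"]``."""
        return cls(tuple(frozenset(s.upper()) for s in specs if s))

    def class_map(self) -> dict[str, int]:
        """Residue -> equivalence-class id (singletons for ungrouped residues)."""
        mapping: dict[str, int] = {}
        for idx, group in enumerate(self.groups):
            for residue in group:
                mapping[residue] = idx
        next_id = len(self.groups)
        for residue in sorted(AMINO_ACIDS - set(mapping)):
            mapping[residue] = next_id
            next_id += 1
        return mapping


#: {V,I,L}, {D,E}, {R,K} — the conservative substitutions used for matching.
DEFAULT_GROUPS = SubstitutionGroups.from_strings(["VIL", "DE", "RK"])
#: No equivalence classes: homology reduces to plain-identity LCS similarity.
IDENTITY_GROUPS = SubstitutionGroups(())


@dataclass
class MatchResult:
    """One query <-> reference pairing with its homology score."""

    query: str
    reference: BioactiveEntry
    matched_positions: int
    homology_pct: float
    passed: bool


def residues_equivalent(x: str, y: str, groups: SubstitutionGroups = DEFAULT_GROUPS) -> bool:
    """True iff x == y or both residues share a substitution group."""
    if x not in AMINO_ACIDS or y not in AMINO_ACIDS:
        raise ValueError(f"non-standard residue in ({x!r}, {y!r})")
    if x == y:
        return True
    return any(x in g and y in g for g in groups.groups)


def _encode(sequence: str, class_map: Mapping[str, int], collapse_il: bool) -> list[int]:
    if collapse_il:
        sequence = sequence.replace("I", "L")
    return [class_map[r] for r in sequence]


def homology(
    query: str,
    reference: str,
    groups: SubstitutionGroups = DEFAULT_GROUPS,
    collapse_il: bool = False,
) -> tuple[int, float]:
    """Equivalence-class LCS homology between two peptide sequences.

    Returns ``(matched_positions, homology_pct)``. ``collapse_il``
    additionally treats I and L as identical before grouping (for search
    workflows where the two are indistinguishable by mass); it is
    independent of, and by default subsumed by, the {V, I, L} group.
    """
    query = validate_sequence(query, "homology query")
    reference = validate_sequence(reference, "homology reference")
    class_map = groups.class_map()
    a = _encode(query, class_map, collapse_il)
    b = _encode(reference, class_map, collapse_il)
    # Classic O(len(a)*len(b)) LCS dynamic programme over class ids.
    prev = [0] * (len(b) + 1)
    for ai in a:
        curr = [0] * (len(b) + 1)
        for j, bj in enumerate(b, start=1):
            if ai == bj:
                curr[j] = prev[j - 1] + 1
            else:
                curr[j] = max(prev[j], curr[j - 1])
        prev = curr
    matched = prev[len(b)]
    pct = 100.0 * matched / max(len(a), len(b))
    return matched, pct


def search(
    query: str,
    db: Sequence[BioactiveEntry],
    threshold: float = DEFAULT_THRESHOLD,
    groups: SubstitutionGroups = DEFAULT_GROUPS,
    collapse_il: bool = False,
) -> list[MatchResult]:
    """Score ``query`` against every database entry.

    Results are sorted by homology_pct descending, ties broken by smaller
    absolute length difference, then database order, so output is
    deterministic. A query "has bioactive potential" iff >= 1 result passed.
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError("threshold must be in (0, 100]")
    scored: list[tuple[float, int, int, MatchResult]] = []
    for idx, entry in enumerate(db):
        matched, pct = homology(query, entry.sequence, groups, collapse_il)
        result = MatchResult(
            query=query,
            reference=entry,
            matched_positions=matched,
            homology_pct=pct,
            passed=pct >= threshold,
        )
        scored.append((-pct, abs(len(query) - len(entry.sequence)), idx, result))
    scored.sort(key=lambda item: item[:3])
    return [item[3] for item in scored]


def best_hit(
    query: str,
    db: Sequence[BioactiveEntry],
    threshold: float = DEFAULT_THRESHOLD,
    groups: SubstitutionGroups = DEFAULT_GROUPS,
    collapse_il: bool = False,
) -> MatchResult | None:
    hits = search(query, db, threshold, groups, collapse_il)
    return hits[0] if hits else None


@dataclass
class PeptideAnnotation:
    """Bioactivity annotation of one differential peptide."""

    sequence: str
    status: str
    hits: list[MatchResult] = field(default_factory=list)
    functions: list[str] = field(default_factory=list)
    best_parent: str | None = None

    @property
    def is_candidate(self) -> bool:
        return bool(self.hits)


def annotate_differential(
    results: Sequence,
    db: Sequence[BioactiveEntry],
    threshold: float = DEFAULT_THRESHOLD,
    groups: SubstitutionGroups = DEFAULT_GROUPS,
    collapse_il: bool = False,
) -> tuple[list[PeptideAnnotation], dict[str, object]]:
    """Annotate up/down differential peptides with database hits.

    ``results`` may be :class:`~lactopept.differential.DifferentialResult`
    objects or any objects exposing ``sequence`` and ``status``. Each
    significantly changed peptide gains its passed-hit list, the union of hit
    functions (sorted), and the parent attribution of its best hit. Returns
    the annotations plus a summary with candidate counts and function unions
    per direction.
    """
    annotations: list[PeptideAnnotation] = []
    for res in results:
        status = getattr(res, "status")
        if status not in ("up", "down"):
            continue
        sequence = getattr(res, "sequence")
        passed = [
            h for h in search(sequence, db, threshold, groups, collapse_il) if h.passed
        ]
        functions = sorted({f for h in passed for f in h.reference.functions})
        annotations.append(
            PeptideAnnotation(
                sequence=sequence,
                status=status,
                hits=passed,
                functions=functions,
                best_parent=passed[0].reference.parent if passed else None,
            )
        )

    def _side(direction: str) -> list[PeptideAnnotation]:
        return [a for a in annotations if a.status == direction and a.is_candidate]

    up, down = _side("up"), _side("down")
    summary: dict[str, object] = {
        "n_up_bioactive": len(up),
        "n_down_bioactive": len(down),
        "functions_up": sorted({f for a in up for f in a.functions}),
        "functions_down": sorted({f for a in down for f in a.functions}),
        "parents_up": {a.sequence: a.best_parent for a in up},
        "parents_down": {a.sequence: a.best_parent for a in down},
    }
    return annotations, summary
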