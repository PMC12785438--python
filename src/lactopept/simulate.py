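"""Synthetic intestinal-digesta peptidome generator.

Produces two-group peptide abundance tables with the statistical structure
the analysis modules assume, standing in for raw mass-spectrometry data that
cannot be redistributed. The generator chains:

1. deterministic in-silico proteolysis of a protein mixture (rule-based cut
   sites, missed-cleavage enumeration, length window) — emulating the joint
   action of gastric pepsin and pancreatic trypsin/chymotrypsin;
2. log-normal base abundances scaled by each protein's mixture weight;
3. a group effect multiplying a chosen fraction of target-parent peptides by
   2**delta in group B (the fortified group);
4. multiplicative replicate noise (normal, coefficient of variation ``cv``,
   truncated at zero) and detection dropout for low-abundance peptides.

All randomness flows from the single integer seed of the
:class:`DigestSpec` through one named generator; runs are bit-reproducible.
The study-like presets mirror a 40:60 casein:whey gavage mix in which
beta-casein is either 43.0% (ordinary) or 63.4% (fortified) of the casein
fraction, three replicates per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import AMINO_ACIDS, ParentProtein, PeptideRecord, PeptideTable, load_parent_proteins


@dataclass(frozen=True)
class CleavageRule:
    """Protease specificity: cut after ``cut_after`` unless the next residue blocks."""

    name: str
    cut_after: frozenset[str]
    blocked_by_next: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cut_after:
            raise ValueError(f"{self.name}: empty cut_after set")
        if not (self.cut_after | self.blocked_by_next) <= AMINO_ACIDS:
            raise ValueError(f"{self.name}: non-standard residues in rule")


PEPSIN = CleavageRule("pepsin", frozenset("FLWY"))
TRYPSIN = CleavageRule("trypsin", frozenset("KR"), frozenset("P"))
CHYMOTRYPSIN = CleavageRule("chymotrypsin", frozenset("FWY"), frozenset("P"))
#: Joint gastric + pancreatic rule set used by the study-like presets.
DEFAULT_RULES = (PEPSIN, TRYPSIN, CHYMOTRYPSIN)


def cut_sites(sequence: str, rules: Sequence[CleavageRule]) -> list[int]:
    """Positions i (1-based, 1 <= i < len) where some rule cuts after residue i."""
    sites: set[int] = set()
    for i in range(1, len(sequence)):
        residue, following = sequence[i - 1], sequence[i]
        for rule in rules:
            if residue in rule.cut_after and following not in rule.blocked_by_next:
                sites.add(i)
                break
    return sorted(sites)


@dataclass(frozen=True)
class Fragment:
    """One digestion fragment with its parent coordinates (1-based inclusive)."""

    sequence: str
    parent_id: str
    start: int
    end: int
    missed_cleavages: int


def digest(
    protein: ParentProtein,
    rules: Sequence[CleavageRule] = DEFAULT_RULES,
    max_missed_cleavages: int = 0,
    length_window: tuple[int, int] | None = None,
) -> list[Fragment]:
    """Enumerate digestion fragments, deterministically.

    Cut sites are the union over all rules; fragments span consecutive sites
    with up to ``max_missed_cleavages`` internal sites, then the length
    window ``[min, max]`` (inclusive) is applied. With no cut sites the whole
    protein is the single fragment.
    """
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    if length_window is not None and length_window[0] < 1:
        raise ValueError("length_window minimum must be >= 1")
    sites = cut_sites(protein.sequence, rules)
    bounds = [0, *sites, len(protein.sequence)]  # fragment borders, 0-based slicing
    fragments: list[Fragment] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed_cleavages, len(bounds))):
            start, end = bounds[i], bounds[j]
            length = end - start
            if length_window is not None and not (
                length_window[0] <= length <= length_window[1]
            ):
                continue
            fragments.append(
                Fragment(
                    sequence=protein.sequence[start:end],
                    parent_id=protein.id,
                    start=start + 1,
                    end=end,
                    missed_cleavages=j - i - 1,
                )
            )
    return fragments


@dataclass
class DigestSpec:
    """Full recipe for one synthetic two-group digesta experiment."""

    proteins: list[tuple[ParentProtein, float]]
    rules: Sequence[CleavageRule] = DEFAULT_RULES
    max_missed_cleavages: int = 7
    length_window: tuple[int, int] | None = (5, 30)
    #: log-normal abundance model, natural-log units
    mu: float = 1.0
    sigma: float = 1.2
    #: group effect: target parents, log2 effect size, affected fraction
    effect_parents: frozenset[str] = frozenset({"beta_CN"})
    delta: float = 3.0
    affected_fraction: float = 0.25
    #: replicate noise and detection
    replicate_cv: float = 0.1
    dropout_rate: float = 0.1
    n_replicates: int = 3
    group_labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.proteins)
        if not np.isclose(total, 1.0):
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        if any(w < 0 for _, w in self.proteins):
            raise ValueError("mixture weights must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.sigma < 0 or self.replicate_cv < 0:
            raise ValueError("sigma and replicate_cv must be >= 0")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_table(spec: DigestSpec) -> tuple[PeptideTable, dict]:
    """Generate a two-group peptide table plus a ground-truth ledger.

    The ledger records the peptides that carry the injected effect, each
    peptide's parents, and the per-group true means, so downstream recovery
    can be scored against the truth.
    """
    rng = np.random.default_rng(spec.seed)

    # Deterministic digest: unique peptides, their parents, summed mixture weight.
    weights: dict[str, float] = {}
    parents: dict[str, set[str]] = {}
    for protein, weight in spec.proteins:
        seen_here: set[str] = set()
        for frag in digest(protein, spec.rules, spec.max_missed_cleavages, spec.length_window):
            parents.setdefault(frag.sequence, set()).add(protein.id)
            if frag.sequence not in seen_here:  # weight counts each parent once
                weights[frag.sequence] = weights.get(frag.sequence, 0.0) + weight
                seen_here.add(frag.sequence)
    peptides = sorted(weights)
    if not peptides:
        raise ValueError("degenerate spec: no peptides survive digestion/length filter")

    base = {
        pep: weights[pep] * rng.lognormal(spec.mu, spec.sigma) for pep in peptides
    }
    targets = [p for p in peptides if parents[p] & spec.effect_parents]
    n_affected = (
        int(round(spec.affected_fraction * len(targets))) if spec.delta != 0.0 else 0
    )
    affected = {
        str(p) for p in (rng.choice(targets, size=n_affected, replace=False) if n_affected else [])
    }

    label_a, label_b = spec.group_labels
    samples_a = [f"{label_a}{i + 1}" for i in range(spec.n_replicates)]
    samples_b = [f"{label_b}{i + 1}" for i in range(spec.n_replicates)]
    samples = samples_a + samples_b
    groups = {**{s: label_a for s in samples_a}, **{s: label_b for s in samples_b}}

    means = {
        label_a: {pep: base[pep] for pep in peptides},
        label_b: {
            pep: base[pep] * (2.0 ** spec.delta if pep in affected else 1.0)
            for pep in peptides
        },
    }
    medians = {g: float(np.median(list(means[g].values()))) for g in (label_a, label_b)}

    records: list[PeptideRecord] = []
    for pep in peptides:
        abundances: dict[str, float] = {}
        for g in (label_a, label_b):
            mean = means[g][pep]
            for i in range(spec.n_replicates):
                value = (
                    mean
                    if spec.replicate_cv == 0.0
                    else max(rng.normal(mean, spec.replicate_cv * mean), 0.0)
                )
                dropped = (
                    mean < medians[g]
                    and spec.dropout_rate > 0.0
                    and rng.random() < spec.dropout_rate
                )
                if not dropped:
                    abundances[f"{g}{i + 1}"] = value
        records.append(
            PeptideRecord(
                pep,
                abundances,
                {"parents": sorted(parents[pep]), "affected": pep in affected},
            )
        )

    truth = {
        "affected": sorted(affected),
        "parents": {pep: sorted(parents[pep]) for pep in peptides},
        "true_mean_a": {pep: means[label_a][pep] for pep in peptides},
        "true_mean_b": {pep: means[label_b][pep] for pep in peptides},
        "n_peptides": len(peptides),
        "seed": spec.seed,
        "delta": spec.delta,
    }
    return PeptideTable(records, samples, groups), truth


# ---------------------------------------------------------------------------
# Study-like presets
# ---------------------------------------------------------------------------

#: beta-casein share of the casein fraction in the two gavage solutions.
BETA_CN_SHARE = {"obcn": 0.430, "fbcn": 0.634}
CASEIN_FRACTION = 0.40  # 40:60 casein:whey in both solutions
#: Relative abundance of the non-beta caseins in bovine casein (alphaS1:alphaS2:kappa).
_OTHER_CASEIN_PARTS = {"alphaS1_CN": 37.0, "alphaS2_CN": 10.0, "kappa_CN": 12.0}
#: Whey split in whey protein isolate (beta-lactoglobulin dominates).
_WHEY_PARTS = {"beta_LG": 0.75, "alpha_LA": 0.25}


def mixture_weights(preset: Literal["obcn", "fbcn"]) -> dict[str, float]:
    """Protein mixture weights (summing to 1) for a study-like preset."""
    beta_share = BETA_CN_SHARE[preset]
    weights = {"beta_CN": CASEIN_FRACTION * beta_share}
    other = CASEIN_FRACTION * (1.0 - beta_share)
    part_total = sum(_OTHER_CASEIN_PARTS.values())
    for pid, part in _OTHER_CASEIN_PARTS.items():
        weights[pid] = other * part / part_total
    for pid, part in _WHEY_PARTS.items():
        weights[pid] = (1.0 - CASEIN_FRACTION) * part
    return weights


def make_study_like(
    preset: Literal["obcn", "fbcn"] = "fbcn",
    seed: int = 0,
    **overrides,
) -> DigestSpec:
    """A :class:`DigestSpec` mirroring the study's gavage compositions.

    ``obcn``: ordinary beta-casein content (mixture weight 0.40 x 0.430);
    ``fbcn``: fortified (0.40 x 0.634). Group labels are OBCN/FBCN with the
    preset's composition generating both groups and the injected effect
    enriching beta-casein peptides in the fortified group. Any
    :class:`DigestSpec` field can be overridden by keyword.
    """
    proteins_by_id = {p.id: p for p in load_parent_proteins()}
    weights = mixture_weights(preset)
    spec_kwargs = dict(
        proteins=[(proteins_by_id[pid], w) for pid, w in weights.items()],
        group_labels=("OBCN", "FBCN"),
        seed=seed,
    )
    spec_kwargs.update(overrides)
    return DigestSpec(**spec_kwargs)
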