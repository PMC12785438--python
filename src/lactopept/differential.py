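"""Differential peptide abundance between two feeding groups.

Implements the two-group comparison applied to digesta peptidomes: detection
filtering, missing-value imputation, per-peptide log2 fold change with an
unpaired two-tailed Student's t-test (equal variance, df = n_a + n_b - 2),
volcano-style classification, Venn set arithmetic on distinct peptides, and
the percent-difference arithmetic used for group comparisons.

Orientation convention: fold changes are B over A, where B is the fortified
group — positive log2fc means enriched in the fortified group. Boundary
conventions: |log2fc| exactly equal to the fold-change threshold counts as
significant; p exactly equal to alpha counts as non-significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PeptideRecord, PeptideTable

Status = Literal["up", "down", "ns", "not_tested"]

#: Significance level; the study calls p < 0.05 significant.
DEFAULT_ALPHA = 0.05
#: Volcano fold-change cutoff in log2 units (2-fold), the conventional default.
DEFAULT_FC_THRESHOLD = 1.0
#: Minimum detections per group for a peptide to enter the comparison.
DEFAULT_MIN_DETECTED = 2


class DegenerateVarianceError(ValueError):
    """Pooled variance is zero; the t statistic is undefined."""


@dataclass
class DifferentialResult:
    """Per-peptide outcome of the two-group comparison (B over A)."""

    sequence: str
    mean_a: float
    mean_b: float
    log2fc: float
    p_value: float
    p_adjusted: float | None
    status: Status


@dataclass(frozen=True)
class VennSummary:
    """Distinct-peptide set arithmetic between two groups."""

    n_a: int
    n_b: int
    n_shared: int

    @property
    def n_unique_a(self) -> int:
        return self.n_a - self.n_shared

    @property
    def n_unique_b(self) -> int:
        return self.n_b - self.n_shared

    @property
    def n_union(self) -> int:
        return self.n_a + self.n_b - self.n_shared

    def as_dict(self) -> dict[str, int]:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_shared": self.n_shared,
            "n_unique_a": self.n_unique_a,
            "n_unique_b": self.n_unique_b,
            "n_union": self.n_union,
        }


# ---------------------------------------------------------------------------
# Filtering and imputation
# ---------------------------------------------------------------------------

def _n_detected(rec: PeptideRecord, samples: Sequence[str]) -> int:
    return sum(1 for s in samples if rec.abundances.get(s, 0.0) > 0.0)


def detect_filter(table: PeptideTable, min_detected: int = DEFAULT_MIN_DETECTED) -> PeptideTable:
    """Drop peptides not reliably detected in either group.

    A peptide is retained when it has >= ``min_detected`` positive,
    non-missing abundances in at least one group. A peptide passing in only
    one group is retained but flagged ``tested=False`` in its annotations:
    it contributes to set/Venn summaries but not to the t-test.
    """
    groups = table.group_labels
    cols = {g: table.samples_of(g) for g in groups}
    for g in groups:
        if min_detected > len(cols[g]):
            raise ValueError(
                f"min_detected={min_detected} exceeds group {g!r} size {len(cols[g])}"
            )
    kept: list[PeptideRecord] = []
    for rec in table.records:
        passed = [g for g in groups if _n_detected(rec, cols[g]) >= min_detected]
        if not passed:
            continue
        annotations = dict(rec.annotations)
        annotations["tested"] = len(passed) == len(groups)
        kept.append(replace(rec, annotations=annotations))
    return PeptideTable(kept, list(table.samples), dict(table.groups))


def impute_missing(
    table: PeptideTable,
    strategy: Literal["half_group_min", "zero"] = "half_group_min",
) -> PeptideTable:
    """Fill missing abundances ahead of the per-peptide statistics.

    ``half_group_min`` replaces each missing cell with half the minimum
    positive abundance of that peptide within its group, falling back to half
    the peptide's global minimum positive value when the group has none.
    ``zero`` fills with 0.0.
    """
    if strategy not in ("half_group_min", "zero"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    groups = table.group_labels
    cols = {g: table.samples_of(g) for g in groups}
    out: list[PeptideRecord] = []
    for rec in table.records:
        abundances = dict(rec.abundances)
        if strategy == "zero":
            for s in table.samples:
                abundances.setdefault(s, 0.0)
        else:
            positives = [v for v in rec.abundances.values() if v > 0.0]
            global_fill = min(positives) / 2.0 if positives else 0.0
            for g in groups:
                group_pos = [
                    rec.abundances[s]
                    for s in cols[g]
                    if rec.abundances.get(s, 0.0) > 0.0
                ]
                fill = min(group_pos) / 2.0 if group_pos else global_fill
                for s in cols[g]:
                    if s not in abundances:
                        abundances[s] = fill
        out.append(replace(rec, abundances=abundances))
    return PeptideTable(out, list(table.samples), dict(table.groups))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def student_t_two_sided(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Equal-variance unpaired Student's t-test, two-sided.

    Returns ``(t, p)`` with df = n_a + n_b - 2 and the two-sided p-value from
    the t distribution's survival function. Raises
    :class:`DegenerateVarianceError` when the pooled variance is zero (the
    caller maps this to a ``not_tested`` status).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 values")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / df
    if pooled_var <= 0.0:
        raise DegenerateVarianceError("zero pooled variance")
    se = math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    t = (a.mean() - b.mean()) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def classify(
    log2fc: float,
    p_value: float | None,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> Status:
    """Volcano classification of one peptide (B-over-A orientation)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if fc_threshold < 0.0:
        raise ValueError("fc_threshold must be >= 0")
    if p_value is None or math.isnan(p_value):
        return "not_tested"
    if p_value < alpha:
        if log2fc >= fc_threshold:
            return "up"
        if log2fc <= -fc_threshold:
            return "down"
    return "ns"


def differential_analysis(
    table: PeptideTable,
    group_a: str | None = None,
    group_b: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    log_transform: bool = True,
    adjust: bool = False,
) -> list[DifferentialResult]:
    """Per-peptide group comparison over a filtered, imputed table.

    ``group_a`` / ``group_b`` default to the table's two group labels in
    sample order (B is the fortified group by the pipeline's convention).
    Fold changes are computed on raw group means; the t-test runs on
    log2-transformed abundances by default (intensities are right-skewed),
    or on the raw values with ``log_transform=False``. With ``adjust=True``
    Benjamini-Hochberg values are reported in ``p_adjusted`` (annotation
    only; classification uses the raw p-value, as the study does).
    """
    labels = table.group_labels
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError(f"expected exactly two groups, got {labels}")
        group_a, group_b = labels
    cols_a = table.samples_of(group_a)
    cols_b = table.samples_of(group_b)

    results: list[DifferentialResult] = []
    for rec in table.records:
        vals_a = np.array([rec.abundances.get(s, 0.0) for s in cols_a])
        vals_b = np.array([rec.abundances.get(s, 0.0) for s in cols_b])
        mean_a = float(vals_a.mean())
        mean_b = float(vals_b.mean())
        if mean_a > 0.0 and mean_b > 0.0:
            log2fc = math.log2(mean_b / mean_a)
        elif mean_b > 0.0:
            log2fc = math.inf
        elif mean_a > 0.0:
            log2fc = -math.inf
        else:
            log2fc = 0.0

        p_value: float | None = None
        if rec.annotations.get("tested", True):
            try:
                if log_transform:
                    floor = _positive_floor(vals_a, vals_b)
                    ta = np.log2(np.maximum(vals_a, floor))
                    tb = np.log2(np.maximum(vals_b, floor))
                else:
                    ta, tb = vals_a, vals_b
                _, p_value = student_t_two_sided(ta, tb)
            except DegenerateVarianceError:
                p_value = None
        status = classify(log2fc, p_value, alpha, fc_threshold)
        results.append(
            DifferentialResult(
                sequence=rec.sequence,
                mean_a=mean_a,
                mean_b=mean_b,
                log2fc=log2fc,
                p_value=math.nan if p_value is None else p_value,
                p_adjusted=None,
                status=status,
            )
        )

    if adjust:
        tested = [r for r in results if not math.isnan(r.p_value)]
        if tested:
            _, p_adj, _, _ = multipletests([r.p_value for r in tested], method="fdr_bh")
            for r, q in zip(tested, p_adj):
                r.p_adjusted = float(q)
    return results


def _positive_floor(*arrays: np.ndarray) -> float:
    """Smallest positive value across arrays, halved; log2-safe floor for zeros."""
    pool = np.concatenate(arrays)
    positive = pool[pool > 0.0]
    if positive.size == 0:
        return 1.0
    return float(positive.min()) / 2.0


# ---------------------------------------------------------------------------
# Set / Venn arithmetic and percent differences
# ---------------------------------------------------------------------------

def venn_summary(set_a: Iterable[str], set_b: Iterable[str]) -> VennSummary:
    """Distinct-peptide overlap between two groups."""
    sa, sb = set(set_a), set(set_b)
    return VennSummary(n_a=len(sa), n_b=len(sb), n_shared=len(sa & sb))


def venn_from_counts(n_a: int, n_b: int, n_shared: int) -> VennSummary:
    """Venn arithmetic from printed counts (e.g. a published Venn diagram)."""
    if n_shared > min(n_a, n_b) or min(n_a, n_b, n_shared) < 0:
        raise ValueError(
            f"inconsistent Venn counts: n_a={n_a}, n_b={n_b}, n_shared={n_shared}"
        )
    return VennSummary(n_a=n_a, n_b=n_b, n_shared=n_shared)


def percent_difference(
    reference: float,
    other: float,
    mode: Literal["lower_than_ref", "more_than_ref"],
) -> float:
    """Percent difference of ``other`` relative to a positive ``reference``.

    ``lower_than_ref``: how much lower ``other`` is, as a percentage of the
    reference; ``more_than_ref``: how much higher.
    """
    if reference <= 0.0:
        raise ValueError("reference must be > 0")
    if mode == "lower_than_ref":
        return 100.0 * (reference - other) / reference
    if mode == "more_than_ref":
        return 100.0 * (other - reference) / reference
    raise ValueError(f"unknown mode {mode!r}")


def results_to_frame(results: Sequence[DifferentialResult]):
    """Differential results as a DataFrame (TSV export layout)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sequence": [r.sequence for r in results],
            "mean_a": [r.mean_a for r in results],
            "mean_b": [r.mean_b for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "status": [r.status for r in results],
        }
    )
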