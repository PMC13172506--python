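"""Validation statistics for the pooling strategy and workflow yields.

Covers sensitivity of pooled detection against individual sequencing,
the VAF-bin breakdown of where missed variants sit, the Wilcoxon
signed-rank check that pooled singleton VAFs center on the design
expectation 1/(2n), and diagnostic-yield summaries over a sequential
solo-then-trio workflow.

Percentages are reported to two decimals with half-up rounding so recomputed
values match printed ones digit for digit.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ValidationRecord",
    "CohortOutcome",
    "DetectionBreakdown",
    "AllelicBalanceResult",
    "sensitivity",
    "vaf_percent",
    "detection_breakdown",
    "allelic_balance_test",
    "yield_summary",
    "round_percent",
]

OUTCOMES = ("diagnosed_known_gene", "candidate_gene", "candidate_cnv", "unsolved")
PHASES = ("solo_wes", "trio_pooled")

# default VAF bin edges: detected at >=1%; near-miss band down to 0.55%;
# trace reads below that; no reads at all.  Contiguous half-open bins so
# every record lands somewhere.
DEFAULT_BIN_EDGES = (0.01, 0.0055)
DEFAULT_BIN_LABELS = ("vaf_ge_1pct", "vaf_0.55_to_1pct", "vaf_below_0.55pct", "no_reads")


def round_percent(value: float, decimals: int = 2) -> float:
    """Half-up decimal rounding, e.g. ``round_percent(96.805) == 96.81``."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ValidationRecord:
    """Pooled re-observation of one variant known from individual WES."""

    variant_key: str
    individual_id: str
    pool_id: str
    individual_wes_detected: bool
    pool_vaf: float
    pool_depth: int

    def __post_init__(self) -> None:
        if not 0 <= self.pool_vaf <= 1:
            raise ValueError(f"pool_vaf={self.pool_vaf} out of [0, 1]")


@dataclass(frozen=True)
class CohortOutcome:
    patient_id: str
    phase: str  # solo_wes | trio_pooled
    outcome: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


def sensitivity(true_positive: int, false_negative: int) -> float:
    """Detection sensitivity ``100 * TP / (TP + FN)``, two decimals.

    >>> sensitivity(1091, 36)
    96.81
    """
    if true_positive < 0 or false_negative < 0:
        raise ValueError("counts must be nonnegative")
    total = true_positive + false_negative
    if total == 0:
        raise ValueError("TP + FN must be > 0")
    return round_percent(100.0 * true_positive / total)


def vaf_percent(alt: int, depth: int) -> float:
    """VAF as a percentage rounded to two decimals.

    >>> vaf_percent(1, 172)
    0.58
    """
    if depth <= 0:
        raise ValueError(f"depth must be > 0, got {depth}")
    if not 0 <= alt <= depth:
        raise ValueError(f"alt must be in [0, depth], got {alt}/{depth}")
    return round_percent(100.0 * alt / depth)


@dataclass(frozen=True)
class DetectionBreakdown:
    counts: dict[str, int]  # label -> count, labels ordered high to low VAF
    detected: int
    not_detected: int
    sensitivity_pct: float


def detection_breakdown(
    vafs: Sequence[float],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    bin_labels: Sequence[str] = DEFAULT_BIN_LABELS,
) -> DetectionBreakdown:
    """Partition pooled VAFs into detection bins and derive sensitivity.

    ``bin_edges`` must be strictly decreasing thresholds; bins are
    ``[edge0, 1]``, ``[edge1, edge0)``, ..., ``(0, edge_last)`` and a final
    exact-zero bin, so the counts always partition the input.  "Detected"
    is the top bin (VAF at or above the first edge, the 1% presence
    threshold by default).
    """
    edges = list(bin_edges)
    if any(e <= 0 or e > 1 for e in edges):
        raise ValueError("bin edges must lie in (0, 1]")
    if any(a <= b for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly decreasing (non-overlapping bins)")
    if len(bin_labels) != len(edges) + 2:
        raise ValueError(
            f"need {len(edges) + 2} labels for {len(edges)} edges, got {len(bin_labels)}"
        )
    counts = {label: 0 for label in bin_labels}
    for vaf in vafs:
        if not 0 <= vaf <= 1:
            raise ValueError(f"VAF {vaf} out of [0, 1]")
        if vaf == 0:
            counts[bin_labels[-1]] += 1
            continue
        for i, edge in enumerate(edges):
            if vaf >= edge:
                counts[bin_labels[i]] += 1
                break
        else:
            counts[bin_labels[-2]] += 1
    detected = counts[bin_labels[0]]
    not_detected = len(vafs) - detected
    return DetectionBreakdown(
        counts=counts,
        detected=detected,
        not_detected=not_detected,
        sensitivity_pct=sensitivity(detected, not_detected),
    )


@dataclass(frozen=True)
class AllelicBalanceResult:
    median: float
    statistic: float
    pvalue: float
    n_nonzero: int
    degenerate: bool = False


def allelic_balance_test(
    vafs: Sequence[float], expected: float
) -> AllelicBalanceResult:
    """Wilcoxon signed-rank test of pooled VAFs against the design expectation.

    Tests whether the observed singleton VAFs deviate from the expected
    allelic balance ``1/(2n)``.  Zero differences are dropped; the exact
    null distribution is used for up to 25 nonzero differences (unless
    ties force the normal path), otherwise a normal approximation with
    continuity correction.  Returns the sample median alongside the test.
    """
    arr = np.asarray(vafs, dtype=float)
    if arr.size < 5:
        raise ValueError(f"need >= 5 observations, got {arr.size}")
    if not 0 < expected <= 0.5:
        raise ValueError(f"expected allelic balance must be in (0, 0.5], got {expected}")
    # round differences so binary representation noise cannot break exact
    # ties or symmetry (0.06 - 0.05 and -(0.04 - 0.05) must rank equally)
    diffs = np.round(arr - expected, 12)
    nonzero = diffs[diffs != 0]
    median = float(np.median(arr))
    if nonzero.size == 0:
        return AllelicBalanceResult(median, 0.0, 1.0, 0, degenerate=True)
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(
        nonzero,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    return AllelicBalanceResult(median, float(res.statistic), float(res.pvalue), int(nonzero.size))


def yield_summary(outcomes: Iterable[CohortOutcome]) -> pd.DataFrame:
    """Per-phase and overall diagnostic-yield table.

    Denominators: the solo phase counts against all patients; the trio
    phase counts against patients who entered the trio phase; overall rows
    aggregate each outcome across phases against all patients.  Unsolved is
    only meaningful per phase and is excluded from the overall rows.
    Percentages are recomputed from raw counts, two decimals, half-up.
    """
    rows = list(outcomes)
    if not rows:
        return pd.DataFrame(columns=["phase", "outcome", "count", "denominator", "percent"])
    all_patients = {r.patient_id for r in rows}
    trio_patients = {r.patient_id for r in rows if r.phase == "trio_pooled"}
    denominators = {"solo_wes": len(all_patients), "trio_pooled": len(trio_patients)}
    records = []
    for phase in PHASES:
        denom = denominators[phase]
        for outcome in OUTCOMES:
            n = sum(1 for r in rows if r.phase == phase and r.outcome == outcome)
            pct = round_percent(100.0 * n / denom) if denom else 0.0
            records.append((phase, outcome, n, denom, pct))
    for outcome in OUTCOMES:
        if outcome == "unsolved":
            continue
        n = sum(1 for r in rows if r.outcome == outcome)
        records.append(
            ("overall", outcome, n, len(all_patients),
             round_percent(100.0 * n / len(all_patients)))
        )
    return pd.DataFrame(records, columns=["phase", "outcome", "count", "denominator", "percent"])
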