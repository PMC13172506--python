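"""Solo-exome CNV filtering cascade and prioritization.

Pooled parental sequencing cannot segregate CNVs (depth-based callers need
individual-level coverage), so CNV handling stays on the proband's solo
exome and leans on quality/consistency filters instead: panel overlap,
within-run recurrence, multi-caller support, gene constraint (LOEUF), and
dosage-sensitivity scores — haploinsufficiency (HI) percentiles for
deletions, triplosensitivity (TS) percentiles for duplications, both on a
0–100 scale where lower means more likely dosage-sensitive — plus
containment within known benign population events of the same type.

Note on the LOEUF rule: the cascade's source text excludes calls with
LOEUF < 0.6 "indicative of low functional impact", which inverts the usual
reading of LOEUF (low LOEUF = constrained gene).  The default here follows
that literal rule; ``loeuf_rule="semantic"`` drops calls whose genes are
all *unconstrained* instead, and ``"off"`` disables the rule.  The CLI
warns whenever the literal rule is active.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .prioritize import GeneInfo

__all__ = [
    "CnvCall",
    "filter_cnvs",
    "prioritize_cnvs",
    "annotate_run_recurrence",
    "mark_population_containment",
    "LOEUF_CUTOFF",
    "DOSAGE_SCORE_MAX",
]

LOEUF_CUTOFF = 0.6
DOSAGE_SCORE_MAX = 40.0  # keep DEL iff HI < 40, DUP iff TS < 40


@dataclass(frozen=True)
class CnvCall:
    """One caller-merged CNV call with its filtering annotations.

    Coordinates are 1-based inclusive.  ``genes`` maps each overlapped gene
    symbol to its :class:`~triopool.prioritize.GeneInfo` (or ``None`` when
    no gene-level scores are known).  ``run_recurrence`` counts distinct
    individuals in the same sequencing run carrying an overlapping
    same-type call (including this one); see
    :func:`annotate_run_recurrence`.
    """

    chrom: str
    start: int
    end: int
    svtype: str  # DEL | DUP
    callers: frozenset[str]
    run_id: str = ""
    sample_id: str = ""
    run_recurrence: int = 1
    genes: Mapping[str, GeneInfo | None] = field(default_factory=dict)
    affects_coding: bool = True
    contained_in_population_event: bool = False
    phenotype_match: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")
        if self.svtype not in ("DEL", "DUP"):
            raise ValueError(f"svtype must be DEL or DUP, got {self.svtype!r}")
        if not self.callers:
            raise ValueError("callers must be nonempty")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def _min_score(self, attr: str) -> float | None:
        vals = [
            getattr(g, attr)
            for g in self.genes.values()
            if g is not None and getattr(g, attr) is not None
        ]
        return min(vals) if vals else None

    @property
    def min_loeuf(self) -> float | None:
        return self._min_score("loeuf")

    @property
    def min_hi(self) -> float | None:
        return self._min_score("hi_score")

    @property
    def min_ts(self) -> float | None:
        return self._min_score("ts_score")


def _rule_panel(call: CnvCall, panel: frozenset[str], cfg: dict) -> str | None:
    if not any(g in panel for g in call.genes):
        return "no_panel_gene"
    return None


def _rule_recurrence(call: CnvCall, panel: frozenset[str], cfg: dict) -> str | None:
    if call.run_recurrence > cfg["max_run_recurrence"]:
        return "recurrent_in_run"
    return None


def _rule_single_caller(call: CnvCall, panel: frozenset[str], cfg: dict) -> str | None:
    if len(call.callers) == 1:
        return "single_caller"
    return None


def _rule_loeuf(call: CnvCall, panel: frozenset[str], cfg: dict) -> str | None:
    mode = cfg["loeuf_rule"]
    if mode == "off":
        return None
    loeuf = call.min_loeuf
    if loeuf is None:
        return None  # rule not evaluable; retain
    if mode == "literal" and loeuf < cfg["loeuf_cutoff"]:
        return "loeuf_literal"
    if mode == "semantic" and loeuf >= cfg["loeuf_cutoff"]:
        return "loeuf_unconstrained"
    return None


def _rule_dosage(call: CnvCall, panel: frozenset[str], cfg: dict) -> str | None:
    if call.svtype == "DEL":
        hi = call.min_hi
        if hi is not None and hi >= cfg["dosage_score_max"]:
            return "haploinsufficiency"
    else:
        ts = call.min_ts
        if ts is not None and ts >= cfg["dosage_score_max"]:
            return "triplosensitivity"
    return None


def _rule_population(call: CnvCall, panel: frozenset[str], cfg: dict) -> str | None:
    if call.contained_in_population_event:
        return "contained_in_population_event"
    return None


_RULES = (
    _rule_panel,
    _rule_recurrence,
    _rule_single_caller,
    _rule_loeuf,
    _rule_dosage,
    _rule_population,
)


def filter_cnvs(
    calls: Sequence[CnvCall],
    panel: Iterable[str],
    loeuf_rule: str = "literal",
    loeuf_cutoff: float = LOEUF_CUTOFF,
    dosage_score_max: float = DOSAGE_SCORE_MAX,
    max_run_recurrence: int = 1,
    rule_order: Sequence | None = None,
) -> tuple[list[CnvCall], list[tuple[CnvCall, str]]]:
    """Apply the CNV cascade; return (retained, [(dropped_call, reason)]).

    Rules, in order: panel overlap; run recurrence; single-caller;
    LOEUF rule (see module note); dosage score (DEL: HI < 40, DUP:
    TS < 40); containment in a same-type benign population event.  Each
    dropped call carries its first failing rule; because the rules are
    mutually independent per call, the *retained set* is the same under
    any rule order (only reasons can differ).
    """
    if loeuf_rule not in ("literal", "semantic", "off"):
        raise ValueError(f"loeuf_rule must be literal/semantic/off, got {loeuf_rule!r}")
    cfg = {
        "loeuf_rule": loeuf_rule,
        "loeuf_cutoff": loeuf_cutoff,
        "dosage_score_max": dosage_score_max,
        "max_run_recurrence": max_run_recurrence,
    }
    panel_set = frozenset(panel)
    rules = tuple(rule_order) if rule_order is not None else _RULES
    retained: list[CnvCall] = []
    dropped: list[tuple[CnvCall, str]] = []
    for call in calls:
        reason = next(
            (r for rule in rules if (r := rule(call, panel_set, cfg)) is not None),
            None,
        )
        if reason is None:
            retained.append(call)
        else:
            dropped.append((call, reason))
    return retained, dropped


def prioritize_cnvs(retained: Sequence[CnvCall]) -> list[CnvCall]:
    """Rank retained calls: more callers first, then coding impact, then
    phenotype relevance, smallest span as the deterministic tie-break.
    The sort is stable, so fully tied calls keep their input order."""
    return sorted(
        retained,
        key=lambda c: (
            -len(c.callers),
            -int(c.affects_coding),
            -int(c.phenotype_match),
            c.span,
        ),
    )


def _reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / a.span, inter / b.span)


def annotate_run_recurrence(
    calls: Sequence[CnvCall], min_reciprocal_overlap: float = 0.5
) -> list[CnvCall]:
    """Fill ``run_recurrence`` from the calls of a whole sequencing run.

    For each call, counts distinct ``sample_id`` values (including its own
    carrier) with a same-run, same-type, same-chromosome call at >= 50%
    reciprocal overlap by default.
    """
    out: list[CnvCall] = []
    for call in calls:
        samples = {call.sample_id}
        for other in calls:
            if (
                other.run_id == call.run_id
                and other.svtype == call.svtype
                and other.chrom == call.chrom
                and other.sample_id != call.sample_id
                and _reciprocal_overlap(call, other) >= min_reciprocal_overlap
            ):
                samples.add(other.sample_id)
        out.append(replace(call, run_recurrence=len(samples)))
    return out


def mark_population_containment(
    calls: Sequence[CnvCall],
    events: Sequence[tuple[str, int, int, str]],
) -> list[CnvCall]:
    """Set ``contained_in_population_event`` for calls fully contained in a
    benign population event of the same type.

    ``events`` are 1-based inclusive ``(chrom, start, end, svtype)`` tuples
    (BED input is converted at the IO boundary).
    """
    out: list[CnvCall] = []
    for call in calls:
        contained = any(
            ev_chrom == call.chrom
            and ev_type == call.svtype
            and ev_start <= call.start
            and call.end <= ev_end
            for ev_chrom, ev_start, ev_end, ev_type in events
        )
        out.append(replace(call, contained_in_population_event=contained))
    return out
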