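"""Mode-of-inheritance-aware SNV filtering and candidate-gene assessment.

The cascade has three independent layers:

1. :func:`frequency_filter` — population-frequency gate keyed on the gene's
   mode of inheritance (dominant context: gnomAD allele count < 5;
   recessive context: allele frequency < 0.1%), with ClinVar overrides —
   benign/likely-benign is always dropped, pathogenic/likely-pathogenic is
   always kept regardless of frequency.
2. :func:`insilico_prioritize` — per-consequence in-silico evidence:
   missense calls are scored by CADD > 20, REVEL > 0.5, AlphaMissense > 0.6
   and SIFT < 0.01; loss-of-function calls need no missense predictors;
   synonymous/splice-region calls use SpliceAI >= 0.6.  The boolean
   connective over the missense predictors is configurable (majority of
   available predictors by default; ``all_of`` and ``any_of`` selectable).
3. :func:`select_reportable` — the zygosity/inheritance reporting criteria:
   (1) de novo variants in known dominant or X-linked genes, or in candidate
   genes with a Domino score >= 0.6; (2) hemizygous variants in X-linked
   genes; (3) homozygous or compound-heterozygous variants in known
   recessive genes or candidate genes with Domino < 0.6.

:func:`candidate_gene_evidence` summarises gene-constraint support for a
candidate (pLI > 0.9, pNull < 0.1, LOEUF < 0.6, missense Z > 3.09, Domino
>= 0.6, gnomAD absent-or-singleton) as flags for ranking; no composite
cutoff is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "AnnotatedVariant",
    "GeneInfo",
    "FilterDecision",
    "InsilicoVerdict",
    "ReportableCall",
    "EvidenceSummary",
    "frequency_filter",
    "insilico_prioritize",
    "select_reportable",
    "candidate_gene_evidence",
]

CONSEQUENCE_CLASSES = ("missense", "lof", "synonymous", "splice_region", "other")
CLINVAR_CLASSES = ("P", "LP", "VUS", "LB", "B", "none")

# in-silico thresholds for missense evidence
CADD_MIN = 20.0
REVEL_MIN = 0.5
ALPHAMISSENSE_MIN = 0.6
SIFT_MAX = 0.01
SPLICEAI_MIN = 0.6  # inclusive

# candidate-gene constraint thresholds
DOMINO_DOMINANT_MIN = 0.6
PLI_HIGH = 0.9
PNULL_LOW = 0.1
LOEUF_CONSTRAINED = 0.6
MISZ_CONSTRAINED = 3.09


@dataclass(frozen=True)
class GeneInfo:
    """Gene-level annotations used for prioritization.

    ``moi`` is the established mode of inheritance (AD/AR/XL/unknown);
    ``in_panel`` marks membership in the curated disease-gene panel;
    the remaining scores are the usual constraint metrics and may be
    missing (``None``).
    """

    symbol: str
    moi: str = "unknown"
    in_panel: bool = False
    domino: float | None = None
    pli: float | None = None
    pnull: float | None = None
    loeuf: float | None = None
    mis_z: float | None = None
    hi_score: float | None = None
    ts_score: float | None = None

    def __post_init__(self) -> None:
        if self.moi not in ("AD", "AR", "XL", "unknown"):
            raise ValueError(f"unknown MOI {self.moi!r} for {self.symbol}")
        for name, lo, hi in (
            ("domino", 0, 1), ("pli", 0, 1), ("pnull", 0, 1),
            ("hi_score", 0, 100), ("ts_score", 0, 100),
        ):
            val = getattr(self, name)
            if val is not None and not lo <= val <= hi:
                raise ValueError(f"{name}={val} out of [{lo}, {hi}] for {self.symbol}")
        if self.loeuf is not None and self.loeuf <= 0:
            raise ValueError(f"loeuf must be positive, got {self.loeuf}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant joined to the annotations the cascade consumes.

    Any score may be ``None`` (missing).  ``inheritance`` is an
    :class:`~triopool.classify.InheritanceStatus` value as a string, or
    ``"unknown"`` when no trio evidence exists (solo analysis).
    """

    key: str
    gene: str
    consequence: str = "other"
    zygosity: str = "het"  # het | hom | hemi
    inheritance: str = "unknown"
    gnomad_ac: int | None = None
    gnomad_af: float | None = None
    clinvar: str = "none"
    cadd: float | None = None
    revel: float | None = None
    alphamissense: float | None = None
    sift: float | None = None
    spliceai: float | None = None
    phylop: float | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.zygosity not in ("het", "hom", "hemi"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.clinvar not in CLINVAR_CLASSES:
            raise ValueError(f"unknown ClinVar class {self.clinvar!r}")
        for name in ("revel", "alphamissense", "sift", "spliceai"):
            val = getattr(self, name)
            if val is not None and not 0 <= val <= 1:
                raise ValueError(f"{name}={val} out of [0, 1]")
        if self.gnomad_af is not None and not 0 <= self.gnomad_af <= 1:
            raise ValueError(f"gnomad_af={self.gnomad_af} out of [0, 1]")
        if self.gnomad_ac is not None and self.gnomad_ac < 0:
            raise ValueError(f"gnomad_ac must be >= 0, got {self.gnomad_ac}")


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str


def frequency_filter(v: AnnotatedVariant, g: GeneInfo | None = None) -> FilterDecision:
    """Population-frequency gate with ClinVar overrides.

    ClinVar benign/likely-benign drops the variant regardless of frequency;
    pathogenic/likely-pathogenic keeps it regardless of frequency.  These
    overrides take precedence over everything else.  Otherwise the gene's
    MOI sets the context: recessive genes use allele frequency < 0.001,
    dominant and X-linked genes (and genes of unknown MOI) use allele
    count < 5.  A missing gnomAD entry is treated as absent (AC 0, AF 0).
    """
    if v.clinvar in ("B", "LB"):
        return FilterDecision(False, "clinvar_benign")
    if v.clinvar in ("P", "LP"):
        return FilterDecision(True, "clinvar_pathogenic")
    moi = g.moi if g is not None else "unknown"
    ac = v.gnomad_ac if v.gnomad_ac is not None else 0
    af = v.gnomad_af if v.gnomad_af is not None else 0.0
    if moi == "AR":
        if af < 0.001:
            return FilterDecision(True, "rare_in_recessive_context")
        return FilterDecision(False, "gnomad_af_above_recessive_cutoff")
    # dominant / X-linked / unknown context
    if ac < 5:
        return FilterDecision(True, "rare_in_dominant_context")
    return FilterDecision(False, "gnomad_ac_above_dominant_cutoff")


@dataclass(frozen=True)
class InsilicoVerdict:
    prioritized: bool
    verdicts: Mapping[str, bool]  # per-predictor pass/fail over available scores
    flags: tuple[str, ...] = ()


def _combine(verdicts: dict[str, bool], mode: str) -> bool:
    if not verdicts:
        return False
    hits = sum(verdicts.values())
    if mode == "all_of":
        return hits == len(verdicts)
    if mode == "any_of":
        return hits > 0
    if mode == "majority":
        return 2 * hits > len(verdicts)
    raise ValueError(f"unknown combination mode {mode!r}")


def insilico_prioritize(v: AnnotatedVariant, mode: str = "majority") -> InsilicoVerdict:
    """Per-consequence in-silico evidence assessment.

    Missense: CADD > 20, REVEL > 0.5, AlphaMissense > 0.6, SIFT < 0.01,
    combined over the *available* predictors per ``mode``; a missense call
    with no predictor at all is not prioritized and is flagged
    ``no_evidence``.  Loss-of-function calls are prioritized without
    missense predictors.  Synonymous and splice-region calls use
    SpliceAI >= 0.6 (inclusive).  Every per-predictor verdict is returned.
    """
    if v.consequence == "lof":
        return InsilicoVerdict(True, {})
    if v.consequence == "missense":
        verdicts: dict[str, bool] = {}
        if v.cadd is not None:
            verdicts["cadd"] = v.cadd > CADD_MIN
        if v.revel is not None:
            verdicts["revel"] = v.revel > REVEL_MIN
        if v.alphamissense is not None:
            verdicts["alphamissense"] = v.alphamissense > ALPHAMISSENSE_MIN
        if v.sift is not None:
            verdicts["sift"] = v.sift < SIFT_MAX
        if not verdicts:
            return InsilicoVerdict(False, {}, flags=("no_evidence",))
        return InsilicoVerdict(_combine(verdicts, mode), verdicts)
    if v.consequence in ("synonymous", "splice_region"):
        if v.spliceai is None:
            return InsilicoVerdict(False, {}, flags=("no_evidence",))
        return InsilicoVerdict(v.spliceai >= SPLICEAI_MIN, {"spliceai": v.spliceai >= SPLICEAI_MIN})
    return InsilicoVerdict(False, {}, flags=("no_rule_for_consequence",))


@dataclass(frozen=True)
class EvidenceSummary:
    """Constraint-evidence flags for candidate-gene ranking (no hard cutoff)."""

    flags: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.flags)


def candidate_gene_evidence(v: AnnotatedVariant, g: GeneInfo) -> EvidenceSummary:
    """Flag the constraint metrics supporting a candidate gene/variant.

    Returns the satisfied flags among {domino_dominant, pli_high, pnull_low,
    loeuf_constrained, misz_constrained, gnomad_absent_or_singleton}; the
    count is for ranking only, no composite threshold is applied.
    """
    flags: set[str] = set()
    if g.domino is not None and g.domino >= DOMINO_DOMINANT_MIN:
        flags.add("domino_dominant")
    if g.pli is not None and g.pli > PLI_HIGH:
        flags.add("pli_high")
    if g.pnull is not None and g.pnull < PNULL_LOW:
        flags.add("pnull_low")
    if g.loeuf is not None and g.loeuf < LOEUF_CONSTRAINED:
        flags.add("loeuf_constrained")
    if g.mis_z is not None and g.mis_z > MISZ_CONSTRAINED:
        flags.add("misz_constrained")
    if v.gnomad_ac is not None and v.gnomad_ac <= 1:
        flags.add("gnomad_absent_or_singleton")
    elif v.gnomad_ac is None:
        flags.add("gnomad_absent_or_singleton")
    return EvidenceSummary(frozenset(flags))


@dataclass(frozen=True)
class ReportableCall:
    """One variant (or comp-het pair) matching a reporting criterion."""

    variants: tuple[AnnotatedVariant, ...]
    gene: str
    criterion: str  # denovo_AD_XL | denovo_candidate_dominant | hemizygous_XL
    #               | biallelic_AR | biallelic_candidate_recessive
    tier: str  # known_gene | candidate_gene
    evidence_flags: frozenset[str] = frozenset()
    flags: tuple[str, ...] = ()


def _denovo_call(v: AnnotatedVariant, g: GeneInfo | None) -> ReportableCall | None:
    if v.inheritance != "de_novo":
        return None
    if g is not None and g.in_panel and g.moi in ("AD", "XL"):
        return ReportableCall((v,), v.gene, "denovo_AD_XL", "known_gene")
    if g is not None and g.domino is not None and g.domino >= DOMINO_DOMINANT_MIN:
        ev = candidate_gene_evidence(v, g)
        return ReportableCall((v,), v.gene, "denovo_candidate_dominant",
                              "candidate_gene", ev.flags)
    return None


def _hemizygous_call(v: AnnotatedVariant, g: GeneInfo | None) -> ReportableCall | None:
    if v.zygosity != "hemi" or g is None or g.moi != "XL":
        return None
    tier = "known_gene" if g.in_panel else "candidate_gene"
    ev = candidate_gene_evidence(v, g) if tier == "candidate_gene" else EvidenceSummary(frozenset())
    return ReportableCall((v,), v.gene, "hemizygous_XL", tier, ev.flags)


def _recessive_gene_branch(g: GeneInfo | None) -> tuple[str, str, tuple[str, ...]] | None:
    """Which recessive criterion a gene supports, or None."""
    if g is not None and g.in_panel and g.moi == "AR":
        return "biallelic_AR", "known_gene", ()
    if g is not None and g.domino is not None and g.domino < DOMINO_DOMINANT_MIN:
        return "biallelic_candidate_recessive", "candidate_gene", ()
    if g is None or (g.domino is None and g.moi == "unknown"):
        # no dominance evidence either way: surface under the recessive
        # criterion but flag the missing MOI evidence
        return "biallelic_candidate_recessive", "candidate_gene", ("no_moi_evidence",)
    return None


def select_reportable(
    variants: Iterable[AnnotatedVariant],
    genes: Mapping[str, GeneInfo],
) -> list[ReportableCall]:
    """Apply the three zygosity/inheritance reporting criteria.

    Criteria are evaluated per variant in their stated order — de novo in a
    dominant/X-linked context, hemizygous in an X-linked gene, biallelic in
    a recessive context — and the first match wins, so each variant yields
    at most one single-variant call.  Compound-heterozygous pairs (one
    maternal, one paternal heterozygous variant in the same gene) are
    emitted as two-variant calls under the recessive criterion; a gene's
    pair calls are additional to any single-variant calls of its members.
    """
    calls: list[ReportableCall] = []
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        by_gene.setdefault(v.gene, []).append(v)

    for gene, vs in by_gene.items():
        g = genes.get(gene)
        for v in vs:
            call = _denovo_call(v, g)
            if call is None:
                call = _hemizygous_call(v, g)
            if call is None and v.zygosity == "hom":
                branch = _recessive_gene_branch(g)
                if branch is not None:
                    criterion, tier, extra = branch
                    ev = (candidate_gene_evidence(v, g).flags
                          if (tier == "candidate_gene" and g is not None) else frozenset())
                    call = ReportableCall((v,), gene, criterion, tier, ev, extra)
            if call is not None:
                calls.append(call)

        # compound heterozygotes: in-trans pairs inferred from pool origin
        branch = _recessive_gene_branch(g)
        if branch is not None:
            criterion, tier, extra = branch
            mats = [v for v in vs if v.zygosity == "het" and v.inheritance == "maternal"]
            pats = [v for v in vs if v.zygosity == "het" and v.inheritance == "paternal"]
            for vm, vp in itertools.product(mats, pats):
                ev = (candidate_gene_evidence(vm, g).flags
                      if (tier == "candidate_gene" and g is not None) else frozenset())
                calls.append(
                    ReportableCall((vm, vp), gene, criterion, tier, ev, extra)
                )
    return calls


def prioritize_variants(
    variants: Iterable[AnnotatedVariant],
    genes: Mapping[str, GeneInfo],
    mode: str = "majority",
) -> list[ReportableCall]:
    """Full cascade: frequency gate, in-silico evidence, reporting criteria.

    ClinVar P/LP variants bypass the in-silico requirement (they carry
    their own evidence); everything else must pass
    :func:`insilico_prioritize` before the reporting criteria are applied.
    """
    screened: list[AnnotatedVariant] = []
    for v in variants:
        dec = frequency_filter(v, genes.get(v.gene))
        if not dec.keep:
            continue
        if v.clinvar in ("P", "LP") or insilico_prioritize(v, mode=mode).prioritized:
            screened.append(v)
    return select_reportable(screened, genes)
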