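"""Inheritance classification of proband variants from pooled-parent evidence.

Parental pools cannot yield individual genotypes; they answer a single
question per site: is the proband's allele *present* in the maternal pool,
in the paternal pool, in both, or in neither?  Presence is decided by the
pool VAF against a fixed threshold (1% by default — a heterozygous carrier
in a pool of 10 contributes an expected 5%, so 1% separates carriers from
sequencing noise while tolerating under-representation).  The combination
of the two presence calls classifies the variant as de novo, maternal,
paternal, or biparental; a pool with no usable coverage at the site makes
the call undetermined rather than silently de novo.

On chrX in a male proband a hemizygous variant can only come from the
mother, so the paternal pool is non-informative and the decision uses the
maternal pool alone.  This sex-aware rule is an explicit design choice of
this package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pool_design import required_pool_depth

__all__ = [
    "Presence",
    "InheritanceStatus",
    "ProbandVariant",
    "PoolObservation",
    "InheritanceCall",
    "PhasedPair",
    "PhasingResult",
    "qc_proband_variant",
    "pool_presence",
    "recount_pool_vaf",
    "classify_inheritance",
    "phase_compound_hets",
    "variant_key",
]

_X_NAMES = {"X", "chrX"}
_Y_NAMES = {"Y", "chrY"}
_MT_NAMES = {"MT", "chrMT", "M", "chrM"}


class Presence(str, Enum):
    """Presence state of a proband allele in one parental pool."""

    PRESENT = "present"
    ABSENT = "absent"
    INSUFFICIENT = "insufficient"  # no usable pool coverage at the site


class InheritanceStatus(str, Enum):
    DE_NOVO = "de_novo"
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BIPARENTAL = "biparental"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ProbandVariant:
    """One normalized biallelic proband call with read support.

    ``genotype`` is one of ``het``, ``hom_alt``, ``hemi``.  Coordinates are
    1-based VCF convention.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    genotype: str = "het"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError(
                f"alt_reads must be in [0, depth]: alt={self.alt_reads}, depth={self.depth}"
            )
        if self.genotype not in ("het", "hom_alt", "hemi"):
            raise ValueError(f"unknown genotype {self.genotype!r}")

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else 0.0

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PoolObservation:
    """Read evidence for one site in one parental pool.

    ``source`` records whether the counts came from the pool's variant
    caller output or from a raw pileup recount at the site; the recount is
    preferred when both exist because caller output can miss low-fraction
    carrier alleles entirely.
    """

    pool_id: str  # "maternal" | "paternal"
    depth: int
    alt_reads: int
    source: str = "caller"

    def __post_init__(self) -> None:
        if self.pool_id not in ("maternal", "paternal"):
            raise ValueError(f"pool_id must be maternal/paternal, got {self.pool_id!r}")
        if self.depth < 0 or not 0 <= self.alt_reads <= max(self.depth, 0):
            raise ValueError(
                f"alt_reads must be in [0, depth]: alt={self.alt_reads}, depth={self.depth}"
            )

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else 0.0


@dataclass(frozen=True)
class InheritanceCall:
    """Classification of one proband variant given both pools."""

    variant_key: str
    status: InheritanceStatus
    maternal_presence: Presence
    paternal_presence: Presence
    maternal: PoolObservation
    paternal: PoolObservation
    flags: tuple[str, ...] = ()

    @property
    def maternal_present(self) -> bool:
        return self.maternal_presence is Presence.PRESENT

    @property
    def paternal_present(self) -> bool:
        return self.paternal_presence is Presence.PRESENT


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


def qc_proband_variant(
    v: ProbandVariant, min_vaf: float = 0.3, min_dp: int = 20
) -> bool:
    """Proband call quality gate: VAF >= ``min_vaf`` and DP >= ``min_dp``.

    Both bounds are inclusive: a call at exactly VAF 0.30 and DP 20 passes.
    """
    return v.vaf >= min_vaf and v.depth >= min_dp


def pool_presence(obs: PoolObservation, threshold: float = 0.01) -> Presence:
    """Decide presence of the allele in a pool from its VAF.

    Inclusive at the threshold: VAF exactly 1% counts as present.  A pool
    with zero depth at the site cannot distinguish absence from dropout and
    returns :attr:`Presence.INSUFFICIENT`.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if obs.depth == 0:
        return Presence.INSUFFICIENT
    return Presence.PRESENT if obs.vaf >= threshold else Presence.ABSENT


def recount_pool_vaf(
    counts_table: pd.DataFrame,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    pool_id: str = "maternal",
) -> PoolObservation:
    """Look up raw pileup counts for a site and return a recount observation.

    ``counts_table`` is the frame produced by
    :func:`triopool.io.read_counts_table`, uniquely indexed by
    ``(chrom, pos, ref, alt)``.  A site missing from the table yields a
    depth-0 observation (insufficient pool coverage) — never a silent
    absence.
    """
    key = (str(chrom), int(pos), str(ref), str(alt))
    try:
        row = counts_table.loc[key]
    except KeyError:
        return PoolObservation(pool_id=pool_id, depth=0, alt_reads=0, source="recount")
    if isinstance(row, pd.DataFrame):  # duplicate index entries
        raise ValueError(f"duplicate counts-table rows for site {key}")
    return PoolObservation(
        pool_id=pool_id,
        depth=int(row["depth"]),
        alt_reads=int(row["alt_count"]),
        source="recount",
    )


def _contig_class(chrom: str) -> str:
    if chrom in _X_NAMES:
        return "X"
    if chrom in _Y_NAMES:
        return "Y"
    if chrom in _MT_NAMES:
        return "MT"
    return "autosome"


# Autosomal decision table over (maternal, paternal) presence.
_AUTOSOMAL_TABLE: Mapping[tuple[Presence, Presence], InheritanceStatus] = {
    (Presence.ABSENT, Presence.ABSENT): InheritanceStatus.DE_NOVO,
    (Presence.PRESENT, Presence.ABSENT): InheritanceStatus.MATERNAL,
    (Presence.ABSENT, Presence.PRESENT): InheritanceStatus.PATERNAL,
    (Presence.PRESENT, Presence.PRESENT): InheritanceStatus.BIPARENTAL,
}


def classify_inheritance(
    v: ProbandVariant,
    maternal: PoolObservation,
    paternal: PoolObservation,
    sex: str = "unknown",
    threshold: float = 0.01,
    pool_size: int | None = None,
    low_depth_fraction: float = 0.5,
) -> InheritanceCall:
    """Classify one QC-passing proband variant from both pool observations.

    Autosomes (and chrX in a female, or chrX het in a male — both pools
    informative): absent/absent is de novo, presence in exactly one pool is
    uniparental, presence in both is biparental.  Insufficient coverage in
    any pool the decision needs makes the call undetermined.

    chrX hemizygous variant in a male proband: only the maternal pool is
    informative (fathers do not transmit X to sons); the paternal presence
    is recorded in the evidence but ignored for the status.

    chrY and mitochondrial contigs, and chrX with unknown proband sex, are
    returned undetermined with an explanatory flag.

    When ``pool_size`` is given, a warning flag is attached to any pool
    whose depth falls below ``low_depth_fraction`` of the design target
    depth for that pool size.
    """
    flags: list[str] = []
    mat = pool_presence(maternal, threshold)
    pat = pool_presence(paternal, threshold)

    if pool_size is not None:
        target = required_pool_depth(pool_size)
        for obs, label in ((maternal, "maternal"), (paternal, "paternal")):
            if obs.depth < low_depth_fraction * target:
                flags.append(f"low_pool_depth:{label}")

    contig = _contig_class(v.chrom)
    status: InheritanceStatus

    if contig in ("Y", "MT"):
        flags.append(f"contig_not_classified:{contig}")
        status = InheritanceStatus.UNDETERMINED
    elif contig == "X" and sex == "unknown":
        flags.append("sex_unknown_on_chrX")
        status = InheritanceStatus.UNDETERMINED
    elif contig == "X" and sex == "male" and v.genotype == "hemi":
        # maternal pool alone decides; paternal X is never transmitted to a son
        if mat is Presence.INSUFFICIENT:
            flags.append("insufficient_pool_coverage:maternal")
            status = InheritanceStatus.UNDETERMINED
        elif mat is Presence.PRESENT:
            status = InheritanceStatus.MATERNAL
        else:
            status = InheritanceStatus.DE_NOVO
    else:
        if contig == "X" and sex == "male":
            flags.append("male_het_on_chrX")
        insufficient = [
            label
            for p, label in ((mat, "maternal"), (pat, "paternal"))
            if p is Presence.INSUFFICIENT
        ]
        if insufficient:
            flags.extend(f"insufficient_pool_coverage:{lab}" for lab in insufficient)
            status = InheritanceStatus.UNDETERMINED
        else:
            status = _AUTOSOMAL_TABLE[(mat, pat)]

    return InheritanceCall(
        variant_key=v.key,
        status=status,
        maternal_presence=mat,
        paternal_presence=pat,
        maternal=maternal,
        paternal=paternal,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class PhasedPair:
    """A candidate compound-heterozygous pair with its phasing verdict."""

    first: ProbandVariant
    second: ProbandVariant
    phase: str  # "in_trans" | "unphaseable"
    reason: str = ""


@dataclass
class PhasingResult:
    in_trans: list[PhasedPair] = field(default_factory=list)
    unphaseable: list[PhasedPair] = field(default_factory=list)


def phase_compound_hets(
    variants_in_gene: Sequence[tuple[ProbandVariant, InheritanceCall]],
) -> PhasingResult:
    """Phase candidate compound heterozygotes in one gene from pool origin.

    A pair is in-trans when one member is maternal and the other paternal.
    Pairs in which either member is biparental (carrier in both pools —
    parental origin ambiguous) or undetermined are reported unphaseable
    with the blocking reason.  Same-parent pairs are in-cis and omitted.
    All variants must be heterozygous in the proband.
    """
    result = PhasingResult()
    for (v1, c1), (v2, c2) in itertools.combinations(variants_in_gene, 2):
        statuses = {c1.status, c2.status}
        if statuses == {InheritanceStatus.MATERNAL, InheritanceStatus.PATERNAL}:
            result.in_trans.append(PhasedPair(v1, v2, "in_trans"))
        elif InheritanceStatus.BIPARENTAL in statuses:
            result.unphaseable.append(
                PhasedPair(v1, v2, "unphaseable", reason="carrier in both pools")
            )
        elif InheritanceStatus.UNDETERMINED in statuses:
            result.unphaseable.append(
                PhasedPair(v1, v2, "unphaseable", reason="undetermined inheritance")
            )
        # same-parent or de novo combinations are in-cis / not a comp-het pair
    return result


def classify_variants(
    variants: Iterable[ProbandVariant],
    maternal_counts: pd.DataFrame,
    paternal_counts: pd.DataFrame,
    sex: str = "unknown",
    threshold: float = 0.01,
    min_vaf: float = 0.3,
    min_dp: int = 20,
    pool_size: int | None = None,
) -> list[tuple[ProbandVariant, InheritanceCall]]:
    """QC-filter proband variants and classify each against recounted pools."""
    out: list[tuple[ProbandVariant, InheritanceCall]] = []
    for v in variants:
        if not qc_proband_variant(v, min_vaf=min_vaf, min_dp=min_dp):
            continue
        mat = recount_pool_vaf(maternal_counts, v.chrom, v.pos, v.ref, v.alt, "maternal")
        pat = recount_pool_vaf(paternal_counts, v.chrom, v.pos, v.ref, v.alt, "paternal")
        out.append(
            (v, classify_inheritance(v, mat, pat, sex=sex, threshold=threshold,
                                     pool_size=pool_size))
        )
    return out
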