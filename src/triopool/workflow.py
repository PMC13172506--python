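"""The sequential diagnostic workflow: solo prioritization, then trio
pooled analysis for undiagnosed patients with parental pools.

Per patient: the solo phase keeps QC-passing, frequency-passing variants
and diagnoses on ClinVar pathogenic/likely-pathogenic hits in panel genes.
Undiagnosed patients with pool data proceed to the trio phase, where each
variant is classified against the recounted pool evidence and the
mode-of-inheritance-aware reporting criteria run with inheritance attached.
Patients without parental samples are annotated as such and cannot advance.
Deterministic given config and inputs; all randomness lives in the
simulator.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .classify import ProbandVariant, classify_variants
from .config import RunConfig
from .io import join_annotations, read_counts_table, read_vcf
from .prioritize import GeneInfo, frequency_filter, insilico_prioritize, select_reportable
from .simulate import SimulatedCohort
from .stats import CohortOutcome

logger = logging.getLogger("triopool")

__all__ = ["run_workflow", "load_cohort_dir", "outcomes_from_frame"]


def _proband_variants(df: pd.DataFrame) -> list[ProbandVariant]:
    return [
        ProbandVariant(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            depth=int(r.depth), alt_reads=int(r.alt_reads), genotype=str(r.genotype),
        )
        for r in df.itertuples(index=False)
    ]


def _annotation_map(annotations: pd.DataFrame) -> dict[str, dict]:
    out: dict[str, dict] = {}
    for row in annotations.to_dict("records"):
        ann = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        if ann.get("gnomad_ac") is not None:
            ann["gnomad_ac"] = int(ann["gnomad_ac"])
        ann.setdefault("clinvar", "none")
        ann["clinvar"] = ann["clinvar"] or "none"
        out[str(row["key"])] = ann
    return out


def _gene_map(genes: pd.DataFrame) -> dict[str, GeneInfo]:
    out: dict[str, GeneInfo] = {}
    for row in genes.to_dict("records"):
        kwargs = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        kwargs["in_panel"] = bool(kwargs.get("in_panel"))
        kwargs["moi"] = kwargs.get("moi") or "unknown"
        out[str(row["symbol"])] = GeneInfo(**kwargs)
    return out


def run_workflow(
    cohort: SimulatedCohort,
    config: RunConfig | None = None,
    pools_available: set[str] | None = None,
) -> pd.DataFrame:
    """Run the two-phase workflow over a cohort; one outcome row per
    patient per phase entered (columns: patient_id, phase, outcome, flags).

    ``pools_available`` restricts which patients have parental pool data
    (default: all).
    """
    config = config or RunConfig()
    genes = _gene_map(cohort.genes)
    annotations = _annotation_map(cohort.annotations)
    rows: list[tuple[str, str, str, str]] = []

    for trio_id in sorted(cohort.probands):
        variants = [
            v for v in _proband_variants(cohort.probands[trio_id])
            if v.vaf >= config.proband_min_vaf and v.depth >= config.proband_min_dp
        ]
        annotated = [
            av for v in variants
            if (av := join_annotations(v, annotations)) is not None
            and frequency_filter(av, genes.get(av.gene)).keep
        ]
        plp = [
            av for av in annotated
            if av.clinvar in ("P", "LP") and genes.get(av.gene) is not None
            and genes[av.gene].in_panel
        ]
        if plp:
            rows.append((trio_id, "solo_wes", "diagnosed_known_gene", ""))
            logger.info("%s: solo-phase P/LP hit in %s", trio_id, plp[0].gene)
            continue
        candidates = [
            av for av in annotated
            if insilico_prioritize(av, mode=config.predictor_mode).prioritized
        ]
        if 0 < len(candidates) <= config.max_unresolved_vus:
            # few enough candidates to segregate individually; no trio needed
            rows.append((trio_id, "solo_wes", "candidate_gene", "segregation_pending"))
            continue
        rows.append((trio_id, "solo_wes", "unsolved", ""))

        if pools_available is not None and trio_id not in pools_available:
            rows.append((trio_id, "trio_pooled", "unsolved", "no_parental_samples"))
            continue

        classified = classify_variants(
            variants,
            cohort.maternal_counts.set_index(["chrom", "pos", "ref", "alt"]),
            cohort.paternal_counts.set_index(["chrom", "pos", "ref", "alt"]),
            sex=cohort.proband_sex.get(trio_id, "unknown"),
            threshold=config.pool_presence_threshold,
            min_vaf=config.proband_min_vaf,
            min_dp=config.proband_min_dp,
            pool_size=config.pool_size,
        )
        trio_annotated = [
            av for v, call in classified
            if (av := join_annotations(v, annotations, inheritance=call.status.value))
            is not None and frequency_filter(av, genes.get(av.gene)).keep
            and (av.clinvar in ("P", "LP")
                 or insilico_prioritize(av, mode=config.predictor_mode).prioritized)
        ]
        calls = select_reportable(trio_annotated, genes)
        if any(c.tier == "known_gene" for c in calls):
            rows.append((trio_id, "trio_pooled", "diagnosed_known_gene", ""))
        elif calls:
            rows.append((trio_id, "trio_pooled", "candidate_gene", ""))
        else:
            rows.append((trio_id, "trio_pooled", "unsolved", ""))

    return pd.DataFrame(rows, columns=["patient_id", "phase", "outcome", "flags"])


def outcomes_from_frame(df: pd.DataFrame) -> list[CohortOutcome]:
    return [
        CohortOutcome(str(r.patient_id), str(r.phase), str(r.outcome))
        for r in df.itertuples(index=False)
    ]


def load_cohort_dir(indir: str | Path) -> SimulatedCohort:
    """Load a cohort directory written by :func:`triopool.io.write_cohort`."""
    indir = Path(indir)
    samples = pd.read_csv(indir / "samples.tsv", sep="\t", dtype=str)
    probands: dict[str, pd.DataFrame] = {}
    sexes: dict[str, str] = {}
    for i, row in enumerate(samples.sort_values("trio_id").itertuples(index=False)):
        vcf = indir / f"proband{i}.vcf"
        vs = list(read_vcf(vcf))
        probands[str(row.trio_id)] = pd.DataFrame(
            [(v.chrom, v.pos, v.ref, v.alt, v.depth, v.alt_reads, v.genotype) for v in vs],
            columns=["chrom", "pos", "ref", "alt", "depth", "alt_reads", "genotype"],
        )
        sexes[str(row.trio_id)] = str(row.sex)
    return SimulatedCohort(
        probands=probands,
        proband_sex=sexes,
        maternal_counts=read_counts_table(indir / "pool_maternal.counts.tsv").reset_index(),
        paternal_counts=read_counts_table(indir / "pool_paternal.counts.tsv").reset_index(),
        truth=pd.read_csv(indir / "truth.tsv", sep="\t")
        if (indir / "truth.tsv").exists() else pd.DataFrame(),
        annotations=pd.read_csv(indir / "annotations.tsv", sep="\t"),
        genes=pd.read_csv(indir / "genes.tsv", sep="\t"),
    )
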