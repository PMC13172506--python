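"""Readers and writers for the formats the workflow exchanges.

VCF 4.2 in and out (cyvcf2 for reading, pysam for writing), pool read-count
tables, annotation and gene-metadata TSVs, gene panels as one symbol per
line, and population CNV events as BED.  Coordinates are 1-based inclusive
internally (VCF convention); BED is converted at this boundary.

Multi-allelic proband records are decomposed to biallelic calls and
left-normalized against the record's own alleles (shared suffix trimmed,
then shared prefix trimmed advancing the position) — no reference genome
is required for this.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from .classify import ProbandVariant
from .prioritize import AnnotatedVariant, GeneInfo
from .cnv import CnvCall

logger = logging.getLogger("triopool")

__all__ = [
    "read_vcf",
    "write_proband_vcf",
    "read_counts_table",
    "write_counts_table",
    "read_gene_table",
    "read_annotation_table",
    "read_panel",
    "read_cnv_table",
    "read_population_events_bed",
    "write_cohort",
    "atomic_write",
]

COUNTS_COLUMNS = ("chrom", "pos", "ref", "alt", "depth", "alt_count")

_CONTIGS = tuple(f"chr{c}" for c in list(range(1, 23)) + ["X", "Y"])


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-normalize one ref/alt pair against itself.

    Trims the shared suffix, then the shared prefix (advancing ``pos``),
    always leaving at least one base on each allele.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def read_vcf(path: str | os.PathLike) -> Iterator[ProbandVariant]:
    """Stream normalized biallelic proband variants from a VCF.

    Uses the first sample.  DP is taken from FORMAT/DP when present, else
    inferred as the sum of AD; the alt read count comes from the AD entry
    of each alt allele.  Records without a called genotype are skipped
    with a warning.  Genotypes map to het / hom_alt / hemi (single-allele
    calls are hemizygous).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    try:
        for record in vcf:
            gts = record.genotypes
            if not gts:
                logger.warning("record %s:%s has no genotype; skipped", record.CHROM, record.POS)
                continue
            alleles = [a for a in gts[0][:-1] if a is not None and a >= 0]
            if not alleles:
                logger.warning("record %s:%s GT missing; skipped", record.CHROM, record.POS)
                continue
            ad = record.format("AD")
            ad_row = None if ad is None else [int(x) for x in ad[0]]
            dp_arr = record.format("DP")
            if dp_arr is not None and int(dp_arr[0][0]) >= 0:
                dp = int(dp_arr[0][0])
            elif ad_row is not None:
                dp = sum(max(x, 0) for x in ad_row)
            else:
                logger.warning("record %s:%s has neither DP nor AD; skipped", record.CHROM, record.POS)
                continue
            for alt_index in sorted({a for a in alleles if a > 0}):
                alt = record.ALT[alt_index - 1]
                alt_reads = 0
                if ad_row is not None and len(ad_row) > alt_index:
                    alt_reads = max(ad_row[alt_index], 0)
                if len(alleles) == 1:
                    genotype = "hemi"
                elif all(a == alt_index for a in alleles):
                    genotype = "hom_alt"
                else:
                    genotype = "het"
                pos, ref, alt_n = trim_alleles(record.POS, record.REF, alt)
                yield ProbandVariant(
                    chrom=record.CHROM,
                    pos=pos,
                    ref=ref,
                    alt=alt_n,
                    depth=max(dp, alt_reads),
                    alt_reads=alt_reads,
                    genotype=genotype,
                )
    finally:
        vcf.close()


def write_proband_vcf(
    variants: pd.DataFrame, path: str | os.PathLike, sample: str = "proband"
) -> None:
    """Write a single-sample VCF 4.2 with GT, DP and AD from a variant frame.

    Expects columns chrom, pos, ref, alt, depth, alt_reads, genotype.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for contig in _CONTIGS:
        header.contigs.add(contig, length=250_000_000)
    header.add_sample(sample)

    gt_map = {"het": (0, 1), "hom_alt": (1, 1), "hemi": (1,)}
    df = variants.sort_values(["chrom", "pos"], kind="stable")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in df.itertuples(index=False):
            rec = out.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos) - 1 + len(str(row.ref)),
                alleles=(str(row.ref), str(row.alt)),
            )
            depth, alt_reads = int(row.depth), int(row.alt_reads)
            rec.samples[sample]["GT"] = gt_map[str(row.genotype)]
            rec.samples[sample]["DP"] = depth
            rec.samples[sample]["AD"] = (depth - alt_reads, alt_reads)
            out.write(rec)


def read_counts_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a pool read-count table, uniquely indexed by (chrom, pos, ref, alt).

    The TSV must have the header ``chrom pos ref alt depth alt_count``.
    Duplicate sites, negative counts and alt_count > depth are rejected
    with the offending data row number (header is row 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df[list(COUNTS_COLUMNS)]
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.depth < 0 or row.alt_count < 0:
            raise ValueError(f"{path}: negative count at row {i}")
        if row.alt_count > row.depth:
            raise ValueError(f"{path}: alt_count {row.alt_count} > depth {row.depth} at row {i}")
    df["pos"] = df["pos"].astype(int)
    dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"])
    if dup.any():
        first = int(dup.idxmax()) + 2
        raise ValueError(f"{path}: duplicate site key at row {first}")
    return df.set_index(["chrom", "pos", "ref", "alt"], verify_integrity=True)


def write_counts_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(COUNTS_COLUMNS))


def read_panel(path: str | os.PathLike) -> set[str]:
    """Gene panel: one symbol per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym and not sym.startswith("#"):
            out.add(sym)
    return out


_GENE_FIELDS = ("moi", "in_panel", "domino", "pli", "pnull", "loeuf", "mis_z",
                "hi_score", "ts_score")


def read_gene_table(path: str | os.PathLike) -> dict[str, GeneInfo]:
    """Gene metadata TSV keyed by column name; 'symbol' is required, the
    score columns are optional and may hold blanks for missing values."""
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str})
    if "symbol" not in df.columns:
        raise ValueError(f"{path}: missing 'symbol' column")
    genes: dict[str, GeneInfo] = {}
    for row in df.to_dict("records"):
        kwargs = {"symbol": row["symbol"]}
        for f in _GENE_FIELDS:
            if f in row and pd.notna(row[f]):
                if f == "in_panel":
                    kwargs[f] = bool(row[f]) if not isinstance(row[f], str) else row[f].lower() in ("1", "true", "yes")
                elif f == "moi":
                    kwargs[f] = str(row[f])
                else:
                    kwargs[f] = float(row[f])
        genes[kwargs["symbol"]] = GeneInfo(**kwargs)
    return genes


_ANN_FLOATS = ("gnomad_af", "cadd", "revel", "alphamissense", "sift", "spliceai", "phylop")


def read_annotation_table(path: str | os.PathLike) -> dict[str, dict]:
    """Variant annotation TSV keyed by the variant key column ``key``.

    Returns raw per-variant dicts; :func:`join_annotations` builds
    :class:`~triopool.prioritize.AnnotatedVariant` objects from them plus
    trio evidence.
    """
    df = pd.read_csv(path, sep="\t", dtype={"key": str, "gene": str, "clinvar": str,
                                            "consequence": str})
    if "key" not in df.columns:
        raise ValueError(f"{path}: missing 'key' column")
    out: dict[str, dict] = {}
    for row in df.to_dict("records"):
        ann = {"key": row["key"]}
        ann["gene"] = str(row.get("gene", "")) if pd.notna(row.get("gene")) else ""
        ann["consequence"] = str(row["consequence"]) if pd.notna(row.get("consequence")) else "other"
        ann["clinvar"] = str(row["clinvar"]) if pd.notna(row.get("clinvar")) else "none"
        ac = row.get("gnomad_ac")
        ann["gnomad_ac"] = int(ac) if pd.notna(ac) else None
        for f in _ANN_FLOATS:
            v = row.get(f)
            ann[f] = float(v) if pd.notna(v) else None
        out[ann["key"]] = ann
    return out


def join_annotations(
    v: ProbandVariant,
    annotations: Mapping[str, dict],
    inheritance: str = "unknown",
) -> AnnotatedVariant | None:
    """Join one proband variant to its annotation row; None when unannotated."""
    ann = annotations.get(v.key)
    if ann is None:
        return None
    zygosity = {"het": "het", "hom_alt": "hom", "hemi": "hemi"}[v.genotype]
    return AnnotatedVariant(
        key=v.key,
        gene=ann["gene"],
        consequence=ann["consequence"],
        zygosity=zygosity,
        inheritance=inheritance,
        gnomad_ac=ann["gnomad_ac"],
        gnomad_af=ann["gnomad_af"],
        clinvar=ann["clinvar"],
        cadd=ann["cadd"],
        revel=ann["revel"],
        alphamissense=ann["alphamissense"],
        sift=ann["sift"],
        spliceai=ann["spliceai"],
        phylop=ann["phylop"],
    )


def read_cnv_table(
    path: str | os.PathLike, genes: Mapping[str, GeneInfo] | None = None
) -> list[CnvCall]:
    """CNV call TSV: chrom, start, end, svtype, callers (comma-separated),
    run_id, sample_id, genes (comma-separated), affects_coding,
    phenotype_match; optional run_recurrence and
    contained_in_population_event."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "svtype": str})
    genes = genes or {}
    calls: list[CnvCall] = []
    for row in df.to_dict("records"):
        symbols = [g for g in str(row.get("genes", "")).split(",") if g and g != "nan"]
        calls.append(
            CnvCall(
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                svtype=str(row["svtype"]),
                callers=frozenset(str(row["callers"]).split(",")),
                run_id=str(row.get("run_id", "")),
                sample_id=str(row.get("sample_id", "")),
                run_recurrence=int(row.get("run_recurrence", 1) or 1),
                genes={s: genes.get(s) for s in symbols},
                affects_coding=bool(row.get("affects_coding", True)),
                contained_in_population_event=bool(row.get("contained_in_population_event", False)),
                phenotype_match=bool(row.get("phenotype_match", False)),
            )
        )
    return calls


def read_population_events_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    """Benign population CNV events from BED (0-based half-open) to 1-based
    inclusive tuples ``(chrom, start, end, svtype)``; the 4th column holds
    DEL or DUP."""
    events = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}: line {lineno}: need chrom, start, end, svtype")
        chrom, start, end, svtype = parts[0], int(parts[1]), int(parts[2]), parts[3]
        events.append((chrom, start + 1, end, svtype))
    return events


def atomic_write(path: str | os.PathLike, text: str) -> None:
    """Write text via a ``.partial`` temp file so failures never leave a
    truncated output behind."""
    path = Path(path)
    tmp = path.with_name(path.name + ".partial")
    tmp.write_text(text)
    tmp.replace(path)


def write_cohort(cohort, outdir: str | os.PathLike) -> None:
    """Write a :class:`~triopool.simulate.SimulatedCohort` to a directory:
    ``probandN.vcf`` per trio, ``pool_maternal.counts.tsv`` /
    ``pool_paternal.counts.tsv``, ``truth.tsv``, ``annotations.tsv``,
    ``genes.tsv`` and ``samples.tsv`` (trio id, sex)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, (trio_id, df) in enumerate(sorted(cohort.probands.items())):
        write_proband_vcf(df, outdir / f"proband{i}.vcf", sample=trio_id)
    write_counts_table(cohort.maternal_counts, outdir / "pool_maternal.counts.tsv")
    write_counts_table(cohort.paternal_counts, outdir / "pool_paternal.counts.tsv")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cohort.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    cohort.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(cohort.proband_sex.items()), columns=["trio_id", "sex"]
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
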