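"""Synthetic trio pooled-WES data under controlled inheritance scenarios.

No patient-level sequencing data accompanies this problem domain publicly,
so every downstream stage is exercised on simulated cohorts with known
truth.  The generator emulates the study conditions directly:

* parental pools of ``pool_size`` individuals sequenced to the design
  target depth ``2 * pool_size * 20`` (Poisson-distributed per site unless
  disabled), with a carrier of ``k`` alleles producing alt reads at
  expected fraction ``k / (2 * pool_size)``;
* a symmetric per-read error converting ref reads to alt and vice versa
  (default 0.001), which stresses the 1% presence threshold;
* optional unequal sample representation in the pool ("overdispersion"),
  modelled as a symmetric Dirichlet draw over per-sample pool weights with
  concentration ``1 / overdispersion`` — the simplest model of pipetting
  variation, which the pooling technique is known to suffer from;
* probands sequenced individually at ~100x with binomial allele sampling.

Scenarios cover de novo, uniparental, biparental, compound-heterozygous
(two variants in one gene, one per parental pool), maternally inherited
hemizygous chrX in a male proband, and homozygous biallelic variants.
Per-variant annotations and gene metadata are drawn scenario-consistently
so prioritization can be tested end to end against the truth table.

All randomness flows from a single :func:`numpy.random.default_rng` seed;
outputs are bit-reproducible for a fixed seed on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import PoolObservation
from .pool_design import required_pool_depth

__all__ = [
    "SCENARIOS",
    "SimConfig",
    "SimulatedCohort",
    "simulate_pool_reads",
    "simulate_cohort",
    "simulate_singleton_validation",
    "simulate_annotated_variants",
]

SCENARIOS = (
    "de_novo",
    "maternal",
    "paternal",
    "biparental",
    "comp_het",
    "hemizygous_maternal",
    "homozygous_biallelic",
)

# de novo variants dominate the pathogenic landscape of severe sporadic
# neurodevelopmental phenotypes; recessive and X-linked mechanisms make up
# the rest.  These defaults shape the simulated cohorts accordingly.
DEFAULT_SCENARIO_MIX: dict[str, float] = {
    "de_novo": 0.40,
    "maternal": 0.15,
    "paternal": 0.15,
    "biparental": 0.10,
    "comp_het": 0.08,
    "hemizygous_maternal": 0.06,
    "homozygous_biallelic": 0.06,
}

_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
_BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    ``pool_depth`` defaults to the design target
    ``required_pool_depth(pool_size)``; ``poisson_depth`` toggles per-site
    Poisson coverage variation (on by default; turn off for exact tests).
    """

    n_trios: int = 16
    pool_size: int = 8
    pool_depth: int | None = None
    proband_depth: int = 100
    error_rate: float = 0.001
    overdispersion: float = 0.0
    scenario_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIO_MIX)
    )
    variants_per_trio: int = 8
    poisson_depth: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trios < 1 or self.pool_size < 1 or self.variants_per_trio < 1:
            raise ValueError("n_trios, pool_size and variants_per_trio must be >= 1")
        if self.pool_depth is None:
            self.pool_depth = required_pool_depth(self.pool_size)
        if self.pool_depth < 1 or self.proband_depth < 1:
            raise ValueError("depths must be >= 1")
        if not 0 <= self.error_rate <= 1:
            raise ValueError(f"error_rate must be in [0, 1], got {self.error_rate}")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        unknown = set(self.scenario_mix) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios in mix: {sorted(unknown)}")
        total = sum(self.scenario_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scenario_mix must sum to 1, got {total}")
        if any(p < 0 for p in self.scenario_mix.values()):
            raise ValueError("scenario proportions must be nonnegative")


def _pool_alt_fraction(
    k_carrier_alleles: int,
    pool_size: int,
    overdispersion: float,
    rng: np.random.Generator,
) -> float:
    """True alt-allele fraction of the pool given carrier alleles and weights."""
    if k_carrier_alleles == 0:
        return 0.0
    doses = np.zeros(pool_size)
    for j in range(k_carrier_alleles):  # spread alleles over samples, het first
        doses[j % pool_size] += 1
    if overdispersion > 0:
        weights = rng.dirichlet(np.full(pool_size, 1.0 / overdispersion))
    else:
        weights = np.full(pool_size, 1.0 / pool_size)
    return float(np.sum(weights * doses / 2.0))


def simulate_pool_reads(
    k_carriers: int,
    pool_size: int,
    depth: int,
    error_rate: float = 0.0,
    overdispersion: float = 0.0,
    rng: np.random.Generator | None = None,
    pool_id: str = "maternal",
    poisson_depth: bool = False,
) -> PoolObservation:
    """Draw read counts for one site in one parental pool.

    ``k_carriers`` counts carrier *alleles* in the pool (0 to
    ``2 * pool_size``); ``k`` heterozygous carriers give an expected alt
    fraction ``k / (2 * pool_size)``.  Sequencing error converts reads
    symmetrically between ref and alt at ``error_rate``.  With
    ``poisson_depth`` the realised depth is Poisson around ``depth``.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if not 0 <= k_carriers <= 2 * pool_size:
        raise ValueError(
            f"k_carriers must be in [0, 2 * pool_size]: k={k_carriers}, pool={pool_size}"
        )
    rng = rng if rng is not None else np.random.default_rng()
    realized = int(rng.poisson(depth)) if poisson_depth else depth
    if realized == 0:
        return PoolObservation(pool_id=pool_id, depth=0, alt_reads=0)
    p_true = _pool_alt_fraction(k_carriers, pool_size, overdispersion, rng)
    p_obs = p_true * (1.0 - error_rate) + (1.0 - p_true) * error_rate
    alt = int(rng.binomial(realized, p_obs))
    return PoolObservation(pool_id=pool_id, depth=realized, alt_reads=alt)


@dataclass
class SimulatedCohort:
    """In-memory simulated cohort; see :func:`triopool.io.write_cohort`.

    ``probands`` maps trio id to a frame with columns chrom, pos, ref, alt,
    depth, alt_reads, genotype.  Pool counts frames share the on-disk
    schema (chrom, pos, ref, alt, depth, alt_count).
    """

    probands: dict[str, pd.DataFrame]
    proband_sex: dict[str, str]
    maternal_counts: pd.DataFrame
    paternal_counts: pd.DataFrame
    truth: pd.DataFrame
    annotations: pd.DataFrame
    genes: pd.DataFrame


def _site(rng: np.random.Generator, idx: int, chrom: str | None = None) -> tuple[str, int, str, str]:
    if chrom is None:
        chrom = _AUTOSOMES[int(rng.integers(len(_AUTOSOMES)))]
    pos = 100_000 + idx * 100 + int(rng.integers(50))
    ref = _BASES[int(rng.integers(4))]
    alt = str(rng.choice([b for b in _BASES if b != ref]))
    return chrom, pos, ref, alt


# scenario -> (maternal carrier alleles, paternal carrier alleles, proband genotype)
_SCENARIO_POOL_K = {
    "de_novo": (0, 0, "het"),
    "maternal": (1, 0, "het"),
    "paternal": (0, 1, "het"),
    "biparental": (1, 1, "het"),
    "hemizygous_maternal": (1, 0, "hemi"),
    "homozygous_biallelic": (1, 1, "hom_alt"),
}

_GENOTYPE_VAF = {"het": 0.5, "hom_alt": 1.0, "hemi": 1.0}


def _proband_reads(
    genotype: str, mean_depth: int, error_rate: float, rng: np.random.Generator
) -> tuple[int, int]:
    depth = max(1, int(rng.poisson(mean_depth)))
    p = _GENOTYPE_VAF[genotype]
    p_obs = p * (1.0 - error_rate) + (1.0 - p) * error_rate
    return depth, int(rng.binomial(depth, p_obs))


def _gene_info_for_scenario(scenario: str, rng: np.random.Generator, symbol: str) -> dict:
    """Scenario-consistent gene metadata (known-panel vs candidate split)."""
    known = bool(rng.integers(2))
    info = {
        "symbol": symbol,
        "moi": "unknown",
        "in_panel": False,
        "domino": None,
        "pli": round(float(rng.uniform()), 3),
        "pnull": round(float(rng.uniform()), 3),
        "loeuf": round(float(rng.uniform(0.1, 2.0)), 3),
        "mis_z": round(float(rng.normal(0, 2)), 3),
        "hi_score": None,
        "ts_score": None,
    }
    if scenario == "de_novo":
        if known:
            info.update(moi="AD", in_panel=True)
        else:
            info.update(domino=round(float(rng.uniform(0.6, 1.0)), 2))
    elif scenario == "hemizygous_maternal":
        info.update(moi="XL", in_panel=known)
    elif scenario in ("comp_het", "homozygous_biallelic"):
        if known:
            info.update(moi="AR", in_panel=True)
        else:
            info.update(domino=round(float(rng.uniform(0.0, 0.59)), 2))
    else:  # inherited het background variants: plain rare gene
        info.update(moi=str(rng.choice(["AD", "AR"])), in_panel=False)
    return info


def _annotation_for_variant(key: str, gene: str, rng: np.random.Generator) -> dict:
    """Deleterious-leaning annotation draw for a planted scenario variant."""
    consequence = str(rng.choice(["missense", "lof", "splice_region"], p=[0.5, 0.35, 0.15]))
    ann = {
        "key": key,
        "gene": gene,
        "consequence": consequence,
        "gnomad_ac": int(rng.integers(0, 2)),
        "gnomad_af": 0.0,
        "clinvar": "none",
        "cadd": None, "revel": None, "alphamissense": None,
        "sift": None, "spliceai": None, "phylop": round(float(rng.uniform(2, 10)), 3),
    }
    if consequence == "missense":
        ann.update(
            cadd=round(float(rng.uniform(23, 35)), 1),
            revel=round(float(rng.uniform(0.6, 1.0)), 2),
            alphamissense=round(float(rng.uniform(0.65, 1.0)), 2),
            sift=0.0,
        )
    elif consequence == "splice_region":
        ann.update(spliceai=round(float(rng.uniform(0.6, 1.0)), 2))
    return ann


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Simulate a cohort of trios with pooled parents under ``config``.

    Deterministic for a fixed seed.  Scenario labels are drawn from
    ``scenario_mix`` per variant; a ``comp_het`` draw emits two variants in
    one gene, one carried only in the maternal pool and one only in the
    paternal pool; ``hemizygous_maternal`` emits a chrX variant in a male
    proband, carried by one mother and absent from the paternal pool.
    """
    rng = np.random.default_rng(config.seed)
    scenarios = list(config.scenario_mix)
    probs = np.array([config.scenario_mix[s] for s in scenarios])

    probands: dict[str, pd.DataFrame] = {}
    proband_sex: dict[str, str] = {}
    pool_rows: dict[str, list] = {"maternal": [], "paternal": []}
    truth_rows, ann_rows, gene_rows = [], [], []
    site_idx = 0
    gene_idx = 0

    for t in range(config.n_trios):
        trio_id = f"trio{t:03d}"
        drawn = [scenarios[i] for i in rng.choice(len(scenarios), size=config.variants_per_trio, p=probs)]
        sex = "male" if "hemizygous_maternal" in drawn else str(rng.choice(["male", "female"]))
        proband_sex[trio_id] = sex
        var_rows = []

        for scenario in drawn:
            gene = f"GENE{gene_idx:05d}"
            gene_idx += 1
            gene_rows.append(_gene_info_for_scenario(scenario, rng, gene))
            if scenario == "comp_het":
                plan = [("maternal", (1, 0), "het"), ("paternal", (0, 1), "het")]
            else:
                k_m, k_p, gt = _SCENARIO_POOL_K[scenario]
                plan = [(scenario, (k_m, k_p), gt)]
            chrom = "chrX" if scenario == "hemizygous_maternal" else None
            for label, (k_m, k_p), gt in plan:
                c, pos, ref, alt = _site(rng, site_idx, chrom)
                site_idx += 1
                depth, alt_reads = _proband_reads(gt, config.proband_depth, config.error_rate, rng)
                var_rows.append((c, pos, ref, alt, depth, alt_reads, gt))
                for pool, k in (("maternal", k_m), ("paternal", k_p)):
                    # a son's X never comes from the paternal pool's X alleles
                    obs = simulate_pool_reads(
                        k, config.pool_size, config.pool_depth,
                        error_rate=config.error_rate,
                        overdispersion=config.overdispersion,
                        rng=rng, pool_id=pool, poisson_depth=config.poisson_depth,
                    )
                    pool_rows[pool].append((c, pos, ref, alt, obs.depth, obs.alt_reads))
                key = f"{c}:{pos}:{ref}>{alt}"
                truth_rows.append(
                    (trio_id, key, c, pos, ref, alt, scenario, label if scenario == "comp_het" else scenario,
                     k_m, k_p, gt, gene, sex)
                )
                ann_rows.append(_annotation_for_variant(key, gene, rng))

        probands[trio_id] = pd.DataFrame(
            var_rows, columns=["chrom", "pos", "ref", "alt", "depth", "alt_reads", "genotype"]
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["trio_id", "key", "chrom", "pos", "ref", "alt", "scenario",
                 "inheritance_label", "k_maternal", "k_paternal", "genotype", "gene", "sex"],
    )
    # comp_het member labels are maternal/paternal origins; map genotype label
    truth["inheritance_label"] = truth.apply(
        lambda r: {
            "de_novo": "de_novo", "maternal": "maternal", "paternal": "paternal",
            "biparental": "biparental", "hemizygous_maternal": "maternal",
            "homozygous_biallelic": "biparental",
        }.get(r["inheritance_label"], r["inheritance_label"]),
        axis=1,
    )
    cols = ["chrom", "pos", "ref", "alt", "depth", "alt_count"]
    return SimulatedCohort(
        probands=probands,
        proband_sex=proband_sex,
        maternal_counts=pd.DataFrame(pool_rows["maternal"], columns=cols),
        paternal_counts=pd.DataFrame(pool_rows["paternal"], columns=cols),
        truth=truth,
        annotations=pd.DataFrame(ann_rows),
        genes=pd.DataFrame(gene_rows),
    )


def simulate_singleton_validation(
    n_variants: int,
    pool_size: int = 10,
    depth: int | None = None,
    error_rate: float = 0.0,
    overdispersion: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    poisson_depth: bool = True,
) -> pd.DataFrame:
    """Ultra-rare singleton variants re-observed in pooled sequencing.

    Each variant is carried heterozygously by exactly one individual in
    exactly one pool (alternating maternal/paternal), matching the
    validation design where ultra-rare variants from individually
    sequenced parents are looked up in their pool.  Returns a frame with
    columns variant_id, pool_id, pool_depth, pool_alt, pool_vaf.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if depth is None:
        depth = required_pool_depth(pool_size)
    rows = []
    for i in range(n_variants):
        pool = "maternal" if i % 2 == 0 else "paternal"
        obs = simulate_pool_reads(
            1, pool_size, depth, error_rate=error_rate,
            overdispersion=overdispersion, rng=rng, pool_id=pool,
            poisson_depth=poisson_depth,
        )
        rows.append((f"var{i:05d}", pool, obs.depth, obs.alt_reads, obs.vaf))
    return pd.DataFrame(rows, columns=["variant_id", "pool_id", "pool_depth", "pool_alt", "pool_vaf"])


def simulate_annotated_variants(
    n: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> tuple[list, dict]:
    """Random annotated variants + gene map for stress-testing prioritization.

    Unlike :func:`simulate_cohort`, draws are *not* scenario-consistent:
    consequences, zygosities, inheritance statuses, ClinVar classes, scores
    and missingness are sampled broadly (including threshold-adjacent
    values) to exercise every branch of the filtering cascade.  Returns
    ``(variants, genes)`` ready for
    :func:`triopool.prioritize.select_reportable`.
    """
    from .prioritize import AnnotatedVariant, GeneInfo

    if rng is None:
        rng = np.random.default_rng(seed)
    n_genes = max(1, n // 3)  # several variants per gene so comp-hets arise
    genes: dict[str, GeneInfo] = {}
    for gi in range(n_genes):
        sym = f"G{gi:04d}"
        genes[sym] = GeneInfo(
            symbol=sym,
            moi=str(rng.choice(["AD", "AR", "XL", "unknown"])),
            in_panel=bool(rng.integers(2)),
            domino=None if rng.uniform() < 0.3 else round(float(rng.uniform()), 2),
            pli=None if rng.uniform() < 0.3 else round(float(rng.uniform()), 2),
            pnull=None if rng.uniform() < 0.3 else round(float(rng.uniform()), 2),
            loeuf=None if rng.uniform() < 0.3 else round(float(rng.uniform(0.05, 2.0)), 2),
            mis_z=None if rng.uniform() < 0.3 else round(float(rng.normal(0, 2)), 2),
        )
    def maybe(x):
        return None if rng.uniform() < 0.25 else x
    variants = []
    for vi in range(n):
        gene = f"G{int(rng.integers(n_genes)):04d}"
        variants.append(
            AnnotatedVariant(
                key=f"chr1:{1000 + vi}:A>T",
                gene=gene,
                consequence=str(rng.choice(["missense", "lof", "synonymous", "splice_region", "other"])),
                zygosity=str(rng.choice(["het", "hom", "hemi"], p=[0.7, 0.2, 0.1])),
                inheritance=str(rng.choice(
                    ["de_novo", "maternal", "paternal", "biparental", "undetermined", "unknown"]
                )),
                gnomad_ac=maybe(int(rng.integers(0, 8))),
                gnomad_af=maybe(round(float(rng.choice([0.0, 1e-6, 5e-4, 1e-3, 0.002, 0.02])), 6)),
                clinvar=str(rng.choice(["P", "LP", "VUS", "LB", "B", "none"],
                                       p=[0.05, 0.05, 0.2, 0.1, 0.1, 0.5])),
                cadd=maybe(round(float(rng.choice([10.0, 19.9, 20.0, 20.1, 30.0])), 1)),
                revel=maybe(round(float(rng.choice([0.1, 0.5, 0.51, 0.9])), 2)),
                alphamissense=maybe(round(float(rng.choice([0.2, 0.6, 0.61, 0.95])), 2)),
                sift=maybe(round(float(rng.choice([0.0, 0.009, 0.01, 0.5])), 3)),
                spliceai=maybe(round(float(rng.choice([0.1, 0.59, 0.6, 0.61, 0.9])), 2)),
            )
        )
    return variants, genes
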