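"""Closed-form design math for pooled parental sequencing.

When parental DNA samples are combined into a single equimolar pool, a
variant carried heterozygously by one individual contributes 1 of the
``2 * n`` alleles in the pool.  Detecting it reliably therefore requires
sequencing the pool deep enough that this single allele is still covered
by a usable number of reads.  This module holds the three pieces of
arithmetic a lab needs before committing samples to a pool:

* :func:`required_pool_depth` — the mean target depth so each heterozygous
  allele is expected to receive a fixed number of reads (20 by default);
* :func:`expected_allelic_balance` — the expected variant allele fraction
  (VAF) of a heterozygous singleton in a pool of ``n`` individuals,
  ``1 / (2 n)``;
* :func:`trio_cost_reduction` — the per-trio sequencing cost saved by
  sequencing the proband individually and amortising two parental pools
  over ``pool_size`` trios each, relative to a standard trio of three
  individual exomes.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PoolSpec",
    "CostModel",
    "required_pool_depth",
    "expected_allelic_balance",
    "pooled_trio_cost",
    "trio_cost_reduction",
]


@dataclass(frozen=True)
class PoolSpec:
    """Design parameters of one parental DNA pool.

    Parameters
    ----------
    n_samples:
        Number of individuals whose DNA is combined in the pool.
    reads_per_het_allele:
        Target number of reads supporting one heterozygous allele of one
        pooled individual (default 20, the conventional per-allele
        coverage for confident detection).
    """

    n_samples: int
    reads_per_het_allele: int = 20

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.reads_per_het_allele < 1:
            raise ValueError(
                f"reads_per_het_allele must be >= 1, got {self.reads_per_het_allele}"
            )


@dataclass(frozen=True)
class CostModel:
    """Cost assumptions for the pooled trio design.

    ``pooled_multiplier`` is the cost of one pooled-WES run relative to one
    standard-WES run; the elevated target depth of a pool makes it more
    expensive than a single exome (default 1.28, i.e. +28%).  Each pool
    contains ``pool_size`` parents, so its cost amortises over that many
    trios.  ``standard_wes_unit_cost`` sets the currency unit.
    """

    pooled_multiplier: float = 1.28
    pool_size: int = 8
    standard_wes_unit_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.pooled_multiplier <= 0:
            raise ValueError(f"pooled_multiplier must be > 0, got {self.pooled_multiplier}")
        if self.pool_size < 1:
            raise ValueError(f"pool_size must be >= 1, got {self.pool_size}")
        if self.standard_wes_unit_cost <= 0:
            raise ValueError(
                f"standard_wes_unit_cost must be > 0, got {self.standard_wes_unit_cost}"
            )


def required_pool_depth(spec: PoolSpec | int, reads_per_het_allele: int = 20) -> int:
    """Mean target depth for a pool: ``n_samples * 2 * reads_per_het_allele``.

    A pool of ``n`` individuals holds ``2 n`` allele copies; covering each
    copy ``reads_per_het_allele`` times on average requires this total
    depth.  Accepts either a :class:`PoolSpec` or a bare sample count.

    The result is an exact integer target; rounding for lane planning is
    the caller's concern.

    >>> required_pool_depth(10)
    400
    """
    if not isinstance(spec, PoolSpec):
        spec = PoolSpec(int(spec), reads_per_het_allele)
    return spec.n_samples * 2 * spec.reads_per_het_allele


def expected_allelic_balance(n_samples: int) -> float:
    """Expected VAF of a heterozygous singleton in a pool: ``1 / (2 n)``.

    >>> expected_allelic_balance(10)
    0.05
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    return 1.0 / (2 * n_samples)


def pooled_trio_cost(model: CostModel = CostModel()) -> float:
    """Sequencing cost of one pooled trio, in standard-WES units.

    One proband sequenced individually plus the per-trio share of one
    maternal and one paternal pool (each pool costs
    ``pooled_multiplier`` units and serves ``pool_size`` trios).
    """
    share = model.pooled_multiplier / model.pool_size
    return model.standard_wes_unit_cost * (1.0 + 2.0 * share)


def trio_cost_reduction(model: CostModel = CostModel()) -> float:
    """Fractional cost reduction of a pooled trio vs a standard trio-WES.

    A standard trio sequences three individual exomes.  The reduction is
    ``1 - pooled_cost / 3`` and is bounded above by 2/3 for any
    multiplier >= 1: the individually sequenced proband is a cost floor.

    >>> round(trio_cost_reduction(CostModel(1.28, 8)), 4)
    0.56
    """
    standard = 3.0 * model.standard_wes_unit_cost
    return 1.0 - pooled_trio_cost(model) / standard
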