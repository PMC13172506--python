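"""Inheritance classification: QC gate, presence calls, truth table, phasing."""

import itertools

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from triopool.classify import (
    InheritanceStatus,
    PoolObservation,
    Presence,
    ProbandVariant,
    classify_inheritance,
    phase_compound_hets,
    pool_presence,
    qc_proband_variant,
    recount_pool_vaf,
)


def make_variant(chrom="chr1", genotype="het", vaf=0.5, depth=100):
    return ProbandVariant(
        chrom=chrom, pos=1000, ref="A", alt="T",
        depth=depth, alt_reads=round(vaf * depth), genotype=genotype,
    )


def obs(pool_id, alt, depth):
    return PoolObservation(pool_id=pool_id, depth=depth, alt_reads=alt)


class TestProbandQC:
    @pytest.mark.parametrize(
        "alt, dp, expected",
        [
            (6, 20, True),    # VAF 0.30, DP 20: both inclusive bounds pass
            (58, 200, False),  # VAF 0.29 below bound despite high depth
            (10, 19, False),   # VAF 0.5 but DP below bound
            (50, 100, True),
        ],
    )
    def test_inclusive_thresholds(self, alt, dp, expected):
        v = ProbandVariant("chr1", 100, "A", "T", depth=dp, alt_reads=alt)
        assert qc_proband_variant(v) is expected


class TestPoolPresence:
    def test_confirmed_de_novo_boundary_absent(self):
        # highest pool VAF ever seen for a confirmed de novo: 1/172 = 0.58%
        assert pool_presence(obs("maternal", 1, 172)) is Presence.ABSENT

    def test_documented_false_negative_mode(self):
        # 1/180 = 0.56% was below threshold yet truly inherited: the method
        # calls it absent by design
        assert pool_presence(obs("maternal", 1, 180)) is Presence.ABSENT

    def test_low_fraction_carrier_present(self):
        assert pool_presence(obs("maternal", 8, 400)) is Presence.PRESENT  # 2%

    def test_exactly_one_percent_is_present(self):
        assert pool_presence(obs("maternal", 4, 400)) is Presence.PRESENT

    def test_zero_depth_is_insufficient_not_absent(self):
        assert pool_presence(obs("maternal", 0, 0)) is Presence.INSUFFICIENT

    def test_threshold_zero_marks_any_alt_read(self):
        assert pool_presence(obs("maternal", 1, 10_000), threshold=0.0) is Presence.PRESENT
        assert pool_presence(obs("maternal", 0, 10_000), threshold=0.0) is Presence.PRESENT


class TestRecount:
    def make_table(self):
        df = pd.DataFrame(
            [("chr1", 100, "A", "T", 320, 3)],
            columns=["chrom", "pos", "ref", "alt", "depth", "alt_count"],
        )
        return df.set_index(["chrom", "pos", "ref", "alt"])

    def test_lookup_arithmetic(self):
        o = recount_pool_vaf(self.make_table(), "chr1", 100, "A", "T")
        assert o.vaf == pytest.approx(3 / 320)
        assert o.source == "recount"
        assert pool_presence(o) is Presence.ABSENT  # 0.94% < 1%

    def test_missing_site_is_insufficient(self):
        o = recount_pool_vaf(self.make_table(), "chr2", 5, "G", "C")
        assert o.depth == 0
        assert pool_presence(o) is Presence.INSUFFICIENT

    def test_duplicate_rows_error(self):
        df = pd.DataFrame(
            [("chr1", 100, "A", "T", 320, 3), ("chr1", 100, "A", "T", 300, 1)],
            columns=["chrom", "pos", "ref", "alt", "depth", "alt_count"],
        ).set_index(["chrom", "pos", "ref", "alt"])
        with pytest.raises(ValueError, match="chr1"):
            recount_pool_vaf(df, "chr1", 100, "A", "T")


# --- truth-table equivalence against a hand-enumerated oracle -------------

_PRESENCE_OBS = {
    Presence.PRESENT: lambda pid: obs(pid, 16, 400),   # 4%
    Presence.ABSENT: lambda pid: obs(pid, 1, 400),     # 0.25%
    Presence.INSUFFICIENT: lambda pid: obs(pid, 0, 0),
}


def oracle_status(mat, pat, contig, sex, genotype):
    """Independent re-derivation of the decision table, written flat."""
    if contig in ("chrY", "chrM"):
        return InheritanceStatus.UNDETERMINED
    if contig == "chrX" and sex == "unknown":
        return InheritanceStatus.UNDETERMINED
    if contig == "chrX" and sex == "male" and genotype == "hemi":
        if mat is Presence.INSUFFICIENT:
            return InheritanceStatus.UNDETERMINED
        if mat is Presence.PRESENT:
            return InheritanceStatus.MATERNAL
        return InheritanceStatus.DE_NOVO
    if mat is Presence.INSUFFICIENT or pat is Presence.INSUFFICIENT:
        return InheritanceStatus.UNDETERMINED
    if mat is Presence.PRESENT and pat is Presence.PRESENT:
        return InheritanceStatus.BIPARENTAL
    if mat is Presence.PRESENT:
        return InheritanceStatus.MATERNAL
    if pat is Presence.PRESENT:
        return InheritanceStatus.PATERNAL
    return InheritanceStatus.DE_NOVO


@pytest.mark.parametrize(
    "mat, pat, contig, sex, genotype",
    [
        (m, p, c, s, g)
        for m, p in itertools.product(Presence, Presence)
        for c in ("chr7", "chrX", "chrY", "chrM")
        for s in ("male", "female", "unknown")
        for g in ("het", "hemi", "hom_alt")
        if not (g == "hemi" and c not in ("chrX", "chrY", "chrM"))
    ],
)
def test_truth_table_total_and_matches_oracle(mat, pat, contig, sex, genotype):
    v = make_variant(chrom=contig, genotype=genotype)
    call = classify_inheritance(
        v, _PRESENCE_OBS[mat]("maternal"), _PRESENCE_OBS[pat]("paternal"), sex=sex
    )
    assert call.status == oracle_status(mat, pat, contig, sex, genotype)
    assert call.maternal_presence == mat and call.paternal_presence == pat


def test_de_novo_iff_both_absent_on_autosomes():
    for mat, pat in itertools.product(Presence, Presence):
        call = classify_inheritance(
            make_variant(), _PRESENCE_OBS[mat]("maternal"), _PRESENCE_OBS[pat]("paternal"),
            sex="female",
        )
        both_absent = mat is Presence.ABSENT and pat is Presence.ABSENT
        assert (call.status is InheritanceStatus.DE_NOVO) == both_absent


def test_hemizygous_maternal_ignores_paternal_pool():
    v = make_variant(chrom="chrX", genotype="hemi", vaf=1.0)
    call = classify_inheritance(
        v, obs("maternal", 16, 400), obs("paternal", 16, 400), sex="male"
    )
    assert call.status is InheritanceStatus.MATERNAL
    assert call.paternal_present  # recorded but unused for the status


def test_low_pool_depth_flag():
    v = make_variant()
    call = classify_inheritance(
        v, obs("maternal", 0, 100), obs("paternal", 0, 400), sex="female", pool_size=10
    )
    assert "low_pool_depth:maternal" in call.flags
    assert "low_pool_depth:paternal" not in call.flags


@given(
    mat_alt=st.integers(0, 400),
    pat_alt=st.integers(0, 400),
    t1=st.floats(0.001, 0.2),
    t2=st.floats(0.001, 0.2),
)
def test_raising_threshold_never_uncalls_de_novo(mat_alt, pat_alt, t1, t2):
    lo, hi = sorted((t1, t2))
    v = make_variant()
    m, p = obs("maternal", mat_alt, 400), obs("paternal", pat_alt, 400)
    at_lo = classify_inheritance(v, m, p, sex="female", threshold=lo)
    at_hi = classify_inheritance(v, m, p, sex="female", threshold=hi)
    if at_lo.status is InheritanceStatus.DE_NOVO:
        assert at_hi.status is InheritanceStatus.DE_NOVO


# --- compound-heterozygote phasing ----------------------------------------


def call_with(status):
    v = make_variant()
    mat = obs("maternal", 16 if status in ("maternal", "biparental") else 0, 400)
    pat = obs("paternal", 16 if status in ("paternal", "biparental") else 0, 400)
    if status == "undetermined":
        mat = obs("maternal", 0, 0)
    return v, classify_inheritance(v, mat, pat, sex="female")


def test_phasing_enumeration_matches_oracle():
    statuses = ("maternal", "paternal", "biparental", "de_novo", "undetermined")
    for s1, s2 in itertools.combinations_with_replacement(statuses, 2):
        result = phase_compound_hets([call_with(s1), call_with(s2)])
        expect_trans = {s1, s2} == {"maternal", "paternal"}
        expect_unphaseable = "biparental" in (s1, s2) or "undetermined" in (s1, s2)
        assert (len(result.in_trans) == 1) == expect_trans
        assert (len(result.unphaseable) == 1) == expect_unphaseable

def test_phasing_reasons():
    result = phase_compound_hets([call_with("maternal"), call_with("biparental")])
    assert result.unphaseable[0].reason == "carrier in both pools"
    result = phase_compound_hets([call_with("maternal"), call_with("undetermined")])
    assert result.unphaseable[0].reason == "undetermined inheritance"
    assert not phase_compound_hets([call_with("maternal"), call_with("maternal")]).in_trans
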