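"""SNV filtering cascade: frequency gate, in-silico evidence, reporting criteria."""

import itertools
from hypothesis import given
from hypothesis import strategies as st

from triopool.prioritize import (
    AnnotatedVariant,
    GeneInfo,
    candidate_gene_evidence,
    frequency_filter,
    insilico_prioritize,
    select_reportable,
)
from triopool.simulate import simulate_annotated_variants


def av(**kwargs):
    defaults = dict(key="chr1:100:A>T", gene="G1")
    defaults.update(kwargs)
    return AnnotatedVariant(**defaults)


AD_GENE = GeneInfo("G1", moi="AD", in_panel=True)
AR_GENE = GeneInfo("G1", moi="AR", in_panel=True)


class TestFrequencyFilter:
    def test_benign_dropped_even_when_absent_from_gnomad(self):
        assert not frequency_filter(av(clinvar="B", gnomad_ac=0), AD_GENE).keep
        assert not frequency_filter(av(clinvar="LB", gnomad_ac=0), AD_GENE).keep

    def test_pathogenic_kept_regardless_of_frequency(self):
        dec = frequency_filter(av(clinvar="P", gnomad_af=0.02), AR_GENE)
        assert dec.keep and dec.reason == "clinvar_pathogenic"
        assert frequency_filter(av(clinvar="LP", gnomad_ac=10_000), AD_GENE).keep

    def test_dominant_allele_count_strictly_below_five(self):
        assert frequency_filter(av(gnomad_ac=4), AD_GENE).keep
        assert not frequency_filter(av(gnomad_ac=5), AD_GENE).keep

    def test_recessive_af_below_point_one_percent(self):
        assert frequency_filter(av(gnomad_af=0.0009), AR_GENE).keep
        assert not frequency_filter(av(gnomad_af=0.001), AR_GENE).keep

    def test_missing_gnomad_treated_as_absent(self):
        assert frequency_filter(av(), AD_GENE).keep
        assert frequency_filter(av(), AR_GENE).keep
        assert frequency_filter(av(), None).keep

    @given(ac=st.integers(0, 100), lower=st.integers(0, 100))
    def test_monotone_in_allele_count(self, ac, lower):
        if lower > ac:
            ac, lower = lower, ac
        if frequency_filter(av(gnomad_ac=ac), AD_GENE).keep:
            assert frequency_filter(av(gnomad_ac=lower), AD_GENE).keep

    def test_clinvar_overrides_precede_frequency_in_any_order(self):
        # the decision is a pure function of (clinvar, ac, af, moi); assert
        # the overrides win for every frequency combination
        for ac, af in itertools.product((0, 4, 5, 100), (0.0, 0.0005, 0.01)):
            for g in (AD_GENE, AR_GENE, None):
                assert not frequency_filter(av(clinvar="B", gnomad_ac=ac, gnomad_af=af), g).keep
                assert frequency_filter(av(clinvar="P", gnomad_ac=ac, gnomad_af=af), g).keep


class TestInsilico:
    def test_unanimous_missense_prioritized_under_every_mode(self):
        # threshold-clearing profile: REVEL 0.7, CADD 26.8, AlphaMissense
        # 0.73, SIFT 0 — deleterious by all four predictors
        v = av(consequence="missense", cadd=26.8, revel=0.7, alphamissense=0.73, sift=0.0)
        for mode in ("all_of", "majority", "any_of"):
            verdict = insilico_prioritize(v, mode=mode)
            assert verdict.prioritized
            assert verdict.verdicts == {
                "cadd": True, "revel": True, "alphamissense": True, "sift": True
            }

    def test_spliceai_inclusive_at_threshold(self):
        assert insilico_prioritize(av(consequence="splice_region", spliceai=0.6)).prioritized
        assert not insilico_prioritize(av(consequence="splice_region", spliceai=0.59)).prioritized
        assert insilico_prioritize(av(consequence="synonymous", spliceai=0.8)).prioritized

    def test_lof_needs_no_missense_predictors(self):
        assert insilico_prioritize(av(consequence="lof")).prioritized

    def test_all_predictors_missing_flagged_no_evidence(self):
        verdict = insilico_prioritize(av(consequence="missense"))
        assert not verdict.prioritized
        assert "no_evidence" in verdict.flags

    def test_majority_over_available_predictors_only(self):
        # 2 of 3 available pass -> majority holds; all_of fails
        v = av(consequence="missense", cadd=30.0, revel=0.9, alphamissense=0.1)
        assert insilico_prioritize(v, mode="majority").prioritized
        assert not insilico_prioritize(v, mode="all_of").prioritized
        # 1 of 3 -> only any_of
        v = av(consequence="missense", cadd=10.0, revel=0.2, alphamissense=0.9)
        assert not insilico_prioritize(v, mode="majority").prioritized
        assert insilico_prioritize(v, mode="any_of").prioritized


class TestCandidateEvidence:
    def test_dominant_lof_candidate_profile(self):
        # haploinsufficient dominant candidate: Domino 0.9, pLI 1, absent
        # from population data
        g = GeneInfo("G", domino=0.9, pli=1.0)
        ev = candidate_gene_evidence(av(consequence="lof", gnomad_ac=0), g)
        assert {"domino_dominant", "pli_high", "gnomad_absent_or_singleton"} <= set(ev.flags)
        assert "loeuf_constrained" not in ev.flags

    def test_recessive_gene_not_flagged_dominant(self):
        g = GeneInfo("G", domino=0.22, pli=0.01)
        ev = candidate_gene_evidence(av(gnomad_ac=2), g)
        assert "domino_dominant" not in ev.flags
        assert "pli_high" not in ev.flags

    def test_all_fields_missing_empty_flags_except_gnomad(self):
        ev = candidate_gene_evidence(av(gnomad_ac=5), GeneInfo("G"))
        assert ev.count == 0


class TestSelectReportable:
    def test_de_novo_in_known_dominant_gene(self):
        calls = select_reportable(
            [av(inheritance="de_novo")], {"G1": AD_GENE}
        )
        assert len(calls) == 1
        assert calls[0].criterion == "denovo_AD_XL" and calls[0].tier == "known_gene"

    def test_de_novo_candidate_dominant_by_domino(self):
        g = GeneInfo("G1", domino=0.9, pli=1.0)
        calls = select_reportable([av(inheritance="de_novo", consequence="lof")], {"G1": g})
        assert calls[0].criterion == "denovo_candidate_dominant"
        assert calls[0].tier == "candidate_gene"

    def test_hemizygous_xl_maternal(self):
        g = GeneInfo("G1", moi="XL", in_panel=True)
        calls = select_reportable(
            [av(zygosity="hemi", inheritance="maternal")], {"G1": g}
        )
        assert calls[0].criterion == "hemizygous_XL" and calls[0].tier == "known_gene"

    def test_homozygous_lof_in_likely_recessive_candidate(self):
        g = GeneInfo("G1", domino=0.22, pli=0.01)
        calls = select_reportable(
            [av(zygosity="hom", consequence="lof", inheritance="biparental")], {"G1": g}
        )
        assert calls[0].criterion == "biallelic_candidate_recessive"

    def test_comp_het_pair_requires_in_trans(self):
        vs = [
            av(key="k1", zygosity="het", inheritance="maternal"),
            av(key="k2", zygosity="het", inheritance="paternal"),
        ]
        calls = select_reportable(vs, {"G1": AR_GENE})
        pair_calls = [c for c in calls if len(c.variants) == 2]
        assert len(pair_calls) == 1 and pair_calls[0].criterion == "biallelic_AR"
        # same-parent variants never pair
        vs_cis = [
            av(key="k1", zygosity="het", inheritance="maternal"),
            av(key="k2", zygosity="het", inheritance="maternal"),
        ]
        assert not select_reportable(vs_cis, {"G1": AR_GENE})

    def test_unknown_moi_hom_surfaces_with_flag(self):
        calls = select_reportable([av(zygosity="hom")], {"G1": GeneInfo("G1")})
        assert calls[0].criterion == "biallelic_candidate_recessive"
        assert "no_moi_evidence" in calls[0].flags


# --- independent row-by-row oracle over simulated annotated variants -------


def oracle_calls(variants, genes):
    """Straight-line re-derivation of the three reporting criteria."""
    out = []
    for v in variants:
        g = genes.get(v.gene)
        if v.inheritance == "de_novo" and g and g.in_panel and g.moi in ("AD", "XL"):
            out.append((("single", v.key), "denovo_AD_XL", "known_gene"))
            continue
        if v.inheritance == "de_novo" and g and g.domino is not None and g.domino >= 0.6:
            out.append((("single", v.key), "denovo_candidate_dominant", "candidate_gene"))
            continue
        if v.zygosity == "hemi" and g and g.moi == "XL":
            tier = "known_gene" if g.in_panel else "candidate_gene"
            out.append((("single", v.key), "hemizygous_XL", tier))
            continue
        if v.zygosity == "hom":
            if g and g.in_panel and g.moi == "AR":
                out.append((("single", v.key), "biallelic_AR", "known_gene"))
            elif g and g.domino is not None and g.domino < 0.6:
                out.append((("single", v.key), "biallelic_candidate_recessive", "candidate_gene"))
            elif g is None or (g.domino is None and g.moi == "unknown"):
                out.append((("single", v.key), "biallelic_candidate_recessive", "candidate_gene"))
    by_gene = {}
    for v in variants:
        by_gene.setdefault(v.gene, []).append(v)
    for gene, vs in by_gene.items():
        g = genes.get(gene)
        if g and g.in_panel and g.moi == "AR":
            crit, tier = "biallelic_AR", "known_gene"
        elif g and g.domino is not None and g.domino < 0.6:
            crit, tier = "biallelic_candidate_recessive", "candidate_gene"
        elif g is None or (g.domino is None and g.moi == "unknown"):
            crit, tier = "biallelic_candidate_recessive", "candidate_gene"
        else:
            continue
        for vm in vs:
            for vp in vs:
                if vm.zygosity == vp.zygosity == "het" and vm.inheritance == "maternal" and vp.inheritance == "paternal":
                    out.append((("pair", vm.key, vp.key), crit, tier))
    return sorted(out)


def test_reporting_criteria_match_oracle_on_simulated_variants():
    variants, genes = simulate_annotated_variants(1000, seed=77)
    calls = select_reportable(variants, genes)
    got = sorted(
        (
            (("single", c.variants[0].key) if len(c.variants) == 1
             else ("pair", c.variants[0].key, c.variants[1].key)),
            c.criterion,
            c.tier,
        )
        for c in calls
    )
    assert got == oracle_calls(variants, genes)
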