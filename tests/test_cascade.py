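import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hapfunnel.cascade import (
    CascadeConfig,
    Genotype,
    VariantRecord,
    cosegregates,
    egene_overlap,
    het_in_associated_parent,
    in_casummit,
    methylation_evidence,
    polymorphic_in_children,
    rare_annotation,
    run_cascade,
    set_overlap_test,
)
from hapfunnel.qtl import QTLFit, QTLResult
from hapfunnel.summits import MasterSummitList, SummitRegion

PAT = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 1]
MAT = [1, 0, 0, 1, 1, 0, 1, 0, 1, 0, 0]


def _variant(chrom, pos, fh, mh, family, pat=PAT, mat=MAT, phased=True):
    """Family variant from parental block-haplotype alleles (paternal|maternal)."""
    gts = {"FATHER": Genotype(fh[0], fh[1], True), "MOTHER": Genotype(mh[0], mh[1], True)}
    for g in ("GF_P", "GM_P", "GF_M", "GM_M"):
        gts[g] = Genotype(0, 0)
    for c, p, m in zip(family.children, pat, mat):
        gts[c] = Genotype(fh[p], mh[m], phased)
    return VariantRecord(chrom, pos, "A", ("G",), gts)


def _qtl(trait_id, block_id, parent="paternal", significant=True):
    fit = QTLFit(0.0, 1.0, 0.1, 0.2, 0.2, 1e-6, 1e-6, 0.5, 11, [])
    return QTLResult(trait_id, block_id, fit, fdr=0.001 if significant else 0.9,
                     is_significant=significant, associated_parent=parent)


@pytest.fixture
def casummits():
    return MasterSummitList(
        [SummitRegion("chr1", 750, 1250, 1000, 10.0, "s1")]
    )


class TestPredicates:
    def test_polymorphic(self, family):
        het_some = _variant("chr1", 10, (0, 1), (0, 0), family)
        assert polymorphic_in_children(het_some, family)
        all_het = _variant("chr1", 10, (0, 1), (1, 0), family,
                           pat=[0] * 11, mat=[0] * 11)
        assert not polymorphic_in_children(all_het, family)  # every child 0/1

    def test_polymorphic_random_matches_distinct_count_oracle(self, family, rng):
        for _ in range(30):
            fh, mh = rng.integers(0, 2, 2), rng.integers(0, 2, 2)
            v = _variant("chr1", 10, tuple(fh), tuple(mh), family)
            gts = {tuple(sorted((v.genotypes[c].a1, v.genotypes[c].a2)))
                   for c in family.children}
            assert polymorphic_in_children(v, family) == (len(gts) >= 2)

    def test_all_missing_warns_false(self, family):
        v = VariantRecord("chr1", 10, "A", ("G",),
                          {c: Genotype(None, None) for c in family.children})
        with pytest.warns(UserWarning):
            assert not polymorphic_in_children(v, family)

    def test_in_casummit_halfopen(self, family, casummits):
        inside = _variant("chr1", 1000, (0, 1), (0, 0), family)
        at_end = _variant("chr1", 1250, (0, 1), (0, 0), family)
        outside = _variant("chr2", 1000, (0, 1), (0, 0), family)
        assert in_casummit(inside, casummits) == "s1"
        assert in_casummit(at_end, casummits) is None
        assert in_casummit(outside, casummits) is None

    def test_in_casummit_matches_allpairs_oracle(self, family, rng):
        regions = [SummitRegion("chr1", s, s + 500, s + 250, 1.0, f"r{i}")
                   for i, s in enumerate(range(0, 50_000, 2000))]
        ml = MasterSummitList(regions)
        for pos in rng.integers(0, 52_000, size=50):
            v = _variant("chr1", int(pos), (0, 1), (0, 0), family)
            expected = next((r.region_id for r in regions
                             if r.start <= pos < r.end), None)
            assert in_casummit(v, ml) == expected

    def test_overlapping_casummits_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            MasterSummitList([
                SummitRegion("chr1", 0, 500, 250, 1.0, "a"),
                SummitRegion("chr1", 400, 900, 650, 2.0, "b"),
            ])

    def test_het_in_associated_parent(self, family):
        qtl_p = _qtl("s1", "blk1", "paternal")
        father_het = _variant("chr1", 10, (0, 1), (0, 0), family)
        mother_het = _variant("chr1", 10, (1, 1), (0, 1), family)
        assert het_in_associated_parent(father_het, qtl_p, family)
        assert not het_in_associated_parent(mother_het, qtl_p, family)
        qtl_b = _qtl("s1", "blk1", "both")
        assert het_in_associated_parent(mother_het, qtl_b, family)


class TestCosegregation:
    def test_perfect_segregation(self, family, informative_tx):
        v = _variant("chr1", 10, (0, 1), (0, 0), family)
        assert cosegregates(v, informative_tx, _qtl("s1", "blk1"), family)

    def test_single_discordant_child_fails(self, family, informative_tx):
        v = _variant("chr1", 10, (0, 1), (0, 0), family)
        child = family.children[1]  # inherits paternal hap 1 -> allele 1
        v.genotypes[child] = Genotype(0, 0, True)  # carries allele 0 instead
        assert not cosegregates(v, informative_tx, _qtl("s1", "blk1"), family)

    def test_variant_on_other_parents_haplotype_fails(self, family, informative_tx):
        """A SNP carried on the maternal haplotype cannot explain a paternal
        accessibility association."""
        v = _variant("chr1", 10, (0, 0), (0, 1), family)
        assert not cosegregates(v, informative_tx, _qtl("s1", "blk1", "paternal"), family)
        assert cosegregates(v, informative_tx, _qtl("s1", "blk1", "maternal"), family)

    def test_unphased_mendelian_deduction(self, family, informative_tx):
        """With the other parent homozygous, allele of origin is deducible
        without phase."""
        v = _variant("chr1", 10, (0, 1), (0, 0), family, phased=False)
        assert cosegregates(v, informative_tx, _qtl("s1", "blk1"), family)

    def test_double_het_unphased_indeterminate(self, family, informative_tx):
        v = _variant("chr1", 10, (0, 1), (0, 1), family, phased=False)
        # 9 of 11 children are unphased double-het trios -> >50% skipped,
        # indeterminate False even though the variant rides the haplotype
        assert not cosegregates(v, informative_tx, _qtl("s1", "blk1"), family)

    def test_simulation_planted_vs_permuted_control(self, family, informative_tx, rng):
        """The planted variant always co-segregates; shuffling child genotypes
        breaks co-segregation in nearly all draws."""
        hits = 0
        n = 60
        for _ in range(n):
            v = _variant("chr1", 10, (0, 1), (0, 0), family)
            assert cosegregates(v, informative_tx, _qtl("s1", "blk1"), family)
            perm = rng.permutation(11)
            shuffled = [v.genotypes[family.children[i]] for i in perm]
            for c, g in zip(family.children, shuffled):
                v.genotypes[c] = g
            hits += cosegregates(v, informative_tx, _qtl("s1", "blk1"), family)
        assert hits / n <= 0.05


class TestAnnotationStages:
    def test_methylation_evidence_membership(self, rng):
        region = SummitRegion("chr1", 750, 1250, 1000, 1.0, "s1")
        assert methylation_evidence(region, {("chr1", 900)})
        assert not methylation_evidence(region, {("chr1", 1250), ("chr2", 900)})
        for _ in range(20):
            cpgs = {("chr1", int(p)) for p in rng.integers(0, 2000, size=10)}
            naive = any(750 <= p < 1250 for c, p in cpgs if c == "chr1")
            assert methylation_evidence(region, cpgs) == naive

    def test_egene_overlap(self):
        egenes = [_qtl("geneA", "blk1"), _qtl("geneB", "blk2", significant=False)]
        assert egene_overlap("blk1", egenes) == (True, False)
        assert egene_overlap("blk2", egenes) == (False, False)
        assert egene_overlap("blk1", egenes, {"geneA"}) == (True, True)

    def test_rare_annotation(self, family):
        v = _variant("chr1", 10, (0, 1), (0, 0), family)
        table = pd.DataFrame(
            {"AFR": [0.01, 0.01], "EUR": [0.03, 0.30], "EAS": [0.04, 0.01]},
            index=[v.key, "chr1:999:A:G"],
        )
        assert rare_annotation(v, table)[0] is True
        other = _variant("chr1", 998, (0, 1), (0, 0), family)
        assert rare_annotation(other, table)[0] is False
        absent = _variant("chr1", 5, (0, 1), (0, 0), family)
        assert rare_annotation(absent, table) == (None, None)


class TestRunCascade:
    def _setup(self, family, informative_tx, rng, n_variants=100):
        region = SummitRegion("chr1", 750, 1250, 1000, 10.0, "s1")
        casummits = MasterSummitList([region])
        qtls = [_qtl("s1", "blk1", "paternal")]
        egenes = [_qtl("geneA", "blk1")]
        inter = {("chr1", 900)}
        variants = [_variant("chr1", 2000 + 10 * i,
                             tuple(rng.integers(0, 2, 2)), tuple(rng.integers(0, 2, 2)),
                             family)
                    for i in range(n_variants - 5)]
        # a handful inside the caSummit, including the fully-concordant one
        variants += [
            _variant("chr1", 1000, (0, 1), (0, 0), family),   # true candidate
            _variant("chr1", 1010, (0, 0), (0, 1), family),   # maternal-borne SNP
            _variant("chr1", 1020, (1, 1), (1, 1), family),   # monomorphic
            _variant("chr1", 1030, (0, 1), (1, 0), family),   # candidate too
            _variant("chr1", 1240, (0, 1), (0, 0), family),   # inside, concordant
        ]
        return variants, casummits, qtls, inter, egenes

    def test_matches_independent_predicate_conjunction(self, family, informative_tx, rng):
        variants, casummits, qtls, inter, egenes = self._setup(family, informative_tx, rng)
        cands, report = run_cascade(variants, casummits, qtls, informative_tx,
                                    family, inter, egenes)
        expected = []
        for v in variants:
            sid = in_casummit(v, casummits)
            ok = (
                polymorphic_in_children(v, family)
                and sid is not None
                and het_in_associated_parent(v, qtls[0], family)
                and cosegregates(v, informative_tx, qtls[0], family)
                and methylation_evidence(casummits.regions[0], inter)
                and egene_overlap("blk1", egenes)[0]
            )
            if ok:
                expected.append(v.key)
        assert [c.variant.key for c in cands] == expected
        assert "chr1:1001:A:G" in expected  # the planted candidate survives
        surv = [s for _, _, s in report.stages]
        ent = [e for _, e, _ in report.stages]
        assert all(s <= e for s, e in zip(surv, ent))
        assert surv == sorted(surv, reverse=True)
        assert surv[-1] == len(cands)

    def test_disabling_a_stage_gives_superset(self, family, informative_tx, rng):
        variants, casummits, qtls, inter, egenes = self._setup(family, informative_tx, rng)
        full, _ = run_cascade(variants, casummits, qtls, informative_tx, family,
                              inter, egenes)
        no_meth, _ = run_cascade(variants, casummits, qtls, informative_tx, family,
                                 set(), egenes,
                                 config=CascadeConfig(require_methylation=False))
        assert {c.variant.key for c in full} <= {c.variant.key for c in no_meth}

    def test_replicated_stage_configurable(self, family, informative_tx, rng):
        variants, casummits, qtls, inter, egenes = self._setup(family, informative_tx, rng)
        cfg = CascadeConfig(require_replicated=True)
        with_repl, rep = run_cascade(variants, casummits, qtls, informative_tx, family,
                                     inter, egenes, replicated_egenes={"geneA"},
                                     config=cfg)
        without, _ = run_cascade(variants, casummits, qtls, informative_tx, family,
                                 inter, egenes, replicated_egenes=set(), config=cfg)
        assert len(with_repl) > 0
        assert without == []
        assert rep.stages[-1][0] == "replicated_egene"

    def test_zero_variants(self, family, informative_tx):
        region = SummitRegion("chr1", 750, 1250, 1000, 10.0, "s1")
        cands, report = run_cascade([], MasterSummitList([region]),
                                    [_qtl("s1", "blk1")], informative_tx, family,
                                    set(), [])
        assert cands == []
        assert all(e == 0 and s == 0 for _, e, s in report.stages)

    def test_audit_ledger_covers_all_variants(self, family, informative_tx, rng):
        variants, casummits, qtls, inter, egenes = self._setup(family, informative_tx, rng,
                                                               n_variants=20)
        _, report = run_cascade(variants, casummits, qtls, informative_tx, family,
                                inter, egenes)
        assert len(report.ledger) == len(variants)
        for entry in report.ledger:
            assert "polymorphic_in_children" in entry.evidence


class TestSetOverlap:
    def test_closed_form_hypergeometric_tail(self):
        a, b = set(range(1, 11)), set(range(6, 16))
        k, odds, p = set_overlap_test(a, b, 100)
        assert k == 5
        assert p == pytest.approx(stats.hypergeom.sf(4, 100, 10, 10))

    def test_disjoint_sets(self):
        _, _, p = set_overlap_test(set(range(10)), set(range(20, 30)), 1000)
        assert p > 0.99

    def test_identical_sets_minimal_p(self):
        k, _, p = set_overlap_test(set(range(10)), set(range(10)), 100)
        assert k == 10
        assert p == pytest.approx(stats.hypergeom.sf(9, 100, 10, 10))
        assert p < 1e-12

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            set_overlap_test(set(range(10)), set(range(10, 20)), 15)
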