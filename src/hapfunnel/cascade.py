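"""The multi-omic variant-prioritization funnel.

Starting from the family's variants, a cascade of pure predicates nominates
candidate *multifunctional* variants — variants with concordant evidence
across chromatin accessibility, gene expression, DNA methylation, and
co-segregation with the informative parental haplotype:

1. polymorphic among the children;
2. located within a significant accessibility summit (caSummit) region;
3. heterozygous in the parent whose haplotype drives the caSummit;
4. co-segregating: the allele each child received from that parent is
   determined by which of the parent's two block haplotypes was transmitted;
5. an intermediate-methylation CpG lies within the caSummit region;
6. the haplotype block also carries a significant eGene (optionally one
   replicated in an external study).

Survivors are annotated as rare when their minor allele frequency is below
0.05 in every reference population. Each stage's entering/surviving counts
form the funnel report; in audit mode every flag is evaluated for every
variant regardless of earlier failures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree, TransmissionTable
from .qtl import QTLResult
from .summits import MasterSummitList, SummitRegion

__all__ = [
    "Genotype",
    "VariantRecord",
    "CandidateVariant",
    "FunnelReport",
    "CascadeConfig",
    "read_vcf",
    "read_maf_table",
    "polymorphic_in_children",
    "in_casummit",
    "het_in_associated_parent",
    "cosegregates",
    "methylation_evidence",
    "egene_overlap",
    "rare_annotation",
    "run_cascade",
    "set_overlap_test",
    "candidates_to_frame",
    "write_evidence_json",
]

STAGE_ORDER = [
    "polymorphic_in_children",
    "in_casummit",
    "het_in_associated_parent",
    "cosegregates",
    "intermediate_methylation",
    "egene_overlap",
    "replicated_egene",
]


@dataclass(frozen=True)
class Genotype:
    """An allele pair (indices into ref+alts). When ``phased`` the order is
    paternal|maternal. ``None`` alleles denote missing calls."""

    a1: int | None
    a2: int | None
    phased: bool = False

    @property
    def missing(self) -> bool:
        return self.a1 is None or self.a2 is None

    @property
    def het(self) -> bool:
        return bool(not self.missing and self.a1 != self.a2)

    def alleles(self) -> tuple[int, ...]:
        return tuple(a for a in (self.a1, self.a2) if a is not None)

    def unordered(self) -> tuple[int, ...] | None:
        return None if self.missing else tuple(sorted((self.a1, self.a2)))


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, Genotype]

    @property
    def key(self) -> str:
        """1-based variant key chrom:pos:ref:alt, matching the MAF table."""
        return f"{self.chrom}:{self.pos + 1}:{self.ref}:{','.join(self.alts)}"

    def n_alleles(self) -> int:
        return 1 + len(self.alts)


@dataclass
class CandidateVariant:
    variant: VariantRecord
    block_id: str | None = None
    casummit_id: str | None = None
    evidence: dict[str, bool | None] = field(default_factory=dict)
    maf_by_population: dict[str, float] | None = None
    is_rare: bool | None = None

    def passes(self, required: list[str]) -> bool:
        return all(self.evidence.get(stage) is True for stage in required)


@dataclass
class FunnelReport:
    stages: list[tuple[str, int, int]]  # (name, entering, surviving)
    #: per-variant evidence ledger (every variant, every evaluated flag)
    ledger: list["CandidateVariant"] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (_, ent, surv) in self.stages:
            if surv > ent:
                raise ValueError("funnel survivors exceed entrants")
        for (_, _, s_prev), (_, e_next, _) in zip(self.stages, self.stages[1:]):
            if e_next != s_prev:
                raise ValueError("funnel stages are not chained")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "entering", "surviving"])


@dataclass
class CascadeConfig:
    require_methylation: bool = True
    require_egene: bool = True
    require_replicated: bool = False
    maf_threshold: float = 0.05
    audit: bool = True  # evaluate every flag even after a stage fails
    max_skip_fraction: float = 0.5  # co-segregation indeterminacy cap

    def required_stages(self) -> list[str]:
        req = STAGE_ORDER[:4]
        if self.require_methylation:
            req.append("intermediate_methylation")
        if self.require_egene:
            req.append("egene_overlap")
        if self.require_replicated:
            req.append("replicated_egene")
        return req


# ---------------------------------------------------------------------------
# stage predicates
# ---------------------------------------------------------------------------

def polymorphic_in_children(v: VariantRecord, ped: Pedigree) -> bool:
    """True iff at least two distinct (unordered) genotypes occur among children."""
    gts = [v.genotypes.get(c, Genotype(None, None)).unordered() for c in ped.children]
    seen = {g for g in gts if g is not None}
    if not seen:
        warnings.warn(f"{v.key}: no child genotypes; treated as non-polymorphic")
        return False
    return len(seen) >= 2


def in_casummit(v: VariantRecord, casummits: MasterSummitList) -> str | None:
    """Id of the caSummit region whose half-open interval contains the variant."""
    region = casummits.locate(v.chrom, v.pos)
    return region.region_id if region is not None else None


def het_in_associated_parent(v: VariantRecord, qtl: QTLResult, ped: Pedigree) -> bool:
    """True iff the parent whose haplotype drives the QTL is heterozygous
    (either parent suffices when the association is 'both')."""
    if qtl.associated_parent not in ("paternal", "maternal", "both"):
        raise ValueError(f"QTL for {qtl.trait_id} has no associated parent")
    father, mother = ped.parents_of(ped.children[0])
    parents = {"paternal": [father], "maternal": [mother], "both": [father, mother]}[
        qtl.associated_parent
    ]
    ok = False
    for p in parents:
        gt = v.genotypes.get(p)
        if gt is None or gt.missing:
            warnings.warn(f"{v.key}: missing genotype for parent {p}")
            continue
        ok = ok or gt.het
    return ok


def _allele_from_parent(
    v: VariantRecord, child: str, parent: str, other_parent: str, parent_is_father: bool
) -> int | None:
    """Allele the child received from ``parent``; None when unresolvable.

    Phased child genotypes are taken as paternal|maternal. Otherwise the
    origin is deduced by Mendelian elimination against the other parent's
    genotype; a double-het trio with an unphased het child is ambiguous.
    """
    gt = v.genotypes.get(child)
    if gt is None or gt.missing:
        return None
    if gt.phased:
        return gt.a1 if parent_is_father else gt.a2
    if gt.a1 == gt.a2:
        return gt.a1
    pgt = v.genotypes.get(parent)
    ogt = v.genotypes.get(other_parent)
    if pgt is None or pgt.missing or ogt is None or ogt.missing:
        return None
    candidates = {
        a
        for (a, b) in ((gt.a1, gt.a2), (gt.a2, gt.a1))
        if a in pgt.alleles() and b in ogt.alleles()
    }
    return candidates.pop() if len(candidates) == 1 else None


def cosegregates(
    v: VariantRecord,
    tx: TransmissionTable,
    qtl: QTLResult,
    ped: Pedigree,
    max_skip_fraction: float = 0.5,
) -> bool:
    """True iff the allele each child received from the associated parent is
    perfectly determined by that parent's transmitted block haplotype.

    For a 'both' association the paternal side is tested first and the
    maternal side accepted as an alternative. Children whose allele of
    origin cannot be resolved are skipped; if more than
    ``max_skip_fraction`` of children are skipped the call is indeterminate
    (False).
    """
    sides = {"paternal": [0], "maternal": [1], "both": [0, 1]}[qtl.associated_parent]
    for side in sides:
        if _cosegregates_one_parent(v, tx, qtl.block_id, ped, side, max_skip_fraction):
            return True
    return False


def _cosegregates_one_parent(
    v: VariantRecord,
    tx: TransmissionTable,
    block_id: str,
    ped: Pedigree,
    side: int,
    max_skip_fraction: float,
) -> bool:
    by_hap: dict[int, set[int]] = {}
    n_total = n_skipped = 0
    for child in ped.children:
        alleles = tx.get(child, block_id)
        if alleles is None:
            continue
        n_total += 1
        father, mother = ped.parents_of(child)
        parent, other = (father, mother) if side == 0 else (mother, father)
        got = _allele_from_parent(v, child, parent, other, parent_is_father=(side == 0))
        if got is None:
            n_skipped += 1
            continue
        by_hap.setdefault(alleles[side], set()).add(got)
    if n_total == 0 or n_skipped > max_skip_fraction * n_total:
        return False
    if any(len(s) > 1 for s in by_hap.values()):
        return False  # same transmitted haplotype, different alleles
    if len(by_hap) == 2:
        (s0, s1) = by_hap.values()
        return s0 != s1  # the variant must distinguish the two haplotypes
    return len(by_hap) == 1  # degenerate: only one haplotype observed


def methylation_evidence(
    region: SummitRegion, intermediate_set: set[tuple[str, int]]
) -> bool:
    """True iff >= 1 intermediate-methylation CpG lies within the region."""
    return any(
        chrom == region.chrom and region.start <= pos < region.end
        for chrom, pos in intermediate_set
    )


def egene_overlap(
    block_id: str,
    egenes: list[QTLResult],
    replicated_set: set[str] | None = None,
) -> tuple[bool, bool]:
    """(block carries a significant eGene, that eGene is externally replicated)."""
    hits = [r for r in egenes if r.is_significant and r.block_id == block_id]
    has = bool(hits)
    replicated = bool(replicated_set) and any(r.trait_id in replicated_set for r in hits)
    return has, replicated


def rare_annotation(
    v: VariantRecord, maf_table: pd.DataFrame, threshold: float = 0.05
) -> tuple[bool | None, dict[str, float] | None]:
    """is_rare iff MAF < threshold in *every* population; None when absent."""
    if v.key not in maf_table.index:
        return None, None
    mafs = maf_table.loc[v.key].astype(float).to_dict()
    return all(m < threshold for m in mafs.values()), mafs


# ---------------------------------------------------------------------------
# the funnel
# ---------------------------------------------------------------------------

def run_cascade(
    variants: list[VariantRecord],
    casummit_regions: MasterSummitList,
    summit_qtls: list[QTLResult],
    tx: TransmissionTable,
    ped: Pedigree,
    intermediate_set: set[tuple[str, int]],
    egene_qtls: list[QTLResult],
    maf_table: pd.DataFrame | None = None,
    replicated_egenes: set[str] | None = None,
    config: CascadeConfig | None = None,
) -> tuple[list[CandidateVariant], FunnelReport]:
    """Apply the funnel stages in order and report per-stage survivor counts.

    ``casummit_regions`` must contain only the regions of *significant*
    caSummits, with region ids matching ``summit_qtls`` trait ids. The stage
    predicates are pure, so disabling a stage can only enlarge the survivor
    set and reordering cannot change it.
    """
    config = config or CascadeConfig()
    qtl_by_summit = {r.trait_id: r for r in summit_qtls if r.is_significant}
    missing = [r.region_id for r in casummit_regions.regions if r.region_id not in qtl_by_summit]
    if missing:
        raise ValueError(f"caSummit regions without a significant QTL: {missing[:5]}")
    region_by_id = {r.region_id: r for r in casummit_regions.regions}

    ledger: list[CandidateVariant] = []
    for v in variants:
        cand = CandidateVariant(variant=v)
        alive = True

        def stage(name: str, fn) -> None:
            nonlocal alive
            if alive or config.audit:
                try:
                    result = fn()
                    cand.evidence[name] = None if result is None else bool(result)
                except ValueError:
                    cand.evidence[name] = None
            else:
                cand.evidence[name] = None
            if cand.evidence[name] is not True and name in required:
                alive = False

        required = config.required_stages()
        stage("polymorphic_in_children", lambda: polymorphic_in_children(v, ped))

        summit_id = in_casummit(v, casummit_regions)
        cand.casummit_id = summit_id
        cand.evidence["in_casummit"] = summit_id is not None
        if summit_id is None:
            alive = False
            for name in STAGE_ORDER[2:]:
                cand.evidence[name] = None  # downstream stages need the caSummit
            ledger.append(cand)
            continue
        qtl = qtl_by_summit[summit_id]
        cand.block_id = qtl.block_id

        stage("het_in_associated_parent", lambda: het_in_associated_parent(v, qtl, ped))
        stage("cosegregates",
              lambda: cosegregates(v, tx, qtl, ped, config.max_skip_fraction))
        stage("intermediate_methylation",
              lambda: methylation_evidence(region_by_id[summit_id], intermediate_set))
        has_eg, repl = egene_overlap(qtl.block_id, egene_qtls, replicated_egenes)
        stage("egene_overlap", lambda: has_eg)
        stage("replicated_egene", lambda: repl)

        if maf_table is not None and cand.passes(required):
            cand.is_rare, cand.maf_by_population = rare_annotation(
                v, maf_table, config.maf_threshold
            )
        ledger.append(cand)

    required = config.required_stages()
    stages = []
    alive_set = list(ledger)
    entering = len(alive_set)
    for name in STAGE_ORDER:
        if name not in required:
            continue
        alive_set = [c for c in alive_set if c.evidence.get(name) is True]
        stages.append((name, entering, len(alive_set)))
        entering = len(alive_set)
    report = FunnelReport(stages, ledger=ledger)
    candidates = [c for c in ledger if c.passes(required)]
    return candidates, report


def set_overlap_test(
    hits_a: set, hits_b: set, universe_size: int
) -> tuple[int, float, float]:
    """Fisher's exact (hypergeometric upper-tail) test of set overlap.

    Returns (overlap count, sample odds ratio, one-sided p). The 2x2 table is
    [[|A∩B|, |A\\B|], [|B\\A|, |U\\(A∪B)|]].
    """
    union = hits_a | hits_b
    if universe_size < len(union):
        raise ValueError("universe smaller than the union of the two sets")
    k = len(hits_a & hits_b)
    a_only = len(hits_a) - k
    b_only = len(hits_b) - k
    neither = universe_size - len(union)
    odds, p = stats.fisher_exact([[k, a_only], [b_only, neither]], alternative="greater")
    return k, float(odds), float(p)


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def read_vcf(path, samples: list[str] | None = None) -> list[VariantRecord]:
    """Read family variants from a (plain-text or indexed) VCF via pysam.

    Phased genotypes are preserved; the paternal|maternal allele order of
    phased child genotypes is assumed (Platinum-genomes convention, and what
    the synthetic generator writes).
    """
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        take = samples or list(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            gts = {}
            for s in take:
                sample = rec.samples[s]
                al = sample["GT"]
                if al is None or len(al) != 2:
                    gts[s] = Genotype(None, None)
                else:
                    gts[s] = Genotype(al[0], al[1], phased=sample.phased)
            out.append(
                VariantRecord(rec.chrom, rec.start, rec.ref, tuple(rec.alts or ()), gts)
            )
    return out


def read_maf_table(path) -> pd.DataFrame:
    """MAF TSV: a ``variant`` key column (chrom:pos1:ref:alt) + one column per
    population."""
    df = pd.read_csv(path, sep="\t")
    if "variant" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected a 'variant' column plus population columns")
    return df.set_index("variant")


def candidates_to_frame(cands: list[CandidateVariant]) -> pd.DataFrame:
    rows = []
    for c in cands:
        row = {
            "variant": c.variant.key,
            "chrom": c.variant.chrom,
            "pos": c.variant.pos,
            "ref": c.variant.ref,
            "alt": ",".join(c.variant.alts),
            "block_id": c.block_id,
            "casummit_id": c.casummit_id,
            "is_rare": c.is_rare,
        }
        for name in STAGE_ORDER:
            row[name] = c.evidence.get(name)
        rows.append(row)
    return pd.DataFrame(rows)


def write_evidence_json(cands: list[CandidateVariant], path) -> None:
    payload = [
        {
            "variant": c.variant.key,
            "block_id": c.block_id,
            "casummit_id": c.casummit_id,
            "evidence": c.evidence,
            "maf_by_population": c.maf_by_population,
            "is_rare": c.is_rare,
        }
        for c in cands
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
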