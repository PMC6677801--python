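"""Synthetic three-generation study generator with a ground-truth ledger.

Generates a complete, file-compatible synthetic study — pedigree, haplotype
blocks, Mendelian block transmission, phased family variants, ATAC-seq
summit/peak/read files, gene and miRNA count matrices, per-strand CpG
methylation counts, allelic read bases, and a population MAF table — from a
single seed, so every pipeline stage can be exercised end-to-end without
external data.

The generative model mirrors the study design it emulates:

* a 17-member CEPH-style family (4 grandparents, 2 parents, 11 children);
* haplotype blocks transmitted as units, each parent passing one of their
  two block haplotypes to each child by a fair coin flip (no within-block
  recombination);
* negative-binomial count traits whose log2 means carry planted paternal /
  maternal haplotype effects plus batch and EBV-quartile covariate effects
  (variance = mu + mu^2 / dispersion);
* beta-binomial CpG methylation — background CpGs near fully methylated or
  unmethylated, CpGs in a planted accessible region intermediate in
  children carrying one active and one inactive allele;
* binomially sampled allelic reads at the planted heterozygous site, biased
  toward the active allele.

One seeded generator drives everything through named substreams, so adding
a component cannot perturb the draws of earlier ones, and identical seeds
give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import Genotype, VariantRecord
from .pedigree import (
    CovariateTable,
    HaplotypeBlock,
    Pedigree,
    PedigreeMember,
    TransmissionTable,
)
from .methylation import CpGMatrix

__all__ = ["PlantedEffect", "TruthConfig", "TruthLedger", "StudyData",
           "simulate_study", "write_study", "worked_example", "nb_draw"]

_STREAMS = [
    "transmission", "haplotypes", "positions", "summits", "reads",
    "genes", "mirnas", "methylation", "allelic", "maf", "covariates",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A haplotype effect planted on one trait in one block.

    Betas are log2 fold-changes on the count mean per transmitted allele
    label (allele 1 relative to allele 0).
    """

    block_index: int
    trait_class: str  # gene | mirna | summit
    beta_paternal: float = 0.0
    beta_maternal: float = 0.0


@dataclass
class TruthConfig:
    """Study conditions for the generator; defaults emulate the real design."""

    n_children: int = 11
    n_blocks: int = 6
    variants_per_block: int = 20
    n_genes: int = 240
    n_mirnas: int = 60
    summits_per_block: int = 30
    planted: list[PlantedEffect] = field(default_factory=lambda: [
        PlantedEffect(0, "summit", beta_paternal=2.0),
        PlantedEffect(0, "gene", beta_paternal=2.0),
        PlantedEffect(0, "mirna", beta_paternal=2.0),
    ])
    #: plant one multifunctional variant in the first planted-summit block
    plant_variant: bool = True
    #: keep background variants out of planted summit regions so the planted
    #: truth is uniquely identifiable
    avoid_planted_summits: bool = True
    nb_mean: dict = field(default_factory=lambda: {"gene": 200.0, "mirna": 100.0, "summit": 100.0})
    nb_dispersion: dict = field(default_factory=lambda: {"gene": 20.0, "mirna": 20.0, "summit": 20.0})
    #: planted traits start from a scaled-down baseline so their fold-change
    #: stays a small share of the library, as one locus is in real data
    planted_baseline_scale: float = 0.2
    batch_effect: float = 0.3  # log2 shift for the second batch
    ebv_slope: float = 0.1  # log2 per EBV quartile
    meth_background: tuple = ((25.0, 2.0), (2.0, 25.0))  # beta params, high/low
    meth_intermediate: tuple = (20.0, 20.0)
    meth_coverage_mean: float = 15.0  # per strand
    allelic_depth: int = 30
    allelic_bias: float = 0.9  # P(read from the active allele)
    maf_populations: tuple = ("AFR", "AMR", "EAS", "EUR", "SAS")
    allele_freq: float = 0.3  # founder haplotype alt-allele frequency
    block_span: int = 100_000
    block_gap: int = 100_000
    chrom: str = "chr1"
    seed: int = 0
    #: optional explicit (paternal, maternal) transmission vectors per block
    fixed_transmission: dict | None = None

    def validate(self) -> None:
        if self.n_children < 3:
            raise ValueError("n_children must be >= 3")
        for d in self.nb_dispersion.values():
            if d <= 0:
                raise ValueError("dispersions must be > 0")
        for pe in self.planted:
            if not 0 <= pe.block_index < self.n_blocks:
                raise ValueError(f"planted effect references nonexistent block {pe.block_index}")


@dataclass
class TruthLedger:
    """Ground truth: planted effects and the expected funnel evidence."""

    seed: int
    planted_effects: list[dict]
    planted_variants: list[dict]

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "planted_effects": self.planted_effects,
             "planted_variants": self.planted_variants},
            indent=2, sort_keys=True,
        ) + "\n"


@dataclass
class StudyData:
    """Everything the pipeline consumes, in memory."""

    cfg: TruthConfig
    ped: Pedigree
    blocks: list[HaplotypeBlock]
    tx: TransmissionTable
    cov: CovariateTable
    per_replicate_summits: dict  # replicate -> list[SummitCall]
    master_peaks: list[tuple[str, int, int]]
    per_child_peaks: dict  # child -> list of intervals
    atac_reads: dict  # child -> list[(chrom, pos, strand)]
    gene_counts: pd.DataFrame
    gene_anno: pd.DataFrame
    mirna_counts: pd.DataFrame
    mirna_anno: pd.DataFrame
    meth_plus: CpGMatrix
    meth_minus: CpGMatrix
    variants: list[VariantRecord]
    maf_table: pd.DataFrame
    allelic_bases: pd.DataFrame
    truth: TruthLedger


def nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    """Negative binomial with variance mu + mu^2 / dispersion (gamma-Poisson)."""
    mean = np.asarray(mean, float)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=size)
    return rng.poisson(lam)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _make_pedigree(n_children: int) -> Pedigree:
    members = [
        PedigreeMember("GF_P", None, None, 1),
        PedigreeMember("GM_P", None, None, 1),
        PedigreeMember("GF_M", None, None, 1),
        PedigreeMember("GM_M", None, None, 1),
        PedigreeMember("FATHER", "GF_P", "GM_P", 2),
        PedigreeMember("MOTHER", "GF_M", "GM_M", 2),
    ]
    members += [
        PedigreeMember(f"C{i + 1:02d}", "FATHER", "MOTHER", 3) for i in range(n_children)
    ]
    return Pedigree(members)


def _trait_mean(cfg: TruthConfig, trait_class: str, beta_p: float, beta_m: float,
                p: np.ndarray, m: np.ndarray, batch: np.ndarray, ebv: np.ndarray,
                planted: bool = False) -> np.ndarray:
    base = np.log2(cfg.nb_mean[trait_class] * (cfg.planted_baseline_scale if planted else 1.0))
    log2_mu = (base + beta_p * p + beta_m * m
               + cfg.batch_effect * batch + cfg.ebv_slope * (ebv - 2.5))
    return np.exp2(log2_mu)


def simulate_study(cfg: TruthConfig, outdir: str | Path | None = None
                   ) -> tuple[StudyData, TruthLedger]:
    """Generate a synthetic study; optionally write all input files to ``outdir``."""
    cfg.validate()
    rngs = _streams(cfg.seed)
    ped = _make_pedigree(cfg.n_children)
    children = ped.children
    n = len(children)
    chrom = cfg.chrom

    # --- blocks -----------------------------------------------------------
    blocks = []
    for b in range(cfg.n_blocks):
        start = b * (cfg.block_span + cfg.block_gap)
        blocks.append(HaplotypeBlock(f"block_{b:02d}", chrom, start, start + cfg.block_span))

    # --- transmission: fair Bernoulli per child x block x parent ----------
    rt = rngs["transmission"]
    tx_entries = {}
    pat = {}
    mat = {}
    for blk in blocks:
        if cfg.fixed_transmission and blk.block_id in cfg.fixed_transmission:
            p_vec, m_vec = (np.asarray(v) for v in cfg.fixed_transmission[blk.block_id])
        else:
            p_vec = rt.integers(0, 2, size=n)
            m_vec = rt.integers(0, 2, size=n)
        pat[blk.block_id], mat[blk.block_id] = p_vec, m_vec
        for c, pv, mv in zip(children, p_vec, m_vec):
            tx_entries[(c, blk.block_id)] = (int(pv), int(mv))
    tx = TransmissionTable(tx_entries)

    # --- covariates -------------------------------------------------------
    rc = rngs["covariates"]
    batch_labels = np.array(["A", "B"])[np.arange(n) % 2]
    ebv_q = (np.arange(n) % 4) + 1
    perm = rc.permutation(n)
    cov_df = pd.DataFrame(
        {"batch": batch_labels[perm], "ebv_quartile": ebv_q[perm]},
        index=pd.Index(children, name="child"),
    )
    cov = CovariateTable(cov_df)
    batch_num = (cov_df["batch"] == "B").to_numpy(float)
    ebv_num = cov_df["ebv_quartile"].to_numpy(float)

    planted_by_class: dict[str, list[PlantedEffect]] = {}
    for pe in cfg.planted:
        planted_by_class.setdefault(pe.trait_class, []).append(pe)

    # --- summits, peaks, reads -------------------------------------------
    from .summits import SummitCall

    rs = rngs["summits"]
    summit_positions: list[tuple[str, int]] = []  # (block_id, summit_pos)
    planted_summit_pos: dict[int, int] = {}
    for bi, blk in enumerate(blocks):
        offsets = np.sort(rs.choice(
            np.arange(1000, cfg.block_span - 1000, 700), size=cfg.summits_per_block,
            replace=False,
        ))
        for j, off in enumerate(offsets):
            pos = blk.start + int(off)
            summit_positions.append((blk.block_id, pos))
            if j == cfg.summits_per_block // 2:
                planted_summit_pos[bi] = pos

    per_replicate_summits = {}
    for rep in ("rep1", "rep2"):
        calls = []
        for _, pos in summit_positions:
            jitter = int(rs.integers(-20, 21))
            calls.append(SummitCall(chrom, pos + jitter, float(rs.uniform(5, 50)), rep))
        per_replicate_summits[rep] = calls
    master_peaks = [(chrom, pos - 400, pos + 400) for _, pos in summit_positions]
    per_child_peaks = {
        c: [(chrom, pos - 300, pos + 300) for _, pos in summit_positions]
        for c in children
    }

    # per-summit read counts with planted effects on planted summits
    rr = rngs["reads"]
    planted_summits = {pe.block_index: pe for pe in planted_by_class.get("summit", [])}
    atac_reads: dict[str, list[tuple[str, int, str]]] = {c: [] for c in children}
    block_index = {blk.block_id: i for i, blk in enumerate(blocks)}
    for block_id, pos in summit_positions:
        bi = block_index[block_id]
        pe = planted_summits.get(bi)
        is_planted = pe is not None and pos == planted_summit_pos.get(bi)
        bp, bm = (pe.beta_paternal, pe.beta_maternal) if is_planted else (0.0, 0.0)
        mu = _trait_mean(cfg, "summit", bp, bm, pat[block_id], mat[block_id],
                         batch_num, ebv_num, planted=is_planted)
        counts = nb_draw(rr, mu, cfg.nb_dispersion["summit"])
        for c, k in zip(children, counts):
            offs = rr.integers(-240, 240, size=int(k))
            strands = np.array(["+", "-"])[rr.integers(0, 2, size=int(k))]
            atac_reads[c].extend((chrom, pos + int(o), s) for o, s in zip(offs, strands))

    # --- gene and miRNA counts -------------------------------------------
    def _count_matrix(trait_class: str, n_traits: int, prefix: str,
                      rng: np.random.Generator):
        planted = {pe.block_index: pe for pe in planted_by_class.get(trait_class, [])}
        ids, rows, anno = [], [], []
        per_block = max(1, n_traits // cfg.n_blocks)
        ti = 0
        for bi, blk in enumerate(blocks):
            for j in range(per_block):
                tid = f"{prefix}{ti:04d}"
                ti += 1
                tss = blk.start + 2000 + j * 997
                pe = planted.get(bi) if j == 0 else None
                bp = pe.beta_paternal if pe else 0.0
                bm = pe.beta_maternal if pe else 0.0
                mu = _trait_mean(cfg, trait_class, bp, bm, pat[blk.block_id],
                                 mat[blk.block_id], batch_num, ebv_num,
                                 planted=pe is not None)
                rows.append(nb_draw(rng, mu, cfg.nb_dispersion[trait_class]))
                ids.append(tid)
                anno.append((chrom, tss, tss + 200))
                if pe:
                    truth_effects.append(
                        {"trait_id": tid, "block_id": blk.block_id,
                         "trait_class": trait_class,
                         "beta_paternal": bp, "beta_maternal": bm}
                    )
        counts = pd.DataFrame(np.array(rows), index=pd.Index(ids, name="trait_id"),
                              columns=children)
        anno = pd.DataFrame(anno, index=counts.index, columns=["chrom", "start", "end"])
        return counts, anno

    truth_effects: list[dict] = []
    rg = rngs["genes"]
    gene_counts, gene_anno = _count_matrix("gene", cfg.n_genes, "gene", rg)
    # decoys exercising the expression filters: sex/EBV-chromosome genes and
    # a low-count gene
    extra = pd.DataFrame(
        nb_draw(rg, np.full((3, n), 50.0), 20.0),
        index=pd.Index(["geneX", "geneEBV", "geneLow"], name="trait_id"), columns=children,
    )
    extra.loc["geneLow"] = nb_draw(rg, np.full(n, 3.0), 20.0)
    gene_counts = pd.concat([gene_counts, extra])
    gene_anno = pd.concat([
        gene_anno,
        pd.DataFrame(
            [("chrX", 1000, 1200), ("EBV", 1000, 1200), (chrom, blocks[0].start + 50, blocks[0].start + 250)],
            index=extra.index, columns=["chrom", "start", "end"],
        ),
    ])

    rm = rngs["mirnas"]
    mirna_counts, mirna_anno = _count_matrix("mirna", cfg.n_mirnas, "mir", rm)
    low = pd.DataFrame(
        nb_draw(rm, np.full((2, n), 2.0), 20.0),
        index=pd.Index(["mirLow1", "mirLow2"], name="trait_id"), columns=children,
    )
    mirna_counts = pd.concat([mirna_counts, low])
    mirna_anno = pd.concat([
        mirna_anno,
        pd.DataFrame([(chrom, 100, 300), (chrom, 400, 600)], index=low.index,
                     columns=["chrom", "start", "end"]),
    ])

    # add a trait-class-wide summit record for the truth ledger
    for bi, pe in planted_summits.items():
        truth_effects.append(
            {"trait_id": f"summit@{chrom}:{planted_summit_pos[bi]}",
             "block_id": blocks[bi].block_id, "trait_class": "summit",
             "beta_paternal": pe.beta_paternal, "beta_maternal": pe.beta_maternal}
        )

    # --- variants and haplotypes -----------------------------------------
    rh, rp = rngs["haplotypes"], rngs["positions"]
    variants: list[VariantRecord] = []
    planted_variant_truth: list[dict] = []
    planted_regions = [
        (blocks[bi].block_id, planted_summit_pos[bi] - 260, planted_summit_pos[bi] + 260)
        for bi in planted_summits
    ]
    for blk in blocks:
        k = cfg.variants_per_block
        lo, hi = blk.start, blk.end
        pos_pool = rp.choice(np.arange(lo, hi), size=4 * k, replace=False)
        if cfg.avoid_planted_summits:
            bad = [(s, e) for b, s, e in planted_regions if b == blk.block_id]
            pos_pool = [p for p in pos_pool if not any(s <= p < e for s, e in bad)]
        positions = sorted(int(p) for p in list(pos_pool)[:k])
        planted_here = (
            cfg.plant_variant
            and planted_summits
            and blk.block_id == blocks[min(planted_summits)].block_id
        )
        for i, pos in enumerate(positions):
            fh = rh.integers(0, 2, size=2)  # father hap0/hap1 alleles
            mh = rh.integers(0, 2, size=2)
            variants.append(_make_variant(chrom, pos, fh, mh, ped, pat[blk.block_id],
                                          mat[blk.block_id]))
        if planted_here:
            bi = min(planted_summits)
            pv_pos = planted_summit_pos[bi] + 10  # inside the summit region
            pe = planted_summits[bi]
            # heterozygous in the associated parent; the alt allele rides the
            # higher-accessibility haplotype (label 1 when beta > 0)
            if abs(pe.beta_paternal) >= abs(pe.beta_maternal):
                fh, mh = np.array([0, 1]), np.array([0, 0])
                assoc = "paternal"
            else:
                fh, mh = np.array([0, 0]), np.array([0, 1])
                assoc = "maternal"
            pv = _make_variant(chrom, pv_pos, fh, mh, ped, pat[blk.block_id],
                               mat[blk.block_id])
            variants.append(pv)
            planted_variant_truth.append(
                {
                    "variant": pv.key,
                    "block_id": blk.block_id,
                    "summit_pos": planted_summit_pos[bi],
                    "associated_parent": assoc,
                    "expected_evidence": {
                        "polymorphic_in_children": True,
                        "in_casummit": True,
                        "het_in_associated_parent": True,
                        "cosegregates": True,
                        "intermediate_methylation": True,
                        "egene_overlap": bool(planted_by_class.get("gene")),
                    },
                    "is_rare": True,
                }
            )
    variants.sort(key=lambda v: (v.chrom, v.pos))

    # --- methylation ------------------------------------------------------
    rme = rngs["methylation"]
    cpg_rows = []  # (pos, true fraction per child)
    for block_id, pos in summit_positions:
        bi = block_index[block_id]
        in_planted = bi in planted_summits and pos == planted_summit_pos.get(bi)
        for cpg_off in (-40, 5, 60):
            cpg_pos = pos + cpg_off
            if in_planted:
                pe = planted_summits[bi]
                carrier = (pat if abs(pe.beta_paternal) >= abs(pe.beta_maternal) else mat)[
                    block_id] == 1
                a_bg, b_bg = cfg.meth_background[0]
                a_int, b_int = cfg.meth_intermediate
                frac = np.where(
                    carrier,
                    rme.beta(a_int, b_int, size=n),
                    rme.beta(a_bg, b_bg, size=n),
                )
            else:
                a, b = cfg.meth_background[int(rme.integers(0, 2))]
                frac = rme.beta(a, b, size=n)
            cpg_rows.append((cpg_pos, frac))
    cpg_rows.sort(key=lambda t: t[0])
    plus_meth, plus_unmeth, minus_meth, minus_unmeth = [], [], [], []
    idx_plus, idx_minus = [], []
    for cpg_pos, frac in cpg_rows:
        for strand_idx, (meths, unmeths, idx, p) in enumerate(
            ((plus_meth, plus_unmeth, idx_plus, cpg_pos),
             (minus_meth, minus_unmeth, idx_minus, cpg_pos + 1))
        ):
            cov_reads = nb_draw(rme, np.full(n, cfg.meth_coverage_mean), 10.0)
            m = rme.binomial(cov_reads, frac)
            meths.append(m)
            unmeths.append(cov_reads - m)
            idx.append((chrom, p))
    meth_plus = CpGMatrix(
        pd.DataFrame(np.array(plus_meth), index=pd.MultiIndex.from_tuples(idx_plus, names=["chrom", "pos"]), columns=children),
        pd.DataFrame(np.array(plus_unmeth), index=pd.MultiIndex.from_tuples(idx_plus, names=["chrom", "pos"]), columns=children),
    )
    meth_minus = CpGMatrix(
        pd.DataFrame(np.array(minus_meth), index=pd.MultiIndex.from_tuples(idx_minus, names=["chrom", "pos"]), columns=children),
        pd.DataFrame(np.array(minus_unmeth), index=pd.MultiIndex.from_tuples(idx_minus, names=["chrom", "pos"]), columns=children),
    )

    # --- allelic reads at the planted het site ---------------------------
    ra = rngs["allelic"]
    allelic_rows = []
    for pvt in planted_variant_truth:
        chrom_v, pos1, ref, alt = pvt["variant"].split(":")
        pos0 = int(pos1) - 1
        carrier_children = [
            c for c in children
            if tx.get(c, pvt["block_id"])[0 if pvt["associated_parent"] == "paternal" else 1] == 1
        ]
        for c in carrier_children:
            n_active = ra.binomial(cfg.allelic_depth, cfg.allelic_bias)
            for _ in range(n_active):
                allelic_rows.append((chrom_v, pos0, ref, alt, c, alt, int(ra.integers(25, 40))))
            for _ in range(cfg.allelic_depth - n_active):
                allelic_rows.append((chrom_v, pos0, ref, alt, c, ref, int(ra.integers(25, 40))))
    allelic_bases = pd.DataFrame(
        allelic_rows,
        columns=["chrom", "pos", "ref_allele", "alt_allele", "sample", "base", "baseq"],
    )

    # --- MAF table --------------------------------------------------------
    rmaf = rngs["maf"]
    planted_keys = {p["variant"] for p in planted_variant_truth}
    maf_rows = []
    for v in variants:
        if v.key in planted_keys:
            mafs = rmaf.uniform(0.001, 0.045, size=len(cfg.maf_populations))
        else:
            mafs = rmaf.uniform(0.0, 0.5, size=len(cfg.maf_populations))
        maf_rows.append([v.key] + [round(float(x), 5) for x in mafs])
    maf_table = pd.DataFrame(
        maf_rows, columns=["variant", *cfg.maf_populations]
    ).set_index("variant")

    truth = TruthLedger(seed=cfg.seed, planted_effects=truth_effects,
                        planted_variants=planted_variant_truth)
    study = StudyData(
        cfg=cfg, ped=ped, blocks=blocks, tx=tx, cov=cov,
        per_replicate_summits=per_replicate_summits, master_peaks=master_peaks,
        per_child_peaks=per_child_peaks, atac_reads=atac_reads,
        gene_counts=gene_counts, gene_anno=gene_anno,
        mirna_counts=mirna_counts, mirna_anno=mirna_anno,
        meth_plus=meth_plus, meth_minus=meth_minus,
        variants=variants, maf_table=maf_table, allelic_bases=allelic_bases,
        truth=truth,
    )
    if outdir is not None:
        write_study(study, outdir)
    return study, truth


def _make_variant(chrom, pos, fh, mh, ped: Pedigree, p_vec, m_vec) -> VariantRecord:
    """Assemble a biallelic variant from parental block-haplotype alleles.

    Children are phased paternal|maternal; parents carry (hap0, hap1);
    grandparents are consistent unphased donors of the parental haplotypes.
    """
    gts = {
        "FATHER": Genotype(int(fh[0]), int(fh[1]), phased=True),
        "MOTHER": Genotype(int(mh[0]), int(mh[1]), phased=True),
        "GF_P": Genotype(int(fh[0]), int(fh[0])),
        "GM_P": Genotype(int(fh[1]), int(fh[1])),
        "GF_M": Genotype(int(mh[0]), int(mh[0])),
        "GM_M": Genotype(int(mh[1]), int(mh[1])),
    }
    for c, pv, mv in zip(ped.children, p_vec, m_vec):
        gts[c] = Genotype(int(fh[pv]), int(mh[mv]), phased=True)
    return VariantRecord(chrom, int(pos), "A", ("G",), gts)


# ---------------------------------------------------------------------------
# file emission — every format the pipeline reads
# ---------------------------------------------------------------------------

def write_study(study: StudyData, outdir: str | Path) -> dict[str, Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ped_rows = [
        {"sample_id": m.sample_id, "father": m.father or ".",
         "mother": m.mother or ".", "generation": m.generation}
        for m in study.ped.members
    ]
    paths["pedigree"] = out / "pedigree.tsv"
    pd.DataFrame(ped_rows).to_csv(paths["pedigree"], sep="\t", index=False)

    paths["blocks"] = out / "blocks.tsv"
    pd.DataFrame(
        [{"block_id": b.block_id, "chrom": b.chrom, "start": b.start, "end": b.end}
         for b in study.blocks]
    ).to_csv(paths["blocks"], sep="\t", index=False)

    paths["transmission"] = out / "transmission.tsv"
    pd.DataFrame(
        [{"child": c, "block": b, "paternal_allele": p, "maternal_allele": m}
         for (c, b), (p, m) in sorted(study.tx.items())]
    ).to_csv(paths["transmission"], sep="\t", index=False)

    paths["covariates"] = out / "covariates.tsv"
    study.cov.table.reset_index().to_csv(paths["covariates"], sep="\t", index=False)

    for rep, calls in study.per_replicate_summits.items():
        p = out / f"summits_{rep}.bed"
        paths[f"summits_{rep}"] = p
        with open(p, "w") as fh:
            for i, c in enumerate(sorted(calls, key=lambda s: (s.chrom, s.summit_pos))):
                fh.write(f"{c.chrom}\t{c.summit_pos}\t{c.summit_pos + 1}\t{rep}_s{i}\t{c.pileup:.3f}\n")

    paths["master_peaks"] = out / "master_peaks.bed"
    with open(paths["master_peaks"], "w") as fh:
        for chrom, s, e in sorted(study.master_peaks):
            fh.write(f"{chrom}\t{s}\t{e}\n")

    for child, peaks in study.per_child_peaks.items():
        p = out / f"peaks_{child}.narrowPeak"
        paths[f"peaks_{child}"] = p
        with open(p, "w") as fh:
            for i, (chrom, s, e) in enumerate(sorted(peaks)):
                summit_off = (e - s) // 2
                fh.write(f"{chrom}\t{s}\t{e}\tpk{i}\t100\t.\t10.0\t5.0\t3.0\t{summit_off}\n")

    paths["atac_reads"] = out / "atac_reads.tsv"
    rows = []
    for child in study.ped.children:
        for chrom, pos, strand in study.atac_reads[child]:
            rows.append((child, chrom, pos, strand))
    pd.DataFrame(rows, columns=["child", "chrom", "pos", "strand"]).to_csv(
        paths["atac_reads"], sep="\t", index=False
    )

    paths["gene_counts"] = out / "gene_counts.tsv"
    study.gene_counts.to_csv(paths["gene_counts"], sep="\t")
    paths["gene_annotations"] = out / "gene_annotations.tsv"
    study.gene_anno.to_csv(paths["gene_annotations"], sep="\t")
    paths["mirna_counts"] = out / "mirna_counts.tsv"
    study.mirna_counts.to_csv(paths["mirna_counts"], sep="\t")
    paths["mirna_annotations"] = out / "mirna_annotations.tsv"
    study.mirna_anno.to_csv(paths["mirna_annotations"], sep="\t")

    from .methylation import write_methylation_tsv

    paths["methylation"] = out / "methylation.tsv"
    write_methylation_tsv(study.meth_plus, study.meth_minus, paths["methylation"])

    paths["vcf"] = out / "variants.vcf"
    _write_vcf(study, paths["vcf"])

    paths["maf"] = out / "maf.tsv"
    study.maf_table.reset_index().to_csv(paths["maf"], sep="\t", index=False)

    paths["allelic_bases"] = out / "allelic_bases.tsv"
    study.allelic_bases.to_csv(paths["allelic_bases"], sep="\t", index=False)

    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        fh.write(study.truth.to_json())
    return paths


def _write_vcf(study: StudyData, path: Path) -> None:
    samples = [m.sample_id for m in study.ped.members]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({v.chrom for v in study.variants})
        for chrom in chroms:
            length = max(v.pos for v in study.variants if v.chrom == chrom) + 10_000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in study.variants:
            gt_strs = []
            for s in samples:
                g = v.genotypes.get(s, Genotype(None, None))
                if g.missing:
                    gt_strs.append("./.")
                else:
                    sep = "|" if g.phased else "/"
                    gt_strs.append(f"{g.a1}{sep}{g.a2}")
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{','.join(v.alts)}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt_strs) + "\n"
            )


# ---------------------------------------------------------------------------
# worked example — a fixed, hand-checkable miniature study
# ---------------------------------------------------------------------------

WORKED_EXAMPLE_SEED = 20190601
#: fixed transmissions for the single block: both parents informative
_WE_PATERNAL = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 1]
_WE_MATERNAL = [1, 0, 0, 1, 1, 0, 1, 0, 1, 0, 0]


def worked_example(outdir: str | Path | None = None) -> tuple[StudyData, TruthLedger]:
    """A fixed miniature study: 1 block, ~20 variants, 11 children, one
    planted multifunctional variant, deterministic transmissions.

    Designed so the planted variant is the unique cascade survivor and the
    planted summit the sole caSummit; expected outputs are enumerable by
    hand from the written files.
    """
    cfg = TruthConfig(
        n_blocks=1,
        variants_per_block=19,  # + 1 planted = 20 total
        n_genes=120,
        n_mirnas=12,
        summits_per_block=30,
        planted=[
            PlantedEffect(0, "summit", beta_paternal=2.5),
            PlantedEffect(0, "gene", beta_paternal=2.5),
        ],
        nb_dispersion={"gene": 80.0, "mirna": 80.0, "summit": 80.0},
        seed=WORKED_EXAMPLE_SEED,
        fixed_transmission={"block_00": (_WE_PATERNAL, _WE_MATERNAL)},
    )
    return simulate_study(cfg, outdir)
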