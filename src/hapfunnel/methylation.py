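"""WGBS CpG filtering and intermediate-methylation detection.

A CpG covered on both strands has its methylated/unmethylated counts summed
across strands. Per child, a CpG is masked when coverage is below 10 reads
or strictly above that child's 99.9th coverage percentile (a PCR-artifact
guard; the percentile is computed on raw coverage, so the two masks commute).
A CpG is called *intermediate* — consistent with one active and one silenced
allele — when at least three unmasked children have methylation fraction in
the closed interval [0.25, 0.75].

Data layout: a ``CpGMatrix`` holds two aligned DataFrames (methylated and
unmethylated counts), indexed by (chrom, pos) with one column per child.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CpGMatrix",
    "merge_strands",
    "coverage_filter",
    "intermediate_cpgs",
    "haplotype_group_means",
    "read_methylation_tsv",
    "write_methylation_tsv",
    "write_bedgraph",
]

MIN_COVERAGE = 10
TOP_PERCENTILE = 99.9
INTERMEDIATE_LOW = 0.25
INTERMEDIATE_HIGH = 0.75


@dataclass
class CpGMatrix:
    """Methylated / unmethylated read counts per CpG per child.

    Index is a (chrom, pos) MultiIndex; pos is the 0-based position of the
    plus-strand C after strand merging. ``mask`` marks per-child values
    excluded by the coverage filters (True = masked).
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    mask: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index) or list(self.meth.columns) != list(
            self.unmeth.columns
        ):
            raise ValueError("meth and unmeth matrices must align")
        if (self.meth.to_numpy() < 0).any() or (self.unmeth.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def children(self) -> list[str]:
        return list(self.meth.columns)

    def coverage(self) -> pd.DataFrame:
        return self.meth + self.unmeth

    def fractions(self) -> pd.DataFrame:
        """Methylation fraction; NaN where coverage is zero or masked."""
        cov = self.coverage()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.meth / cov
        frac = frac.where(cov > 0)
        if self.mask is not None:
            frac = frac.where(~self.mask)
        return frac


def merge_strands(plus: CpGMatrix, minus: CpGMatrix) -> CpGMatrix:
    """Sum counts across strands per CpG per child.

    The minus-strand C of a CpG sits one base 3' of the plus-strand C, so a
    minus record at pos maps to the plus record at pos - 1. Minus records
    without a plus partner are kept as their own CpGs (at pos - 1) with a
    warning.
    """
    shifted = pd.MultiIndex.from_arrays(
        [minus.meth.index.get_level_values(0),
         minus.meth.index.get_level_values(1) - 1],
        names=["chrom", "pos"],
    )
    minus_meth = minus.meth.set_axis(shifted)
    minus_unmeth = minus.unmeth.set_axis(shifted)
    orphans = shifted.difference(plus.meth.index)
    if len(orphans):
        warnings.warn(f"{len(orphans)} minus-strand CpG records without a plus partner")
    meth = plus.meth.add(minus_meth, fill_value=0).astype(int)
    unmeth = plus.unmeth.add(minus_unmeth, fill_value=0).astype(int)
    meth = meth.sort_index()
    unmeth = unmeth.sort_index()
    return CpGMatrix(meth, unmeth)


def coverage_filter(
    cpgs: CpGMatrix,
    min_cov: int = MIN_COVERAGE,
    top_percentile: float = TOP_PERCENTILE,
) -> CpGMatrix:
    """Mask per-child values with coverage < ``min_cov`` or strictly above the
    child's ``top_percentile`` coverage percentile.

    The percentile is taken per child over that child's covered CpGs (raw
    coverage, before the minimum-coverage mask), and the cut is exclusive:
    only coverage strictly above the percentile value is masked, so a flat
    coverage distribution masks nothing.
    """
    cov = cpgs.coverage()
    mask = cov < min_cov
    for child in cpgs.children:
        c = cov[child]
        covered = c[c > 0]
        if len(covered):
            thr = np.percentile(covered, top_percentile)
            mask[child] = mask[child] | (c > thr)
    return CpGMatrix(cpgs.meth, cpgs.unmeth, mask=mask)


def intermediate_cpgs(
    cpgs: CpGMatrix,
    low: float = INTERMEDIATE_LOW,
    high: float = INTERMEDIATE_HIGH,
    min_children: int = 3,
) -> set[tuple[str, int]]:
    """CpGs where >= ``min_children`` unmasked children have methylation
    fraction in the closed interval [low, high]."""
    if low >= high:
        raise ValueError("low bound must be below high bound")
    frac = cpgs.fractions()
    n_inter = ((frac >= low) & (frac <= high)).sum(axis=1)
    keep = n_inter[n_inter >= min_children].index
    return {(str(c), int(p)) for c, p in keep}


def haplotype_group_means(
    cpgs: CpGMatrix, genotype_groups: dict[str, str]
) -> pd.DataFrame:
    """Per-CpG, per-genotype-group mean methylation fraction and median coverage.

    ``genotype_groups`` maps each child to a group label (e.g. the three
    diplotypes at a variant). Groups must partition the children; an empty
    group yields NaN means. Returns a frame with a (group, statistic)
    column MultiIndex.
    """
    if set(genotype_groups) != set(cpgs.children):
        raise ValueError("genotype_groups must assign every child exactly once")
    frac = cpgs.fractions()
    cov = cpgs.coverage()
    if cpgs.mask is not None:
        cov = cov.where(~cpgs.mask)
    pieces = {}
    for group in sorted(set(genotype_groups.values())):
        members = [c for c in cpgs.children if genotype_groups[c] == group]
        pieces[(group, "mean_fraction")] = frac[members].mean(axis=1)
        pieces[(group, "median_coverage")] = cov[members].median(axis=1)
    return pd.DataFrame(pieces)


# ---------------------------------------------------------------------------
# i/o — TSV: chrom, pos, strand, then meth_<child>/unmeth_<child> per child
# ---------------------------------------------------------------------------

def read_methylation_tsv(path) -> tuple[CpGMatrix, CpGMatrix]:
    """Read a per-strand methylation TSV; returns (plus, minus) matrices."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "strand"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    children = sorted({c[5:] for c in df.columns if c.startswith("meth_")})
    out = []
    for strand in "+-":
        sub = df[df["strand"] == strand]
        idx = pd.MultiIndex.from_arrays([sub["chrom"], sub["pos"]], names=["chrom", "pos"])
        meth = pd.DataFrame({c: sub[f"meth_{c}"].to_numpy() for c in children}, index=idx)
        unmeth = pd.DataFrame({c: sub[f"unmeth_{c}"].to_numpy() for c in children}, index=idx)
        out.append(CpGMatrix(meth.sort_index(), unmeth.sort_index()))
    return out[0], out[1]


def write_methylation_tsv(plus: CpGMatrix, minus: CpGMatrix, path) -> None:
    frames = []
    for strand, m in (("+", plus), ("-", minus)):
        df = pd.DataFrame(index=m.meth.index)
        for c in m.children:
            df[f"meth_{c}"] = m.meth[c]
            df[f"unmeth_{c}"] = m.unmeth[c]
        df.insert(0, "strand", strand)
        frames.append(df.reset_index())
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_bedgraph(cpgs: CpGMatrix, child: str, path) -> None:
    """Export one child's methylation fractions as bedGraph."""
    frac = cpgs.fractions()[child].dropna()
    with open(path, "w") as fh:
        for (chrom, pos), v in frac.items():
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{v:.4f}\n")
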