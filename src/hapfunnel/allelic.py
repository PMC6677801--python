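"""Allele-specific read counting and allelic-imbalance testing.

At a heterozygous site inside an accessible region, reads carrying each
allele are tallied (bases below a quality floor excluded; bases matching
neither allele counted separately) and the ref/alt split is tested against a
1:1 expectation with a two-sided exact binomial test. An allele-exclusive
pileup — all reads from one allele — is the signature of chromatin open on
one haplotype only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["Site", "AllelicCount", "count_alleles", "imbalance_test",
           "count_alleles_pileup", "read_site_bases_tsv", "allelic_to_frame"]

MIN_BASEQ = 20


@dataclass(frozen=True)
class Site:
    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: ref and alt alleles are identical")


@dataclass
class AllelicCount:
    site: Site
    n_ref: int
    n_alt: int
    n_other: int
    sample_id: str = ""

    @property
    def depth(self) -> int:
        return self.n_ref + self.n_alt


def count_alleles(
    read_bases: list[tuple[str, int]],
    site: Site,
    min_baseq: int = MIN_BASEQ,
    sample_id: str = "",
) -> AllelicCount:
    """Tally (base, base_quality) observations at a site into ref/alt/other."""
    n_ref = n_alt = n_other = 0
    for base, qual in read_bases:
        if qual < min_baseq:
            continue
        if base == site.ref_allele:
            n_ref += 1
        elif base == site.alt_allele:
            n_alt += 1
        else:
            n_other += 1
    return AllelicCount(site, n_ref, n_alt, n_other, sample_id)


def imbalance_test(c: AllelicCount, expected_ratio: float = 0.5) -> float | None:
    """Two-sided exact binomial p-value for allelic imbalance.

    Tests n_ref successes in n_ref + n_alt informative reads against
    ``expected_ratio``, two-sided by the minimum-likelihood method (outcomes
    no more probable than the observed one contribute). Zero informative
    reads give None with a warning.
    """
    if c.depth == 0:
        warnings.warn(f"{c.site.chrom}:{c.site.pos}: no informative reads")
        return None
    return float(stats.binomtest(c.n_ref, c.depth, expected_ratio).pvalue)


def count_alleles_pileup(
    alignment_path,
    site: Site,
    min_baseq: int = MIN_BASEQ,
    sample_id: str = "",
) -> AllelicCount:
    """Tally alleles from a coordinate-sorted SAM/BAM pileup at the site.

    Reads flagged as duplicates or QC-fail upstream are honored (excluded by
    pysam's pileup defaults).
    """
    import pysam

    bases: list[tuple[str, int]] = []
    with pysam.AlignmentFile(str(alignment_path)) as af:
        for col in af.pileup(site.chrom, site.pos, site.pos + 1, truncate=True,
                             min_base_quality=0):
            if col.reference_pos != site.pos:
                continue
            for pr in col.pileups:
                if pr.is_del or pr.is_refskip or pr.query_position is None:
                    continue
                read = pr.alignment
                bases.append(
                    (
                        read.query_sequence[pr.query_position],
                        read.query_qualities[pr.query_position],
                    )
                )
    return count_alleles(bases, site, min_baseq, sample_id)


def read_site_bases_tsv(path) -> list[tuple[str, int]]:
    """Read a per-read base TSV (columns: base, baseq)."""
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["base"].astype(str), df["baseq"].astype(int)))


def allelic_to_frame(counts: list[AllelicCount]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.site.chrom,
                "pos": c.site.pos,
                "ref_allele": c.site.ref_allele,
                "alt_allele": c.site.alt_allele,
                "sample_id": c.sample_id,
                "n_ref": c.n_ref,
                "n_alt": c.n_alt,
                "n_other": c.n_other,
                "p_imbalance": imbalance_test(c) if c.depth else None,
            }
            for c in counts
        ]
    )
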