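"""Haplotype-inheritance QTL scans for genes, miRNAs, and accessibility summits.

Each trait is anchored to the haplotype block it resides in and regressed on
the paternal and maternal block-transmission indicators (plus technical
covariates)::

    T_i ~ mu + beta_p * p_i + beta_m * m_i  (+ batch, EBV quartile)

The joint test is an F-test of the retained haplotype terms against the
nested covariate-only model; marginal t-tests attribute the signal to a
parent. Benjamini–Hochberg FDR is applied across each scan, with class-level
significance thresholds: eGenes at FDR < 0.4, caSummits at FDR < 0.5,
e-miRNAs at FDR < 0.4 by default (all configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .pedigree import (
    CovariateTable,
    DesignMatrix,
    HaplotypeBlock,
    InsufficientSampleError,
    Pedigree,
    TransmissionTable,
    build_design,
)

__all__ = [
    "TraitMatrix",
    "QTLFit",
    "QTLResult",
    "DEFAULT_FDR",
    "filter_gene_counts",
    "filter_mirna_counts",
    "tmm_factors",
    "fit_trait",
    "qtl_scan",
    "results_to_frame",
]

TraitClass = Literal["gene", "mirna", "summit"]

#: default scan-level FDR thresholds per trait class
DEFAULT_FDR: dict[str, float] = {"gene": 0.4, "mirna": 0.4, "summit": 0.5}

SEX_EBV_CHROMS = {"chrX", "chrY", "X", "Y", "EBV", "chrEBV"}


@dataclass
class TraitMatrix:
    """Traits x children values with per-trait genomic anchors.

    ``anchors`` has one row per trait (chrom, start, end); a trait is tested
    against the single haplotype block containing its anchor midpoint.
    """

    values: pd.DataFrame
    anchors: pd.DataFrame
    trait_class: str

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.anchors.index):
            self.anchors = self.anchors.reindex(self.values.index)
            if self.anchors.isna().any().any():
                raise ValueError("anchors missing for some traits")


@dataclass
class QTLFit:
    intercept: float
    beta_paternal: float | None
    beta_maternal: float | None
    se_paternal: float | None
    se_maternal: float | None
    p_joint: float | None
    p_paternal: float | None
    p_maternal: float | None
    n_used: int
    dropped_terms: list[str]


@dataclass
class QTLResult:
    trait_id: str
    block_id: str
    fit: QTLFit
    fdr: float | None = None
    is_significant: bool = False
    associated_parent: str = "none"  # paternal | maternal | both | none


# ---------------------------------------------------------------------------
# trait filtering / normalization
# ---------------------------------------------------------------------------

def _log2_cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    lib = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    return np.log2(counts / lib * 1e6 + 1.0)


def filter_gene_counts(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    min_mean: float = 10.0,
    excluded_chroms: set[str] = SEX_EBV_CHROMS,
) -> TraitMatrix:
    """Gene-expression trait matrix: drop sex/EBV chromosomes, keep genes with
    mean raw count >= ``min_mean`` across children, transform to log2(CPM+1).

    Library sizes are totals over all genes passing the chromosome filter,
    computed before the mean-count filter.
    """
    ann = annotations.reindex(counts.index)
    if ann["chrom"].isna().any():
        missing = list(ann.index[ann["chrom"].isna()])[:5]
        raise ValueError(f"annotations missing for genes, e.g. {missing}")
    keep_chrom = ~ann["chrom"].isin(excluded_chroms)
    counts = counts.loc[keep_chrom]
    ann = ann.loc[keep_chrom]
    lib = counts.sum(axis=0)
    keep = counts.mean(axis=1) >= min_mean
    if not keep.any():
        raise ValueError("no genes pass the mean-count filter; review the threshold")
    values = _log2_cpm(counts.loc[keep], lib)
    return TraitMatrix(values=values, anchors=ann.loc[keep, ["chrom", "start", "end"]],
                       trait_class="gene")


def tmm_factors(
    counts: pd.DataFrame,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (edgeR's algorithm).

    The reference library is the one whose upper-quartile (of CPM over
    nonzero rows) is closest to the mean upper-quartile. Per library, genes
    expressed in both it and the reference contribute log-ratios M and
    average log-abundances A; the extreme 30% of M and 5% of A are trimmed
    and the factor is 2 to the (inverse-variance-weighted) trimmed mean of M.
    Factors are rescaled to have geometric mean 1.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("library with zero total counts")
    cpm = counts / lib * 1e6
    uq = cpm[counts > 0].quantile(0.75)
    ref = (uq - uq.mean()).abs().idxmin()

    factors = {}
    y_ref = counts[ref].to_numpy(float)
    n_ref = lib[ref]
    for col in counts.columns:
        y = counts[col].to_numpy(float)
        n = lib[col]
        ok = (y > 0) & (y_ref > 0)
        if ok.sum() == 0:
            factors[col] = 1.0
            continue
        p, p_ref = y[ok] / n, y_ref[ok] / n_ref
        M = np.log2(p / p_ref)
        A = 0.5 * np.log2(p * p_ref)
        # asymptotic (delta-method) variance of M, as in edgeR
        w = (n - y[ok]) / (n * y[ok]) + (n_ref - y_ref[ok]) / (n_ref * y_ref[ok])
        finite = np.isfinite(M) & np.isfinite(A) & np.isfinite(w)
        M, A, w = M[finite], A[finite], w[finite]
        if len(M) == 0 or np.max(np.abs(M)) < 1e-6:
            factors[col] = 1.0
            continue
        m_lo, m_hi = np.quantile(M, [m_trim, 1 - m_trim])
        a_lo, a_hi = np.quantile(A, [a_trim, 1 - a_trim])
        keep = (M >= m_lo) & (M <= m_hi) & (A >= a_lo) & (A <= a_hi)
        if keep.sum() == 0:
            factors[col] = 1.0
            continue
        f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[col] = float(2.0 ** f)
    fac = pd.Series(factors)
    fac /= np.exp(np.log(fac).mean())
    return fac


def filter_mirna_counts(
    counts: pd.DataFrame,
    anchors: pd.DataFrame | None = None,
    min_count: int = 5,
    min_children: int = 4,
) -> TraitMatrix:
    """miRNA trait matrix: keep miRNAs with >= ``min_count`` counts in at least
    ``min_children`` children, then TMM-normalize and transform to log2 CPM
    of the effective (TMM-scaled) library sizes."""
    if counts.shape[1] < 2:
        raise ValueError("miRNA normalization needs at least 2 children")
    keep = (counts >= min_count).sum(axis=1) >= min_children
    kept = counts.loc[keep]
    fac = tmm_factors(kept)
    eff_lib = kept.sum(axis=0) * fac
    values = np.log2(kept / eff_lib * 1e6 + 1.0)
    anch = anchors.reindex(kept.index) if anchors is not None else pd.DataFrame(
        index=kept.index, columns=["chrom", "start", "end"]
    )
    return TraitMatrix(values=values, anchors=anch, trait_class="mirna")


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def fit_trait(trait_values: pd.Series, design: DesignMatrix) -> QTLFit:
    """OLS fit of one trait on the block design.

    ``p_joint`` is the F-test of the retained haplotype terms against the
    nested covariate-only model; when the haplotype terms explain nothing
    beyond the nested model (e.g. a constant trait) the convention p = 1 is
    used. With every haplotype term dropped the joint test is undefined
    (``p_joint`` is None).
    """
    y = trait_values.reindex(design.X.index).to_numpy(float)
    X = design.X
    n, k = X.shape
    if n < k + 1:
        raise InsufficientSampleError(
            f"{n} children for {k} design columns in block {design.block_id}"
        )

    full = sm.OLS(y, X.to_numpy()).fit()
    params = dict(zip(X.columns, full.params))
    bse = dict(zip(X.columns, full.bse))
    pvals = dict(zip(X.columns, full.pvalues))

    hap = design.haplotype_terms
    p_joint = None
    if hap:
        reduced_cols = [c for c in X.columns if c not in hap]
        reduced = sm.OLS(y, X[reduced_cols].to_numpy()).fit()
        df_num = len(hap)
        df_den = n - k
        diff = reduced.ssr - full.ssr
        if df_den <= 0:
            p_joint = None
        elif full.ssr <= 1e-12 and diff <= 1e-12:
            p_joint = 1.0  # degenerate: nothing left to explain
        else:
            from scipy import stats

            F = (diff / df_num) / (full.ssr / df_den) if full.ssr > 0 else np.inf
            p_joint = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0

    def _get(d, term):
        v = d.get(term)
        return None if v is None else float(v)

    return QTLFit(
        intercept=float(params.get("mu", np.nan)),
        beta_paternal=_get(params, "paternal"),
        beta_maternal=_get(params, "maternal"),
        se_paternal=_get(bse, "paternal"),
        se_maternal=_get(bse, "maternal"),
        p_joint=p_joint,
        p_paternal=_get(pvals, "paternal"),
        p_maternal=_get(pvals, "maternal"),
        n_used=n,
        dropped_terms=list(design.dropped_terms),
    )


def _anchor_block(
    anchors: pd.DataFrame, blocks: list[HaplotypeBlock]
) -> dict[str, HaplotypeBlock]:
    """Map each trait to the single block containing its anchor midpoint."""
    mapping: dict[str, HaplotypeBlock] = {}
    by_chrom: dict[str, list[HaplotypeBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda b: b.start)
    for trait_id, row in anchors.iterrows():
        if pd.isna(row["chrom"]):
            continue
        mid = (int(row["start"]) + int(row["end"])) // 2
        for b in by_chrom.get(str(row["chrom"]), []):
            if b.start <= mid < b.end:
                mapping[str(trait_id)] = b
                break
    return mapping


def qtl_scan(
    traits: TraitMatrix,
    blocks: list[HaplotypeBlock],
    tx: TransmissionTable,
    cov: CovariateTable | None,
    ped: Pedigree,
    fdr_threshold: float | None = None,
    marginal_alpha: float = 0.05,
    fdr_method: str = "fdr_bh",
) -> list[QTLResult]:
    """Scan every anchored trait against its own block and call significance.

    FDR is computed over all joint p-values in the scan (genome-wide per
    scan). ``associated_parent`` is assigned among significant results as the
    parent(s) whose marginal t-test p < ``marginal_alpha``; if neither
    marginal reaches it, the parent with the smaller marginal p is taken.
    """
    if fdr_threshold is None:
        fdr_threshold = DEFAULT_FDR.get(traits.trait_class, 0.4)
    anchor_map = _anchor_block(traits.anchors, blocks)
    results: list[QTLResult] = []
    designs: dict[str, DesignMatrix] = {}
    n_skipped = 0
    for trait_id in traits.values.index:
        block = anchor_map.get(str(trait_id))
        if block is None:
            n_skipped += 1
            continue
        if block.block_id not in designs:
            designs[block.block_id] = build_design(block, tx, cov, ped)
        design = designs[block.block_id]
        if design.uninformative:
            continue
        fit = fit_trait(traits.values.loc[trait_id], design)
        results.append(QTLResult(str(trait_id), block.block_id, fit))
    if not results:
        raise ValueError(f"no testable traits (skipped {n_skipped} without a block)")

    testable = [r for r in results if r.fit.p_joint is not None]
    if testable:
        pvals = np.array([r.fit.p_joint for r in testable])
        _, fdrs, _, _ = multipletests(pvals, method=fdr_method)
        for r, q in zip(testable, fdrs):
            r.fdr = float(q)
            r.is_significant = q < fdr_threshold
            if r.is_significant:
                r.associated_parent = _attribute_parent(r.fit, marginal_alpha)
    return results


def _attribute_parent(fit: QTLFit, alpha: float) -> str:
    pp = fit.p_paternal if fit.p_paternal is not None else np.inf
    pm = fit.p_maternal if fit.p_maternal is not None else np.inf
    pat, mat = pp < alpha, pm < alpha
    if pat and mat:
        return "both"
    if pat:
        return "paternal"
    if mat:
        return "maternal"
    if np.isfinite(pp) or np.isfinite(pm):
        return "paternal" if pp <= pm else "maternal"
    return "none"


def results_to_frame(results: list[QTLResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        f = r.fit
        rows.append(
            {
                "trait_id": r.trait_id,
                "block_id": r.block_id,
                "beta_paternal": f.beta_paternal,
                "beta_maternal": f.beta_maternal,
                "se_paternal": f.se_paternal,
                "se_maternal": f.se_maternal,
                "p_joint": f.p_joint,
                "p_paternal": f.p_paternal,
                "p_maternal": f.p_maternal,
                "fdr": r.fdr,
                "is_significant": r.is_significant,
                "associated_parent": r.associated_parent,
                "n_used": f.n_used,
                "dropped_terms": ",".join(f.dropped_terms),
            }
        )
    return pd.DataFrame(rows)
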