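"""miRNA mediation regression: does a same-block e-miRNA predict an eGene?

For every (eGene, e-miRNA) pair anchored in the same haplotype block, the
eGene's expression is regressed on the miRNA's expression plus the technical
covariates (batch, EBV quartile). A pair with BH FDR < 0.05 on the miRNA
coefficient is flagged as a potential mediator of the haplotype effect. The
haplotype transmission terms are excluded from this regression by default
(``include_haplotype`` adds them back). An empty pair list is a legitimate
outcome, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .pedigree import CovariateTable, DesignMatrix

__all__ = ["MediationResult", "mediation_scan", "mediation_to_frame"]


@dataclass
class MediationResult:
    egene_id: str
    mirna_id: str
    block_id: str
    beta_mirna: float
    p_mirna: float
    fdr: float | None = None
    mediates: bool = False


def mediation_scan(
    egene_values: pd.DataFrame,
    egene_blocks: dict[str, str],
    emirna_values: pd.DataFrame,
    emirna_blocks: dict[str, str],
    cov: CovariateTable | None = None,
    fdr_threshold: float = 0.05,
    hap_designs: dict[str, DesignMatrix] | None = None,
) -> list[MediationResult]:
    """Regress each eGene on each same-block e-miRNA; BH FDR over all pairs.

    ``egene_blocks`` / ``emirna_blocks`` map trait ids to block ids; only
    pairs sharing a block are tested. Values must be normalized on the same
    children (columns). Passing ``hap_designs`` (block id -> design) includes
    that block's haplotype indicators as additional covariates.
    """
    children = list(egene_values.columns)
    if list(emirna_values.columns) != children:
        emirna_values = emirna_values[children]

    pairs = [
        (g, m, b)
        for g, b in egene_blocks.items()
        for m, mb in emirna_blocks.items()
        if mb == b and g in egene_values.index and m in emirna_values.index
    ]
    results: list[MediationResult] = []
    for gene, mirna, block in pairs:
        y = egene_values.loc[gene].to_numpy(float)
        X = pd.DataFrame({"mu": 1.0, "mirna": emirna_values.loc[mirna].to_numpy(float)},
                         index=children)
        if cov is not None:
            sub = cov.table.loc[children]
            for lev in sorted(sub["batch"].unique())[1:]:
                X[f"batch_{lev}"] = (sub["batch"] == lev).astype(float).to_numpy()
            X["ebv"] = sub["ebv_quartile"].astype(float).to_numpy()
        if hap_designs is not None and block in hap_designs:
            hd = hap_designs[block].X
            for term in ("paternal", "maternal"):
                if term in hd.columns:
                    X[term] = hd[term].reindex(children).to_numpy()
        X = X.loc[:, [c for c in X.columns if c == "mu" or X[c].nunique() > 1]]
        fit = sm.OLS(y, X.to_numpy()).fit()
        j = list(X.columns).index("mirna")
        results.append(
            MediationResult(gene, mirna, block, float(fit.params[j]), float(fit.pvalues[j]))
        )
    if results:
        _, fdrs, _, _ = multipletests(np.array([r.p_mirna for r in results]), method="fdr_bh")
        for r, q in zip(results, fdrs):
            r.fdr = float(q)
            r.mediates = q < fdr_threshold
    return results


def mediation_to_frame(results: list[MediationResult],
                       targets: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate results; an optional (mirna_id, gene_id) target-pair table adds
    a ``known_target`` annotation column."""
    df = pd.DataFrame(
        [
            {
                "egene_id": r.egene_id,
                "mirna_id": r.mirna_id,
                "block_id": r.block_id,
                "beta_mirna": r.beta_mirna,
                "p_mirna": r.p_mirna,
                "fdr": r.fdr,
                "mediates": r.mediates,
            }
            for r in results
        ]
    )
    if targets is not None and len(df):
        known = set(zip(targets["mirna_id"], targets["gene_id"]))
        df["known_target"] = [
            (m, g) in known for m, g in zip(df["mirna_id"], df["egene_id"])
        ]
    return df
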