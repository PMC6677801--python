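"""Pedigree structure, haplotype blocks, transmission, and the inheritance design matrix.

The analysis unit is a three-generation family (a CEPH-style pedigree): four
grandparents, two parents, and the children of the third generation. For each
child and each haplotype block we know which of the father's two block
haplotypes (``p_i``) and which of the mother's two (``m_i``) were transmitted.
Quantitative traits are regressed on these transmissions::

    T_i ~ mu + beta_p * p_i + beta_m * m_i  (+ covariates)

This module holds the family/transmission containers and builds the per-block
design matrix for that regression. Haplotype alleles are encoded with
founder-arbitrary 0/1 labels: swapping a parent's labels negates the fitted
coefficient but leaves the joint test invariant, so the labelling carries no
inferential content.

Coordinates are 0-based half-open (BED convention) throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PedigreeError",
    "Pedigree",
    "HaplotypeBlock",
    "TransmissionTable",
    "CovariateTable",
    "DesignMatrix",
    "load_pedigree",
    "load_blocks",
    "load_transmission",
    "load_covariates",
    "build_design",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree, block table, or transmission table."""


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    father: str | None
    mother: str | None
    generation: int


@dataclass
class Pedigree:
    """A validated family. ``children`` is the analysis set (maximum generation)."""

    members: list[PedigreeMember]
    children: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate sample ids in pedigree")
        by_id = {m.sample_id: m for m in self.members}
        for m in self.members:
            for parent in (m.father, m.mother):
                if parent is not None and parent not in by_id:
                    raise PedigreeError(
                        f"sample {m.sample_id!r} references missing parent {parent!r}"
                    )
                if parent is not None and by_id[parent].generation >= m.generation:
                    raise PedigreeError(
                        f"parent {parent!r} of {m.sample_id!r} does not precede it "
                        "in generation order"
                    )
        self._check_acyclic(by_id)
        if not self.children:
            max_gen = max(m.generation for m in self.members)
            self.children = [m.sample_id for m in self.members if m.generation == max_gen]
        if len(set(self.children)) != len(self.children):
            raise PedigreeError("duplicate ids in children list")
        for c in self.children:
            m = by_id.get(c)
            if m is None:
                raise PedigreeError(f"child {c!r} not a pedigree member")
            if m.father is None or m.mother is None:
                raise PedigreeError(f"child {c!r} lacks a recorded parent")
        self._by_id = by_id

    @staticmethod
    def _check_acyclic(by_id: dict[str, PedigreeMember]) -> None:
        # generation ordering already forbids cycles; this guards malformed input
        # where generations were forged but links loop.
        for start in by_id:
            seen: set[str] = set()
            stack = [start]
            while stack:
                cur = stack.pop()
                if cur in seen:
                    raise PedigreeError(f"cycle in parent links at {cur!r}")
                seen.add(cur)
                m = by_id[cur]
                stack.extend(p for p in (m.father, m.mother) if p is not None)

    def member(self, sample_id: str) -> PedigreeMember:
        return self._by_id[sample_id]

    def parents_of(self, child_id: str) -> tuple[str, str]:
        m = self._by_id[child_id]
        assert m.father is not None and m.mother is not None
        return m.father, m.mother


@dataclass(frozen=True)
class HaplotypeBlock:
    """A chromosomal segment transmitted as a unit within the family."""

    block_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise PedigreeError(f"block {self.block_id}: start must be < end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class TransmissionTable:
    """(child, block) -> (paternal allele, maternal allele), each in {0, 1}.

    The allele label identifies which of that parent's two block haplotypes
    the child received; labels are founder-arbitrary.
    """

    def __init__(self, entries: dict[tuple[str, str], tuple[int, int]]):
        for key, (p, m) in entries.items():
            if p not in (0, 1) or m not in (0, 1):
                raise PedigreeError(f"transmission for {key} must use 0/1 allele labels")
        self._entries = dict(entries)

    def get(self, child_id: str, block_id: str) -> tuple[int, int] | None:
        return self._entries.get((child_id, block_id))

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()


@dataclass
class CovariateTable:
    """Per-child technical covariates: batch label and EBV expression quartile."""

    table: pd.DataFrame  # index: child id; columns: batch, ebv_quartile

    def __post_init__(self) -> None:
        missing = {"batch", "ebv_quartile"} - set(self.table.columns)
        if missing:
            raise PedigreeError(f"covariate table missing columns: {sorted(missing)}")
        bad = set(self.table["ebv_quartile"].unique()) - {1, 2, 3, 4}
        if bad:
            raise PedigreeError(f"ebv_quartile values outside 1-4: {sorted(bad)}")
        if self.table.index.has_duplicates:
            raise PedigreeError("duplicate child rows in covariate table")


@dataclass
class DesignMatrix:
    """Regression design for one block: rows are children with complete data.

    Columns: ``mu`` (intercept), ``paternal``/``maternal`` 0/1 transmission
    indicators (constant ones dropped and recorded), then batch one-hot
    (first level as reference) and ``ebv`` as one ordinal column.
    """

    X: pd.DataFrame
    block_id: str
    dropped_terms: list[str]
    haplotype_terms: list[str]

    @property
    def children(self) -> list[str]:
        return list(self.X.index)

    @property
    def n_used(self) -> int:
        return len(self.X)

    @property
    def uninformative(self) -> bool:
        """True when both haplotype indicators were constant (block carries no signal)."""
        return not self.haplotype_terms


class InsufficientSampleError(PedigreeError):
    """Too few children with complete data to fit the model."""


# ---------------------------------------------------------------------------
# readers — documented TSV dialects (see docs/methods.md)
# ---------------------------------------------------------------------------

def _read_tsv(path, required: list[str], optional: list[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(required) - set(df.columns)
    if missing:
        raise PedigreeError(f"{path}: missing required columns {sorted(missing)}")
    unknown = set(df.columns) - set(required) - set(optional)
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {sorted(unknown)}")
        df = df.drop(columns=sorted(unknown))
    return df


def load_pedigree(path) -> Pedigree:
    """Read a 4-column pedigree TSV (sample_id, father, mother, generation).

    Missing parents are denoted ``.`` or empty. Children are all members of
    the maximum generation.
    """
    df = _read_tsv(path, ["sample_id", "father", "mother", "generation"])

    def _opt(v) -> str | None:
        return None if pd.isna(v) or v in (".", "") else str(v)

    members = [
        PedigreeMember(str(r.sample_id), _opt(r.father), _opt(r.mother), int(r.generation))
        for r in df.itertuples()
    ]
    return Pedigree(members)


def load_blocks(path) -> list[HaplotypeBlock]:
    """Read a haplotype-block TSV (block_id, chrom, start, end); validates
    per-chromosome non-overlap."""
    df = _read_tsv(path, ["block_id", "chrom", "start", "end"])
    blocks = [
        HaplotypeBlock(str(r.block_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]
    by_chrom: dict[str, list[HaplotypeBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.start)
        for a, b in zip(bs, bs[1:]):
            if b.start < a.end:
                raise PedigreeError(f"overlapping blocks on {chrom}: {a.block_id}, {b.block_id}")
    return blocks


def load_transmission(path) -> TransmissionTable:
    """Read a transmission TSV (child, block, paternal_allele, maternal_allele)."""
    df = _read_tsv(path, ["child", "block", "paternal_allele", "maternal_allele"])
    entries = {
        (str(r.child), str(r.block)): (int(r.paternal_allele), int(r.maternal_allele))
        for r in df.itertuples()
    }
    return TransmissionTable(entries)


def load_covariates(path) -> CovariateTable:
    """Read a covariate TSV (child, batch, ebv_quartile)."""
    df = _read_tsv(path, ["child", "batch", "ebv_quartile"])
    df["ebv_quartile"] = df["ebv_quartile"].astype(int)
    return CovariateTable(df.set_index("child")[["batch", "ebv_quartile"]])


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    block: HaplotypeBlock,
    tx: TransmissionTable,
    cov: CovariateTable | None,
    ped: Pedigree,
    min_children: int = 3,
) -> DesignMatrix:
    """Build the inheritance design matrix for one block.

    Children without a transmission record for this block (or without
    covariates, when supplied) are dropped; ``n_used`` reflects the rows kept.
    A haplotype indicator constant across the retained children is removed and
    listed in ``dropped_terms`` — a block where both are constant is flagged
    uninformative rather than raising.
    """
    rows, kept = [], []
    for child in ped.children:
        alleles = tx.get(child, block.block_id)
        if alleles is None:
            continue
        if cov is not None and child not in cov.table.index:
            continue
        rows.append(alleles)
        kept.append(child)
    if len(kept) < min_children:
        raise InsufficientSampleError(
            f"block {block.block_id}: only {len(kept)} children with complete data"
        )

    X = pd.DataFrame(1.0, index=pd.Index(kept, name="child"), columns=["mu"])
    X["paternal"] = [float(p) for p, _ in rows]
    X["maternal"] = [float(m) for _, m in rows]

    dropped = [t for t in ("paternal", "maternal") if X[t].nunique() == 1]
    X = X.drop(columns=dropped)
    hap_terms = [t for t in ("paternal", "maternal") if t not in dropped]

    if cov is not None:
        sub = cov.table.loc[kept]
        levels = sorted(sub["batch"].unique())
        for lev in levels[1:]:  # first level is the reference
            X[f"batch_{lev}"] = (sub["batch"] == lev).astype(float).to_numpy()
        X["ebv"] = sub["ebv_quartile"].astype(float).to_numpy()
        const = [c for c in X.columns if c != "mu" and X[c].nunique() == 1]
        X = X.drop(columns=const)  # e.g. every child in one EBV quartile

    return DesignMatrix(X=X, block_id=block.block_id, dropped_terms=dropped, haplotype_terms=hap_terms)
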