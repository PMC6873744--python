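"""Greedy p-value-ordered LD clumping to select independent instruments.

A panel of instruments must be (approximately) independent for the
inverse-variance combination of Wald ratios to be valid. Clumping iterates
SNPs from most to least significant and keeps a SNP only if no already-kept
SNP on the same chromosome within the window is in LD with it above the r^2
threshold. LD is supplied as a precomputed r^2 matrix (square TSV or sparse
pair list); estimating LD from a reference genotype panel is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .summary_data import GwasSummaryRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDMatrix:
    """Symmetric matrix of squared allelic correlations over SNP ids."""

    snp_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self):
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        n = len(self.snp_ids)
        if r2.shape != (n, n):
            raise ValueError(f"r2 matrix shape {r2.shape} does not match {n} ids")
        if len(set(self.snp_ids)) != n:
            raise ValueError("duplicate snp_ids in LD matrix")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-12):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(r2 < -1e-12) or np.any(r2 > 1 + 1e-12):
            raise ValueError("LD r2 entries must lie in [0, 1]")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.snp_ids)})

    def get(self, a: str, b: str) -> float | None:
        """r^2 between two SNPs, or None if either is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_table(cls, path) -> "LDMatrix":
        """Square TSV with rsID header row and first column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise DataError(f"{path}: row and column ids differ")
        return cls(snp_ids=tuple(df.columns), r2=df.to_numpy(dtype=float))

    @classmethod
    def from_pairs(cls, path, snp_ids: Sequence[str] | None = None) -> "LDMatrix":
        """Sparse three-column (id1, id2, r2) file; unlisted pairs are 0."""
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         names=["id1", "id2", "r2"], comment="#")
        ids = list(snp_ids) if snp_ids is not None else sorted(
            set(df["id1"]) | set(df["id2"])
        )
        index = {s: i for i, s in enumerate(ids)}
        r2 = np.eye(len(ids))
        for _, row in df.iterrows():
            i, j = index[str(row["id1"])], index[str(row["id2"])]
            r2[i, j] = r2[j, i] = float(row["r2"])
        return cls(snp_ids=tuple(ids), r2=r2)

    def to_table(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t"
        )


@dataclass(frozen=True)
class RemovedSnp:
    index_snp: str
    r2: float
    reason: str


@dataclass(frozen=True)
class ClumpResult:
    kept: tuple[str, ...]
    removed: Mapping[str, RemovedSnp] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def greedy_clump(
    records: Sequence[GwasSummaryRecord],
    ld: LDMatrix,
    r2_max: float = 0.001,
    window_bp: int = 2_000_000,
) -> ClumpResult:
    """Select independent SNPs by greedy p-value-ordered clumping.

    SNPs are visited in ascending p-value (ties broken lexicographically on
    rsID, so results are order-independent). A SNP is kept unless some
    already-kept SNP on the same chromosome within ``window_bp`` of it has
    r^2 strictly above ``r2_max``; cross-chromosome pairs never clump. Pairs
    missing from ``ld`` default to r^2 = 0 with a warning.
    """
    if not records:
        return ClumpResult(kept=())
    ids = [r.snp_id for r in records]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate snp_ids in clumping input")
    missing = [s for s in ids if s not in ld.snp_ids]
    if missing:
        logger.warning("SNPs absent from LD matrix treated as unlinked: %s", missing)

    order = sorted(records, key=lambda r: (r.p_value, r.snp_id))
    kept: list[GwasSummaryRecord] = []
    removed: dict[str, RemovedSnp] = {}
    for cand in order:
        offender = None
        for idx in kept:
            if idx.chromosome != cand.chromosome:
                continue
            if abs(idx.position - cand.position) > window_bp:
                continue
            r2 = ld.get(idx.snp_id, cand.snp_id)
            if r2 is None:
                r2 = 0.0
            if r2 > r2_max:
                offender = (idx.snp_id, r2)
                break
        if offender is None:
            kept.append(cand)
        else:
            removed[cand.snp_id] = RemovedSnp(
                index_snp=offender[0], r2=offender[1], reason="r2_above_threshold"
            )
    return ClumpResult(kept=tuple(k.snp_id for k in kept), removed=removed)


def locus_blocks(
    records: Sequence[GwasSummaryRecord],
    proximity_bp: int = 200_000,
) -> dict[str, str]:
    """Assign SNPs to locus blocks by shared gene label or physical proximity.

    Two SNPs share a block when they carry the same gene annotation or sit
    within ``proximity_bp`` of each other on the same chromosome (transitive
    closure). Used to build the block-LD stand-in for the packaged study,
    where only the locus structure — not pairwise r^2 — is known.
    """
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            same_gene = (
                a.gene_label is not None and a.gene_label == b.gene_label
            )
            near = (
                a.chromosome == b.chromosome
                and abs(a.position - b.position) <= proximity_bp
            )
            if same_gene or near:
                union(i, j)

    return {records[i].snp_id: f"block{find(i)}" for i in range(n)}
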