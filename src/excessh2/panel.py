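"""Reference panel container, variant filtering, MAF and windowed LD (r²).

The panel mirrors what a small imputation reference panel provides: an
ordered list of autosomal biallelic variants and a diploid dosage matrix
(individuals x variants, values 0/1/2, NaN for missing). MAF and pairwise
r² computed here feed the expected-heritability models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset(range(1, 23))


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant.

    ``maf`` is the observed minor allele frequency in the panel and
    ``info`` the genotype-certainty (information) score in [0, 1].
    """

    id: str
    chrom: int
    pos: int
    a1: str
    a2: str
    maf: float
    info: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.id}: MAF {self.maf} outside [0, 0.5]")
        if not (0.0 <= self.info <= 1.0):
            raise ValueError(f"{self.id}: info score {self.info} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be 1-based, got {self.pos}")


@dataclass
class ReferencePanel:
    """Ordered variants plus an individuals x variants diploid dosage matrix."""

    variants: list[VariantRecord]
    dosages: np.ndarray  # float array, entries in {0,1,2} or NaN

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-dimensional")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"dosage matrix has {self.dosages.shape[1]} columns for "
                f"{len(self.variants)} variants"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def validate_maf(self, atol: float = 1e-12) -> None:
        """Check stored MAFs against the dosage matrix."""
        recomputed = compute_maf(self)
        stored = np.array([v.maf for v in self.variants])
        bad = np.where(np.abs(recomputed - stored) > atol)[0]
        if bad.size:
            names = ", ".join(self.variants[j].id for j in bad[:5])
            raise ValueError(f"stored MAF disagrees with dosages for: {names}")


def compute_maf(panel: ReferencePanel) -> np.ndarray:
    """Observed minor allele frequency per variant, min(p, 1-p) with
    p = mean dosage / 2 over non-missing individuals."""
    d = panel.dosages
    n_obs = np.isfinite(d).sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.where(n_obs == 0)[0][0])
        raise ValueError(f"variant {panel.variants[j].id} has no observed genotypes")
    p = np.nansum(d, axis=0) / (2.0 * n_obs)
    return np.minimum(p, 1.0 - p)


def filter_variants(panel: ReferencePanel, maf_min: float = 0.01) -> ReferencePanel:
    """Restrict a panel to autosomal variants with MAF >= maf_min (inclusive).

    Order is preserved. Raises if nothing survives.
    """
    maf = compute_maf(panel)
    keep = [
        j
        for j, v in enumerate(panel.variants)
        if v.chrom in AUTOSOMES and maf[j] >= maf_min
    ]
    removed = panel.n_variants - len(keep)
    logger.info("filter_variants: removed %d of %d variants", removed, panel.n_variants)
    if not keep:
        raise ValueError(
            f"no variants remain after autosome + MAF >= {maf_min} filter"
        )
    variants = [
        replace(panel.variants[j], maf=float(maf[j])) for j in keep
    ]
    return ReferencePanel(variants=variants, dosages=panel.dosages[:, keep])


@dataclass
class LDTable:
    """Sparse symmetric windowed r² map.

    Entries are stored once with index pair ``(min(j,k), max(j,k))`` over
    variant *positions in the panel order*; the unit diagonal is implicit.
    """

    n_variants: int
    window_kb: float
    entries: dict[tuple[int, int], float] = field(default_factory=dict)

    def get(self, j: int, k: int) -> float:
        if j == k:
            return 1.0
        key = (j, k) if j < k else (k, j)
        return self.entries.get(key, 0.0)

    def set(self, j: int, k: int, r2: float) -> None:
        if j == k:
            return
        if not (0.0 <= r2 <= 1.0 + 1e-12):
            raise ValueError(f"r² {r2} outside [0, 1]")
        key = (j, k) if j < k else (k, j)
        self.entries[key] = min(float(r2), 1.0)

    def neighbors(self, j: int) -> list[tuple[int, float]]:
        """All stored partners of j (excluding j itself)."""
        out = []
        for (a, b), r2 in self.entries.items():
            if a == j:
                out.append((b, r2))
            elif b == j:
                out.append((a, r2))
        return out

    def neighbor_index(self) -> list[list[tuple[int, float]]]:
        """Adjacency list over all variants; O(entries) to build."""
        adj: list[list[tuple[int, float]]] = [[] for _ in range(self.n_variants)]
        for (a, b), r2 in self.entries.items():
            adj[a].append((b, r2))
            adj[b].append((a, r2))
        return adj


def ld_r2(panel: ReferencePanel, window_kb: float = 1000.0) -> LDTable:
    """Squared Pearson correlation of dosage columns for all same-chromosome
    pairs within ``window_kb`` kilobases.

    Missing genotypes are handled pairwise-complete. Zero-variance columns
    (monomorphic variants) are an error: they should have been filtered.
    """
    d = panel.dosages
    var = np.nanvar(d, axis=0)
    if (var == 0).any():
        j = int(np.where(var == 0)[0][0])
        raise ValueError(
            f"variant {panel.variants[j].id} has zero variance; filter first"
        )
    table = LDTable(n_variants=panel.n_variants, window_kb=window_kb)
    window_bp = window_kb * 1000.0
    chroms = np.array([v.chrom for v in panel.variants])
    poss = np.array([v.pos for v in panel.variants], dtype=float)
    has_missing = np.isnan(d).any()
    order = np.lexsort((poss, chroms))
    for chrom in np.unique(chroms):
        idx = order[chroms[order] == chrom]
        if idx.size < 2:
            continue
        if not has_missing:
            corr = np.corrcoef(d[:, idx], rowvar=False)
        for ii in range(idx.size):
            j = int(idx[ii])
            for kk in range(ii + 1, idx.size):
                k = int(idx[kk])
                if poss[k] - poss[j] > window_bp:
                    break
                if has_missing:
                    x, y = d[:, j], d[:, k]
                    ok = np.isfinite(x) & np.isfinite(y)
                    x, y = x[ok], y[ok]
                    if x.size < 2 or x.var() == 0 or y.var() == 0:
                        continue
                    r = np.corrcoef(x, y)[0, 1]
                else:
                    r = corr[ii, kk]
                table.set(j, k, float(r * r))
    return table
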