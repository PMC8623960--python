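"""Per-variant expected relative heritability under LDAK and LDAK-Thin.

Both models assume a variant's expected heritability contribution scales as

    E[h²_j] ∝ [f_j (1 - f_j)]^(1+α) · ϖ_j · r_j

with f_j the observed MAF, α the MAF-heritability exponent, ϖ_j an LD-based
SNP weight and r_j the genotype information score. Under LDAK the weights
solve (approximately) Σ_k ϖ_k r²_jk = 1 per variant, so variants in
high-LD regions are down-weighted; under LDAK-Thin ϖ_j ∈ {0, 1}, obtained
by thinning near-duplicate variants at an r² threshold.

Shares are normalized to sum to 100 over retained variants (relative,
percent-of-total units; every downstream statistic is a ratio and is
invariant to this constant). Tagging q_j = Σ_k r²_jk u_k adds back the
heritability a variant captures through LD with its neighbors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import nnls

from .panel import LDTable, VariantRecord

logger = logging.getLogger(__name__)


class Model(str, Enum):
    LDAK = "LDAK"
    LDAK_THIN = "LDAK-Thin"


@dataclass(frozen=True)
class ModelSpec:
    model: Model = Model.LDAK
    alpha: float = -0.25
    thin_r2: float = 0.98
    window_kb: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.thin_r2 <= 1.0):
            raise ValueError("thin_r2 must lie in (0, 1]")


@dataclass
class TaggingTable:
    """Per-variant expected share u_j (Σu = 100) and LD tagging q_j."""

    variants: list[VariantRecord]
    weights: np.ndarray
    u: np.ndarray
    q: np.ndarray | None
    spec: ModelSpec

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(self.u.sum() - 100.0) > 1e-8:
            raise ValueError(f"u must sum to 100, got {self.u.sum()!r}")

    def q_by_id(self) -> dict[str, float]:
        if self.q is None:
            raise ValueError("tagging (q) not yet computed")
        return {v.id: float(q) for v, q in zip(self.variants, self.q)}


_REG_LAMBDA = 1e-7  # Tikhonov term selecting the minimal-norm NNLS solution


def _components(adj: list[list[tuple[int, float]]]) -> list[list[int]]:
    """Connected components of the LD window graph."""
    n = len(adj)
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            j = stack.pop()
            comp.append(j)
            for k, _ in adj[j]:
                if not seen[k]:
                    seen[k] = True
                    stack.append(k)
        comps.append(sorted(comp))
    return comps


def ldak_weights(ld: LDTable, variants: list[VariantRecord]) -> np.ndarray:
    """LDAK SNP weights: minimal-norm non-negative solution of
    Σ_k ϖ_k r²_jk ≈ 1 for every variant j, solved independently per
    connected component of the windowed LD graph.

    The minimal-norm point matters when the system is rank-deficient
    (duplicate variants): a clique of c duplicates then gets ϖ = 1/c each.
    It is selected by augmenting the NNLS system with a tiny ridge term.
    Variants with no LD neighbors get ϖ = 1 exactly.
    """
    n = len(variants)
    if ld.n_variants != n:
        raise ValueError("LD table does not cover the variant list")
    adj = ld.neighbor_index()
    w = np.ones(n)
    sqrt_lam = np.sqrt(_REG_LAMBDA)
    for comp in _components(adj):
        c = len(comp)
        if c == 1:
            continue
        a = np.eye(c)
        pos = {j: i for i, j in enumerate(comp)}
        for j in comp:
            for k, r2 in adj[j]:
                a[pos[j], pos[k]] = r2
        aug = np.vstack([a, sqrt_lam * np.eye(c)])
        b = np.concatenate([np.ones(c), np.zeros(c)])
        try:
            sol, _ = nnls(aug, b)
        except RuntimeError:
            warnings.warn(
                f"NNLS failed for an LD component of size {c}; using ϖ=1",
                stacklevel=2,
            )
            sol = np.ones(c)
        w[comp] = sol
    return w


def thin_weights(
    ld: LDTable, variants: list[VariantRecord], thin_r2: float = 0.98
) -> np.ndarray:
    """LDAK-Thin binary weights by greedy position-ordered thinning.

    Scanning variants in (chrom, pos) order, a variant is dropped (ϖ=0)
    iff it has r² > thin_r2 with an earlier *retained* variant inside the
    LD window; one representative survives per duplicate clique.
    """
    n = len(variants)
    order = sorted(range(n), key=lambda j: (variants[j].chrom, variants[j].pos))
    adj = ld.neighbor_index()
    w = np.zeros(n)
    retained: set[int] = set()
    for j in order:
        if any(k in retained and r2 > thin_r2 for k, r2 in adj[j]):
            continue
        w[j] = 1.0
        retained.add(j)
    return w


def expected_h2(
    variants: list[VariantRecord], weights: np.ndarray, spec: ModelSpec
) -> np.ndarray:
    """Normalized expected shares u_j = 100 · raw_j / Σ raw with
    raw_j = [f_j(1-f_j)]^(1+α) · ϖ_j · r_j."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(variants),):
        raise ValueError("weights not aligned with variants")
    f = np.array([v.maf for v in variants])
    r = np.array([v.info for v in variants])
    with np.errstate(divide="ignore"):
        het = np.power(f * (1.0 - f), 1.0 + spec.alpha)
    het[~np.isfinite(het)] = 0.0  # f=0 with negative exponent
    raw = het * weights * r
    total = raw.sum()
    if total <= 0:
        raise ValueError("no variant contributes expected heritability")
    return 100.0 * raw / total


def compute_tagging(u: np.ndarray, ld: LDTable) -> np.ndarray:
    """Tagging q_j = Σ_{k in window of j} r²_jk · u_k, including k = j
    with r² = 1."""
    u = np.asarray(u, dtype=float)
    q = u.copy()
    for (j, k), r2 in ld.entries.items():
        q[j] += r2 * u[k]
        q[k] += r2 * u[j]
    return q


def build_tagging_table(
    variants: list[VariantRecord], ld: LDTable, spec: ModelSpec
) -> TaggingTable:
    """Weights → shares → tagging, under the requested model."""
    if spec.model is Model.LDAK:
        w = ldak_weights(ld, variants)
    else:
        w = thin_weights(ld, variants, spec.thin_r2)
    u = expected_h2(variants, w, spec)
    q = compute_tagging(u, ld)
    logger.info(
        "tagging table: model=%s alpha=%s, %d variants, %d retained",
        spec.model.value,
        spec.alpha,
        len(variants),
        int((w > 0).sum()),
    )
    return TaggingTable(variants=variants, weights=w, u=u, q=q, spec=spec)
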