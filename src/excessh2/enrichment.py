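"""Hypergeometric over-representation analysis with BH FDR control.

For a gene set with M members in a universe of N genes and an interest
list of n genes overlapping the set in m, the enrichment p-value is the
upper tail P(X >= m) of the hypergeometric distribution — the chance of
seeing at least m set members in n uniform draws without replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .synthetic import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ORAResult:
    set_name: str
    N: int
    M: int
    n: int
    m: int
    p: float
    q: float

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def hypergeom_p(N: int, M: int, n: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m)."""
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"infeasible counts: N={N}, M={M}, n={n}")
    if not (0 <= m <= min(M, n)):
        raise ValueError(f"overlap m={m} infeasible for M={M}, n={n}")
    # sf(m-1) = P(X >= m); exact in scipy's log-space implementation
    return float(hypergeom.sf(m - 1, N, M, n))


def bh_fdr(pvals: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if (pvals <= 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    return q


def ora(
    interest: list[str],
    sets: GeneSetCollection,
    universe: list[str] | None = None,
) -> list[ORAResult]:
    """Over-representation of ``interest`` in each gene set.

    The universe defaults to the union of all set members and the interest
    list; genes outside the universe are dropped from sets (logged), and
    the interest list must be contained in the universe.
    """
    if not interest:
        raise ValueError("interest gene list is empty")
    if universe is None:
        universe = sorted(set(interest) | {g for s in sets.sets.values() for g in s})
    uni = set(universe)
    interest_set = set(interest)
    outside = interest_set - uni
    if outside:
        raise ValueError(f"interest genes outside universe: {sorted(outside)[:5]}")
    N, n = len(uni), len(interest_set)

    names, ps, rows = [], [], []
    for name, members in sets.sets.items():
        mem = set(members)
        dropped = len(mem) - len(mem & uni)
        if dropped:
            logger.info("set %s: dropped %d genes outside universe", name, dropped)
        mem &= uni
        M = len(mem)
        m = len(mem & interest_set)
        ps.append(hypergeom_p(N, M, n, m))
        names.append(name)
        rows.append((M, m))
    qs = bh_fdr(ps)
    return [
        ORAResult(set_name=name, N=N, M=M, n=n, m=m, p=p, q=float(q))
        for name, (M, m), p, q in zip(names, rows, ps, qs)
    ]
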