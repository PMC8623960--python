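"""Set-level relative heritability and the excess statistics.

G1 is the core (disease) susceptibility set, G2 the union of G1 with one
phenotype's susceptibility variants, and G3 a size-matched union of G1
with random variants that provides the permutation null. From the set
sums h²_G1, h²_G2 and sizes n_G1, n_G2 four statistics are derived:

    h̄²_total = h²_G2 / n_G2
    h̄²_pheno = (h²_G2 − h²_G1) / (n_G2 − n_G1)
    AHPV      = 100 · (h²_G2 − h²_G1) / h²_G2        [percent]
    RHPV      = h̄²_pheno / (h²_G1 / n_G1)            [ratio]

AHPV is the share of the union's heritability attributable to the
phenotype-specific variants; RHPV compares their per-variant excess
heritability with the core set's per-variant heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .heritability import TaggingTable


@dataclass(frozen=True)
class VariantSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"variant set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


def union_set(core: VariantSet, pheno: VariantSet) -> VariantSet:
    """G2 = core ∪ phenotype set."""
    members = core.members | pheno.members
    if members == core.members:
        import warnings

        warnings.warn(
            f"{pheno.name}: union equals the core set; excess statistics "
            "will be degenerate",
            stacklevel=2,
        )
    return VariantSet(name=f"{core.name}+{pheno.name}", members=frozenset(members))


def set_relative_h2(tagging: TaggingTable, s: VariantSet) -> float:
    """Σ_{j∈s} q_j over the tagging table."""
    q = tagging.q_by_id()
    unknown = [v for v in s.members if v not in q]
    if unknown:
        raise KeyError(
            f"variant set {s.name!r} has members absent from the tagging "
            f"table: {sorted(unknown)[:5]}"
        )
    return float(sum(q[v] for v in s.members))


@dataclass(frozen=True)
class ExcessStats:
    h2_g1: float
    h2_g2: float
    n_g1: int
    n_g2: int
    h_bar_total: float
    h_bar_pheno: float
    ahpv: float
    rhpv: float


def excess_stats(h2_g1: float, h2_g2: float, n_g1: int, n_g2: int) -> ExcessStats:
    """The four derived statistics from two set sums and two set sizes."""
    if n_g2 <= n_g1:
        raise ValueError(
            f"no phenotype-specific variants: n_G2={n_g2} <= n_G1={n_g1}"
        )
    if h2_g2 <= 0:
        raise ValueError("h2_G2 must be positive")
    if h2_g1 <= 0:
        raise ValueError("h2_G1 must be positive")
    h_bar_total = h2_g2 / n_g2
    h_bar_pheno = (h2_g2 - h2_g1) / (n_g2 - n_g1)
    ahpv = 100.0 * (h2_g2 - h2_g1) / h2_g2
    rhpv = h_bar_pheno / (h2_g1 / n_g1)
    return ExcessStats(
        h2_g1=h2_g1,
        h2_g2=h2_g2,
        n_g1=n_g1,
        n_g2=n_g2,
        h_bar_total=h_bar_total,
        h_bar_pheno=h_bar_pheno,
        ahpv=ahpv,
        rhpv=rhpv,
    )


@dataclass
class NullDistribution:
    """Set sums of size-matched random unions G3 = core ∪ random extras."""

    draws: np.ndarray
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def sd(self) -> float:
        return float(np.std(self.draws, ddof=1)) if len(self.draws) > 1 else 0.0


def sample_null(
    tagging: TaggingTable,
    core: VariantSet,
    k_extra: int,
    n_rep: int = 100,
    seed: int = 0,
) -> NullDistribution:
    """Draw ``n_rep`` random G3 sets: the core plus ``k_extra`` variants
    sampled uniformly without replacement from the tagging table minus the
    core. Matching |G3| = |G2| controls the inflation that comes purely
    from adding variants."""
    q = tagging.q_by_id()
    eligible = np.array(sorted(set(q) - core.members))
    if k_extra > len(eligible):
        raise ValueError(
            f"need {k_extra} non-core variants, only {len(eligible)} eligible"
        )
    core_sum = set_relative_h2(tagging, core)
    q_eligible = np.array([q[v] for v in eligible])
    rng = np.random.default_rng(seed)
    draws = np.empty(n_rep)
    for i in range(n_rep):
        idx = rng.choice(len(eligible), size=k_extra, replace=False)
        draws[i] = core_sum + q_eligible[idx].sum()
    return NullDistribution(draws=draws, seed=seed)


def significance(
    observed: float, null: NullDistribution, alpha: float = 0.05
) -> tuple[bool, float]:
    """One-sided empirical p (is the observed set sum higher than random?)
    with the (1 + #{draws ≥ observed}) / (1 + n) permutation convention;
    ties count against significance."""
    draws = np.asarray(null.draws)
    if draws.size == 0:
        raise ValueError("empty null distribution")
    p = (1.0 + float((draws >= observed).sum())) / (1.0 + draws.size)
    return p <= alpha, p


def count_correlation(
    contributions: np.ndarray, counts: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (with two-sided t-test p) between per-phenotype
    heritability contributions and variant counts."""
    contributions = np.asarray(contributions, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if contributions.size < 3:
        raise ValueError("need at least 3 phenotypes")
    if np.ptp(contributions) == 0 or np.ptp(counts) == 0:
        raise ValueError("constant input vector")
    r, p = sps.pearsonr(contributions, counts)
    return float(r), float(p)
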