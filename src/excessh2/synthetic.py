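"""Synthetic inputs with controlled statistical structure.

Everything the downstream analysis would normally obtain externally — a
reference panel of diploid genotypes, per-phenotype susceptibility-variant
catalogs with a known overlap pattern, a protein-interaction network with a
planted dense hub community, and pathway-style gene sets with one planted
enriched set — is generated here as a pure function of its seed and
parameters.

LD is induced per block through a latent Gaussian copula: haplotypes are
thresholded multivariate normals with a common within-block correlation
solved numerically so that the *realized genotype* r² lands near the
requested target. All variants in a block share one allele frequency
(unequal frequencies would cap attainable r² below the target).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .panel import ReferencePanel, VariantRecord, compute_maf

N_AUTOSOMES = 22
BLOCK_SPACING_BP = 1000  # 1 kb between adjacent variants in a block


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic reference panel.

    ``within_block_r2`` is the target pairwise genotype r² inside an LD
    block; cross-block LD is left at the finite-sample baseline (~1/n).
    """

    n_individuals: int
    n_variants: int
    block_size: int = 10
    within_block_r2: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    info_range: tuple[float, float] | None = None  # None => info score 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_variants < 1 or self.block_size < 1:
            raise ValueError("n_individuals, n_variants, block_size must be positive")
        if not (0.0 <= self.within_block_r2 <= 1.0):
            raise ValueError("within_block_r2 must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0.01 <= lo <= hi <= 0.5")


@dataclass(frozen=True)
class PhenotypeSpec:
    """One behaviour-related phenotype's susceptibility-variant set."""

    name: str
    n_variants: int
    overlap_with_core: int

    def __post_init__(self) -> None:
        if self.overlap_with_core > self.n_variants:
            raise ValueError(
                f"{self.name}: overlap {self.overlap_with_core} exceeds "
                f"set size {self.n_variants}"
            )


@dataclass
class VariantCatalog:
    """Named variant sets: one core (disease) set plus phenotype sets."""

    core_name: str
    sets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def core(self) -> list[str]:
        return self.sets[self.core_name]

    def phenotype_names(self) -> list[str]:
        return [n for n in self.sets if n != self.core_name]


def _latent_rho(target_r2: float, p: float) -> float:
    """Latent normal correlation giving thresholded-indicator correlation
    sqrt(target_r2) at allele frequency p.

    Indicator correlation for a common threshold t = Phi^-1(p) is
    (Phi2(t, t; rho) - p²) / (p(1-p)); invert by bisection.
    """
    if target_r2 <= 0.0:
        return 0.0
    r = float(np.sqrt(target_r2))
    t = stats.norm.ppf(p)
    denom = p * (1.0 - p)

    def f(rho: float) -> float:
        orthant = stats.multivariate_normal.cdf(
            [t, t], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return (orthant - p * p) / denom - r

    if f(1.0 - 1e-9) < 0:
        return 1.0 - 1e-9
    return float(brentq(f, 0.0, 1.0 - 1e-9, xtol=1e-10))


def _block_layout(n_variants: int, block_size: int) -> list[tuple[int, int, int]]:
    """(block_start, chrom, pos_start) per block: chromosomes 1..22
    round-robin, 1-based positions, 1 kb spacing, blocks contiguous."""
    layout = []
    next_pos = {c: 1 for c in range(1, N_AUTOSOMES + 1)}
    for b, start in enumerate(range(0, n_variants, block_size)):
        chrom = (b % N_AUTOSOMES) + 1
        size = min(block_size, n_variants - start)
        layout.append((start, chrom, next_pos[chrom]))
        next_pos[chrom] += size * BLOCK_SPACING_BP
    return layout


_MAX_BLOCK_RETRIES = 50


def gen_panel(config: SimulationConfig) -> ReferencePanel:
    """Simulate a diploid dosage panel with per-block LD structure.

    Each haplotype is a thresholded draw from a block-equicorrelated
    multivariate normal; dosage is the sum of two independent haplotypes.
    Blocks whose realized MAF drops below 0.01 (or that go monomorphic)
    are resampled, with a bounded retry count.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_variants
    dosages = np.empty((n, m))
    mafs = np.empty(m)
    lo, hi = config.maf_range

    for start, chrom, _pos in _block_layout(m, config.block_size):
        size = min(config.block_size, m - start)
        for attempt in range(_MAX_BLOCK_RETRIES):
            p = rng.uniform(lo, hi)
            rho = _latent_rho(config.within_block_r2, p)
            cov = np.full((size, size), rho)
            np.fill_diagonal(cov, 1.0)
            chol = np.linalg.cholesky(cov)
            t = stats.norm.ppf(p)
            hap1 = (rng.standard_normal((n, size)) @ chol.T) < t
            hap2 = (rng.standard_normal((n, size)) @ chol.T) < t
            block = (hap1 + hap2).astype(float)
            freq = block.mean(axis=0) / 2.0
            maf = np.minimum(freq, 1.0 - freq)
            if (maf >= 0.01).all() and (block.std(axis=0) > 0).all():
                dosages[:, start : start + size] = block
                mafs[start : start + size] = maf
                break
        else:
            raise RuntimeError(
                f"block at variant {start}: could not realize MAF >= 0.01 in "
                f"{_MAX_BLOCK_RETRIES} attempts (maf_range too extreme for n?)"
            )

    if config.info_range is None:
        infos = np.ones(m)
    else:
        infos = rng.uniform(config.info_range[0], config.info_range[1], size=m)

    variants = []
    for start, chrom, pos0 in _block_layout(m, config.block_size):
        size = min(config.block_size, m - start)
        for i in range(size):
            j = start + i
            variants.append(
                VariantRecord(
                    id=f"rs{j + 1:06d}",
                    chrom=chrom,
                    pos=pos0 + i * BLOCK_SPACING_BP,
                    a1="A",
                    a2="G",
                    maf=float(mafs[j]),
                    info=float(infos[j]),
                )
            )
    return ReferencePanel(variants=variants, dosages=dosages)


def gen_phenotype_catalog(
    panel: ReferencePanel,
    core_size: int,
    specs: list[PhenotypeSpec],
    seed: int,
    core_name: str = "core",
) -> VariantCatalog:
    """Draw a core set and per-phenotype sets with exact requested overlaps.

    Each phenotype set shares exactly ``overlap_with_core`` variants with
    the core; non-core members are drawn from the remaining panel variants
    (and may be shared between phenotypes, as real catalogs overlap).
    """
    rng = np.random.default_rng(seed)
    ids = np.array(panel.variant_ids())
    if core_size > len(ids):
        raise ValueError(f"core_size {core_size} exceeds panel size {len(ids)}")
    core = rng.choice(ids, size=core_size, replace=False)
    core_set = set(core)
    non_core = np.array([v for v in ids if v not in core_set])

    catalog = VariantCatalog(core_name=core_name)
    catalog.sets[core_name] = sorted(core)
    for spec in specs:
        if spec.overlap_with_core > core_size:
            raise ValueError(
                f"{spec.name}: overlap {spec.overlap_with_core} exceeds core "
                f"size {core_size}"
            )
        n_new = spec.n_variants - spec.overlap_with_core
        if n_new > len(non_core):
            raise ValueError(
                f"{spec.name}: needs {n_new} non-core variants, panel has "
                f"{len(non_core)}"
            )
        shared = rng.choice(core, size=spec.overlap_with_core, replace=False)
        fresh = rng.choice(non_core, size=n_new, replace=False)
        catalog.sets[spec.name] = sorted(np.concatenate([shared, fresh]))
    return catalog


def gen_network(
    n_nodes: int,
    n_hubs: int,
    p_background: float,
    p_hub: float,
    seed: int,
    node_prefix: str = "GENE",
):
    """Random undirected PPI-style graph with a planted hub community.

    Pairs touching any of the first ``n_hubs`` nodes are wired with
    probability ``p_hub``; all other pairs with ``p_background``. Edge
    confidences are uniform in (0, 1].
    """
    import networkx as nx

    if n_hubs > 0 and p_hub < p_background:
        raise ValueError("p_hub must be >= p_background")
    if n_hubs >= n_nodes:
        raise ValueError("n_hubs must be smaller than n_nodes")
    rng = np.random.default_rng(seed)
    names = [f"{node_prefix}{i:04d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(names)
    g.graph["planted_hubs"] = names[:n_hubs]
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            p = p_hub if (i < n_hubs or j < n_hubs) else p_background
            if rng.random() < p:
                conf = 1.0 - rng.random()  # uniform in (0, 1]
                g.add_edge(names[i], names[j], confidence=float(conf))
    return g


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-writable)."""

    sets: dict[str, list[str]]
    planted: str | None = None  # name of the planted enriched set, if any


def gen_gene_sets(
    genes: list[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    enriched_in: list[str],
    seed: int,
) -> GeneSetCollection:
    """Random gene sets plus, when ``enriched_in`` is non-empty, one planted
    set containing most of those genes (80%, at least one) padded with
    random genes up to the set-size range."""
    rng = np.random.default_rng(seed)
    universe = list(genes)
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError(f"set size {hi} exceeds universe {len(universe)}")
    missing = set(enriched_in) - set(universe)
    if missing:
        raise ValueError(f"enriched_in genes not in universe: {sorted(missing)[:5]}")

    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"SET{i:04d}"] = sorted(rng.choice(universe, size=size, replace=False))

    planted = None
    if enriched_in:
        n_in = max(1, int(round(0.8 * len(enriched_in))))
        members = list(rng.choice(enriched_in, size=n_in, replace=False))
        pool = [g for g in universe if g not in set(members)]
        size = max(lo, n_in)
        pad = size - n_in
        if pad > 0:
            members += list(rng.choice(pool, size=pad, replace=False))
        planted = "SET_PLANTED"
        sets[planted] = sorted(members)
    return GeneSetCollection(sets=sets, planted=planted)
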