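"""Generate the synthetic study inputs.

Emulates the real data sources at desk scale: a reference panel of 404
diploid individuals (the reported panel size) over 4,000 variants in
10-variant LD blocks; a susceptibility-variant catalog with the published
per-phenotype set sizes and core overlaps; pathway-style gene sets with
one planted enriched set; and a PPI-style network with a planted hub
community.

Bulky inputs (VCF/PLINK panel, catalog) go to scratch/sim_inputs/; the
downstream drivers read them from there.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from excessh2 import io as eio
from excessh2.synthetic import (
    PhenotypeSpec,
    SimulationConfig,
    gen_gene_sets,
    gen_network,
    gen_panel,
    gen_phenotype_catalog,
)

OUT = ROOT / "scratch" / "sim_inputs"

# Per-phenotype set sizes and core overlaps from the published catalog:
# overlap = |set| + |core| - |union|.
PHENOTYPES = [
    ("educational_attainment", 1263, 2),
    ("lifetime_smoking_index", 126, 0),
    ("alcohol_consumption", 98, 1),
    ("coffee_consumption", 14, 1),
    ("breakfast_skipping", 6, 0),
    ("caffeine_intake", 2, 0),
    ("morningness", 342, 2),
    ("insomnia", 244, 1),
    ("sleep_duration", 77, 0),
    ("daytime_napping", 36, 0),
    ("short_sleep", 26, 0),
    ("restless_leg_syndrome", 20, 0),
    ("moderate_to_vigorous_physical_activity", 9, 1),
    ("strenuous_sports", 6, 0),
    ("vigorous_physical", 5, 0),
    ("accelerometer", 2, 0),
]

CORE_SIZE = 363
PANEL_SEED = 2021
CATALOG_SEED = 2022
GENESET_SEED = 2023
NETWORK_SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    config = SimulationConfig(
        n_individuals=404,
        n_variants=4000,
        block_size=10,
        within_block_r2=0.6,
        maf_range=(0.05, 0.5),
        seed=PANEL_SEED,
    )
    panel = gen_panel(config)
    eio.write_vcf(panel, OUT / "panel.vcf")
    eio.write_plink(panel, OUT / "panel")
    print(f"panel: {panel.n_individuals} individuals x {panel.n_variants} variants")

    specs = [PhenotypeSpec(name, n, k) for name, n, k in PHENOTYPES]
    catalog = gen_phenotype_catalog(
        panel, CORE_SIZE, specs, seed=CATALOG_SEED, core_name="type_2_diabetes"
    )
    eio.write_catalog(catalog, panel, OUT / "catalog.tsv")
    union = set(catalog.core)
    for name in catalog.phenotype_names():
        union |= set(catalog.sets[name])
    print(f"catalog: core {CORE_SIZE} + {len(specs)} phenotypes, "
          f"overall union {len(union)} variants")

    genes = [f"GENE{i:04d}" for i in range(1000)]
    interest = genes[:55]  # stand-in for the annotated susceptibility genes
    coll = gen_gene_sets(genes, 40, (20, 60), enriched_in=interest[:10],
                         seed=GENESET_SEED)
    eio.write_gmt(coll, OUT / "gene_sets.gmt")
    (OUT / "interest_genes.txt").write_text("\n".join(interest) + "\n")
    print(f"gene sets: {len(coll.sets)} sets (planted: {coll.planted})")

    net = gen_network(200, 20, p_background=0.02, p_hub=0.4, seed=NETWORK_SEED)
    eio.write_network(net, OUT / "network.tsv")
    (OUT / "planted_hubs.txt").write_text(
        "\n".join(net.graph["planted_hubs"]) + "\n"
    )
    print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges, "
          f"20 planted hubs")


if __name__ == "__main__":
    main()
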