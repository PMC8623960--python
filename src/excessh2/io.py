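"""Readers and writers for the pipeline's file formats.

Panels round-trip through VCFv4.2 (GT fields, read back with cyvcf2) and
PLINK1 bed/bim/fam (SNP-major 2-bit codes). Catalogs, LD tables, tagging
tables and networks are tab-separated text; gene sets use GMT. All table
writers prefix '#' metadata lines naming the generating parameters so a
run is self-describing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .heritability import TaggingTable
from .panel import LDTable, ReferencePanel, VariantRecord
from .synthetic import GeneSetCollection, VariantCatalog

# ---------------------------------------------------------------- VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=excessh2-synthetic
##INFO=<ID=INFOSCORE,Number=1,Type=Float,Description="Genotype certainty score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(panel: ReferencePanel, path: str | Path) -> None:
    """Write a panel as uncompressed VCFv4.2 with unphased GT fields.

    Dosage counts the ALT (a2) allele, so 0 -> 0/0, 1 -> 0/1, 2 -> 1/1.
    """
    path = Path(path)
    samples = [f"sample{i:04d}" for i in range(panel.n_individuals)]
    contigs = sorted({v.chrom for v in panel.variants})
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, v in enumerate(panel.variants):
            col = panel.dosages[:, j]
            gts = "\t".join(
                "./." if np.isnan(x) else gt_map[x] for x in col
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.a1}\t{v.a2}\t.\t.\t"
                f"INFOSCORE={v.info:g}\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> ReferencePanel:
    """Read a biallelic VCF into a panel (multi-allelic records rejected)."""
    from cyvcf2 import VCF

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    vcf = VCF(str(path), gts012=True)
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; split first"
            )
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=missing
        dosage = np.array(rec.gt_types, dtype=float)
        dosage[dosage == 3] = np.nan
        info = rec.INFO.get("INFOSCORE")
        columns.append(dosage)
        n_obs = np.isfinite(dosage).sum()
        p = np.nansum(dosage) / (2 * n_obs) if n_obs else 0.0
        variants.append(
            VariantRecord(
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=int(rec.CHROM),
                pos=rec.POS,
                a1=rec.REF,
                a2=rec.ALT[0],
                maf=float(min(p, 1 - p)),
                info=float(info) if info is not None else 1.0,
            )
        )
    if not variants:
        raise ValueError(f"no variants in {path}")
    return ReferencePanel(variants=variants, dosages=np.column_stack(columns))


# ---------------------------------------------------------------- PLINK1

_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major
# 2-bit codes, indexed by ALT-allele dosage; 0b01 is missing
_CODE_FOR_DOSAGE = {0.0: 0b00, 1.0: 0b10, 2.0: 0b11}
_DOSAGE_FOR_CODE = {0b00: 0.0, 0b01: np.nan, 0b10: 1.0, 0b11: 2.0}


def write_plink(panel: ReferencePanel, prefix: str | Path) -> None:
    """Write bed/bim/fam. The bim A1 column holds the panel's a1 allele
    and bed code 0b00 means two a1 alleles (ALT dosage 0)."""
    prefix = Path(prefix)
    with open(f"{prefix}.fam", "w") as fh:
        for i in range(panel.n_individuals):
            fh.write(f"F{i:04d} sample{i:04d} 0 0 0 -9\n")
    with open(f"{prefix}.bim", "w") as fh:
        for v in panel.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.a1}\t{v.a2}\n")
    n = panel.n_individuals
    n_bytes = (n + 3) // 4
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(panel.n_variants):
            col = panel.dosages[:, j]
            buf = bytearray(n_bytes)
            for i, x in enumerate(col):
                code = 0b01 if np.isnan(x) else _CODE_FOR_DOSAGE[x]
                buf[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(buf))


def read_plink(prefix: str | Path) -> ReferencePanel:
    """Read a bed/bim/fam trio written by :func:`write_plink` (or PLINK1,
    SNP-major)."""
    prefix = Path(prefix)
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None)
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    raw = Path(f"{prefix}.bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK1)")
    expected = 3 + m * n_bytes
    if len(raw) != expected:
        raise ValueError(
            f"{prefix}.bed: expected {expected} bytes for {n} individuals x "
            f"{m} variants, found {len(raw)} (truncated or corrupt)"
        )
    dosages = np.empty((n, m))
    for j in range(m):
        block = raw[3 + j * n_bytes : 3 + (j + 1) * n_bytes]
        for i in range(n):
            code = (block[i // 4] >> (2 * (i % 4))) & 0b11
            dosages[i, j] = _DOSAGE_FOR_CODE[code]
    variants = []
    for j, row in bim.iterrows():
        col = dosages[:, j]
        n_obs = np.isfinite(col).sum()
        p = np.nansum(col) / (2 * n_obs) if n_obs else 0.0
        variants.append(
            VariantRecord(
                id=str(row["id"]),
                chrom=int(row["chrom"]),
                pos=int(row["pos"]),
                a1=str(row["a1"]),
                a2=str(row["a2"]),
                maf=float(min(p, 1 - p)),
            )
        )
    return ReferencePanel(variants=variants, dosages=dosages)


def read_panel(path: str | Path, format: str = "vcf") -> ReferencePanel:
    if format == "vcf":
        return read_vcf(path)
    if format == "plink1":
        return read_plink(path)
    raise ValueError(f"unknown panel format {format!r}")


# ---------------------------------------------------------------- tables


def _write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_catalog(catalog: VariantCatalog, panel: ReferencePanel, path: str | Path) -> None:
    by_id = {v.id: v for v in panel.variants}
    rows = []
    for name, members in catalog.sets.items():
        for vid in members:
            v = by_id[vid]
            eaf = 1.0 - v.maf  # a2 treated as effect allele
            rows.append((name, vid, v.chrom, v.pos, v.a1, v.a2, round(eaf, 6)))
    df = pd.DataFrame(
        rows, columns=["phenotype", "rsid", "chr", "pos", "a1", "a2", "eaf"]
    )
    _write_tsv(df, path, meta={"core_set": catalog.core_name})


def read_catalog(path: str | Path) -> VariantCatalog:
    core_name = "core"
    with open(path) as fh:
        for line in fh:
            if line.startswith("# core_set:"):
                core_name = line.split(":", 1)[1].strip()
            if not line.startswith("#"):
                break
    df = read_tsv(path)
    catalog = VariantCatalog(core_name=core_name)
    for name, grp in df.groupby("phenotype", sort=False):
        catalog.sets[str(name)] = sorted(grp["rsid"].astype(str))
    return catalog


def write_ld(ld: LDTable, panel: ReferencePanel, path: str | Path) -> None:
    ids = panel.variant_ids()
    rows = [(ids[j], ids[k], r2) for (j, k), r2 in sorted(ld.entries.items())]
    df = pd.DataFrame(rows, columns=["id1", "id2", "r2"])
    _write_tsv(df, path, meta={"window_kb": ld.window_kb})


def write_tagging(tag: TaggingTable, path: str | Path, seed: int | None = None) -> None:
    df = pd.DataFrame(
        {
            "id": [v.id for v in tag.variants],
            "chrom": [v.chrom for v in tag.variants],
            "pos": [v.pos for v in tag.variants],
            "maf": [v.maf for v in tag.variants],
            "weight": tag.weights,
            "u": tag.u,
            "q": tag.q,
        }
    )
    meta = {
        "model": tag.spec.model.value,
        "alpha": tag.spec.alpha,
        "window_kb": tag.spec.window_kb,
    }
    if seed is not None:
        meta["seed"] = seed
    _write_tsv(df, path, meta=meta)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.sets.items():
            fh.write(name + "\tsynthetic\t" + "\t".join(members) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return GeneSetCollection(sets=sets)


def write_network(net, path: str | Path) -> None:
    rows = [
        (u, v, round(d.get("confidence", 0.5), 6))
        for u, v, d in sorted(net.edges(data=True))
    ]
    df = pd.DataFrame(rows, columns=["gene1", "gene2", "score"])
    _write_tsv(df, path)


def read_network(path: str | Path):
    import networkx as nx

    df = read_tsv(path)
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(str(row["gene1"]), str(row["gene2"]), confidence=float(row["score"]))
    return g
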