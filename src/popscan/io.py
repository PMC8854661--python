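"""Reading and writing the standard formats.

VCF parsing goes through cyvcf2; only biallelic SNPs are loaded (multiallelic
records and indels are skipped with a logged count, not split).  Missense
status comes from an ANN-style INFO field containing ``missense_variant`` or
from a sidecar TSV of (chrom, pos) coordinates.  Site depth is taken from
INFO/DP when present, else from the mean of per-sample FORMAT/DP.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_popmap",
    "read_chrom_lengths",
    "read_vcf",
    "write_vcf",
    "filter_sites",
    "read_intervals",
]

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_GT_CODE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def read_popmap(path: str | Path) -> dict[str, str]:
    """Sample -> population map from a two-column TSV (no header)."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {ln}: expected 'sample<TAB>population'")
        out[parts[0]] = parts[1]
    if not out:
        raise ValueError(f"{path}: empty population map")
    return out


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Chromosome lengths from a TSV / .fai-style file (first two columns)."""
    out: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {ln}: expected 'chrom<TAB>length'")
        out[parts[0]] = int(parts[1])
    if not out:
        raise ValueError(f"{path}: no chromosome lengths found")
    return out


def _read_annotation_tsv(path: str | Path) -> set[tuple[str, int]]:
    tab = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in tab.columns]
    if "chrom" in cols and "pos" in cols:
        chrom = tab[tab.columns[cols.index("chrom")]]
        pos = tab[tab.columns[cols.index("pos")]]
    else:  # headerless two-column file
        tab = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
        chrom, pos = tab[0], tab[1]
    return set(zip(chrom.astype(str), pos.astype(int)))


def read_vcf(
    path: str | Path,
    popmap: str | Path | Mapping[str, str],
    annotations: str | Path | None = None,
) -> GenotypeMatrix:
    """Load biallelic SNPs with GT genotypes into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF 4.x file (plain or bgzipped) with GT fields.
    popmap
        Path to a sample<TAB>population TSV, or an in-memory mapping.
        Every VCF sample must be present.
    annotations
        Optional sidecar TSV of missense sites (columns chrom, pos), used
        when the VCF lacks ANN annotations.
    """
    if not isinstance(popmap, Mapping):
        popmap = read_popmap(popmap)
    sidecar = _read_annotation_tsv(annotations) if annotations is not None else None

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in popmap]
    if missing:
        raise ValueError(
            f"samples in VCF absent from population map: {', '.join(missing)}"
        )
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    missense: list[bool] = []
    depths: list[float] = []
    geno_rows: list[np.ndarray] = []
    n_skipped = 0
    any_depth = False
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        chroms.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        ann = v.INFO.get("ANN")
        is_mis = ann is not None and "missense_variant" in str(ann)
        if sidecar is not None:
            is_mis = is_mis or (v.CHROM, v.POS) in sidecar
        missense.append(is_mis)
        dp = v.INFO.get("DP")
        if dp is None:
            try:
                fmt_dp = v.format("DP")
            except KeyError:
                fmt_dp = None
            if fmt_dp is not None:
                dp = float(np.nanmean(np.where(fmt_dp < 0, np.nan, fmt_dp)))
        if dp is not None:
            any_depth = True
            depths.append(float(dp))
        else:
            depths.append(np.nan)
        geno_rows.append(_GT_CODE[v.gt_types])
    if not geno_rows:
        raise ValueError(f"{path}: no biallelic SNP records found")
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/indel records", n_skipped)
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "missense": missense,
        }
    )
    if any_depth:
        variants["depth"] = depths
    return GenotypeMatrix(
        samples=samples,
        populations=np.asarray([popmap[s] for s in samples], dtype=object),
        variants=variants,
        genotypes=np.vstack(geno_rows),
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> Path:
    """Write a minimal VCF 4.2 with GT fields (deterministic output)."""
    path = Path(path)
    depth = gm.variants["depth"].to_numpy() if "depth" in gm.variants else None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popscan\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in dict.fromkeys(gm.variants["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n'
        )
        if depth is not None:
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        chrom = gm.variants["chrom"].to_numpy()
        pos = gm.variants["pos"].to_numpy()
        ref = gm.variants["ref"].to_numpy()
        alt = gm.variants["alt"].to_numpy()
        mis = gm.variants["missense"].to_numpy()
        for i in range(gm.n_variants):
            info_parts = []
            if mis[i]:
                info_parts.append(f"ANN={alt[i]}|missense_variant|MODERATE|gene")
            if depth is not None and np.isfinite(depth[i]):
                info_parts.append(f"DP={int(depth[i])}")
            info = ";".join(info_parts) if info_parts else "."
            gts = "\t".join(_GT_STR[int(g)] for g in gm.genotypes[i])
            fh.write(
                f"{chrom[i]}\t{pos[i]}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )
    return path


def filter_sites(
    gm: GenotypeMatrix,
    max_missing: float = 0.10,
    min_depth: float | None = 4,
    max_depth: float | None = 500,
    min_maf: float = 0.0,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply per-site filters; returns the filtered matrix and a rule report.

    A site is removed when its missing rate is strictly above ``max_missing``,
    its depth is strictly below ``min_depth`` or strictly above ``max_depth``
    (depth filter active only when depth is available and bounds are not
    None), or (when ``min_maf`` > 0) its overall minor-allele frequency is
    not strictly above ``min_maf``.  Idempotent by construction.
    """
    n = gm.n_variants
    keep = np.ones(n, dtype=bool)
    report = {"input": n}
    miss_rate = (gm.genotypes == MISSING).mean(axis=1)
    bad_missing = miss_rate > max_missing
    report["missing"] = int(bad_missing.sum())
    keep &= ~bad_missing
    if "depth" in gm.variants.columns and (min_depth is not None or max_depth is not None):
        depth = gm.variants["depth"].to_numpy(dtype=float)
        bad_depth = np.zeros(n, dtype=bool)
        finite = np.isfinite(depth)
        if min_depth is not None:
            bad_depth |= finite & (depth < min_depth)
        if max_depth is not None:
            bad_depth |= finite & (depth > max_depth)
        report["depth"] = int(bad_depth.sum())
        keep &= ~bad_depth
    else:
        report["depth"] = 0
    if min_maf > 0:
        j, ntot = gm.allele_counts(np.arange(gm.n_samples))
        with np.errstate(divide="ignore", invalid="ignore"):
            af = np.where(ntot > 0, j / np.maximum(ntot, 1), 0.0)
        maf = np.minimum(af, 1.0 - af)
        bad_maf = ~(maf > min_maf)
        report["maf"] = int(bad_maf.sum())
        keep &= ~bad_maf
    else:
        report["maf"] = 0
    report["kept"] = int(keep.sum())
    if report["kept"] == 0:
        raise ValueError(
            "all sites removed by filters; review max_missing/depth/maf thresholds"
        )
    return gm.take_variants(keep), report


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open) or GFF3 (1-based, gene rows).

    Returns a DataFrame with columns chrom, start, end (internal 0-based
    half-open) and gene_id.  Overlapping genes are preserved as distinct
    records.
    """
    path = Path(path)
    rows: list[dict] = []
    is_gff = path.suffix.lower() in (".gff", ".gff3")
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            if is_gff:
                if len(parts) < 9:
                    raise ValueError("expected 9 GFF3 columns")
                if parts[2].lower() != "gene":
                    continue
                start1, end1 = int(parts[3]), int(parts[4])
                gene_id = f"line{ln}"
                for kv in parts[8].split(";"):
                    if kv.startswith("ID="):
                        gene_id = kv[3:]
                        break
                rows.append(
                    {"chrom": parts[0], "start": start1 - 1, "end": end1, "gene_id": gene_id}
                )
            else:
                parts = line.split()  # BED tolerates any whitespace
                if len(parts) < 3:
                    raise ValueError("expected >=3 BED columns")
                start0, end0 = int(parts[1]), int(parts[2])
                gene_id = parts[3] if len(parts) > 3 else f"interval{ln}"
                rows.append(
                    {"chrom": parts[0], "start": start0, "end": end0, "gene_id": gene_id}
                )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed line {ln}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no intervals found")
    out = pd.DataFrame(rows)
    if (out["start"] < 0).any() or (out["end"] <= out["start"]).any():
        bad = out.index[(out["start"] < 0) | (out["end"] <= out["start"])][0]
        raise ValueError(f"{path}: invalid interval at record {bad + 1}")
    return out
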