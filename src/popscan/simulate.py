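"""Synthetic genotype datasets with known population structure.

The generator follows the Balding–Nichols model: each segregating site has an
ancestral frequency ``p0`` drawn from a neutral-like spectrum (density
proportional to 1/x on ``[eps, 1-eps]``) and each population k draws its own
frequency ``p_k ~ Beta(p0 (1-F_k)/F_k, (1-p0)(1-F_k)/F_k)``, so that
``E[p_k] = p0`` and ``Var(p_k | p0) = F_k p0 (1-p0)``.  Two populations
drifted with the same F have expected Weir–Cockerham F_ST close to F, and the
expected per-site heterozygosity is ``2 p0 (1-p0) (1-F)`` — both are exposed
as closed-form oracles by :func:`analytic_expectations`.

Planted features:

* **sweeps** — inside a sweep region the target population's frequencies are
  re-drawn with ``F_sweep`` instead of its background F, giving an expected
  within-region diversity ratio ``(1-F_sweep)/(1-F_bg)``;
* **inversions** — each sample carries ``g ~ Binomial(2, q)`` copies of the
  inverted arrangement; a fraction ``marker_frac`` of SNPs inside the region
  are markers whose haplotype alleles equal the inversion allele (flipped
  with probability ``marker_error``), producing the three-cluster PCA /
  elevated-heterozygosity / LD-block signature of a real inversion;
* **Z chromosome** — the flagged chromosome's SNP density is scaled by
  ``z_density_scale`` (default 3/4, the neutral expectation for a
  female-heterogametic sex chromosome), so the expected per-bp diversity
  ratio Z/autosome equals the scaling factor exactly.

Linkage disequilibrium is optional: ``ld_mode="independent"`` draws genotypes
site-by-site under Hardy–Weinberg; ``ld_mode="copula"`` builds haplotypes from
a latent Gaussian process with correlation ``exp(-d/lambda)`` between sites
``d`` bp apart, thresholded to the per-site marginal frequency.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .core import MISSING, GenotypeMatrix

__all__ = [
    "SweepSpec",
    "InversionSpec",
    "SimConfig",
    "SimTruth",
    "draw_site_frequencies",
    "simulate_genotypes",
    "simulate_dataset",
    "write_dataset",
    "analytic_expectations",
]


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: the target population drifts with ``f_sweep`` here."""

    population: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    f_sweep: float


@dataclass(frozen=True)
class InversionSpec:
    """A planted inversion haplotype block."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    freq: float  # inversion-allele frequency q
    marker_frac: float = 0.25
    marker_error: float = 0.0


@dataclass
class SimConfig:
    """Full description of one synthetic dataset.

    Defaults emulate the study system this package was built around: three
    moderately diverged populations (background F ~ 0.15, the genome-wide
    differentiation scale of the refugial/colonized moth populations), SNP
    density of 0.01 per bp (the study called ~6.3M SNPs on a 518 Mb genome)
    and a Z chromosome carrying 3/4 of the autosomal diversity.
    """

    chromosomes: dict[str, int]
    populations: dict[str, int]
    drift: dict[str, float] = field(default_factory=dict)  # per-pop F_k
    freq_floor: float = 0.01
    snp_density: float = 0.01
    z_chrom: str | None = None
    z_density_scale: float = 0.75
    ld_mode: str = "independent"  # or "copula"
    ld_lambda: float = 1000.0  # bp
    sweeps: list[SweepSpec] = field(default_factory=list)
    inversions: list[InversionSpec] = field(default_factory=list)
    missense_prob: float = 0.02
    gene_length: int = 2_000
    intergenic_gap: int = 3_000
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pop in self.populations:
            self.drift.setdefault(pop, 0.15)
        for pop, f in self.drift.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"drift F for {pop} must be in [0, 1), got {f}")
        for frac in (self.freq_floor, self.missense_prob, self.missing_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 < self.freq_floor < 0.5:
            raise ValueError("freq_floor must be in (0, 0.5)")
        if self.ld_mode not in ("independent", "copula"):
            raise ValueError(f"unknown ld_mode {self.ld_mode!r}")
        if self.z_chrom is not None and self.z_chrom not in self.chromosomes:
            raise ValueError(f"z_chrom {self.z_chrom!r} not among chromosomes")
        for sw in self.sweeps:
            if sw.population not in self.populations:
                raise ValueError(f"sweep targets unknown population {sw.population!r}")
            self._check_region(sw.chrom, sw.start, sw.end)
            if sw.f_sweep <= self.drift[sw.population]:
                raise ValueError("sweep F must exceed the background F of its population")
        for inv in self.inversions:
            self._check_region(inv.chrom, inv.start, inv.end)
            if not 0.0 <= inv.freq <= 1.0 or not 0.0 <= inv.marker_frac <= 1.0:
                raise ValueError("inversion freq and marker_frac must lie in [0, 1]")
            if not 0.0 <= inv.marker_error <= 1.0:
                raise ValueError("inversion marker_error must lie in [0, 1]")

    def _check_region(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.chromosomes:
            raise ValueError(f"region on unknown chromosome {chrom!r}")
        if not 1 <= start <= end <= self.chromosomes[chrom]:
            raise ValueError(f"region {chrom}:{start}-{end} outside chromosome bounds")


@dataclass
class SimTruth:
    """Ground truth of the planted features, for recovery tests and reports."""

    sweeps: list[SweepSpec]
    inversions: list[InversionSpec]
    inversion_genotypes: dict[str, dict[str, int]]  # region key -> sample -> 0/1/2
    drift: dict[str, float]
    ld_lambda: float
    z_chrom: str | None
    z_density_scale: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sweeps": [dataclasses.asdict(s) for s in self.sweeps],
            "inversions": [dataclasses.asdict(i) for i in self.inversions],
            "inversion_genotypes": self.inversion_genotypes,
            "drift": self.drift,
            "ld_lambda": self.ld_lambda,
            "z_chrom": self.z_chrom,
            "z_density_scale": self.z_density_scale,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            sweeps=[SweepSpec(**s) for s in d["sweeps"]],
            inversions=[InversionSpec(**i) for i in d["inversions"]],
            inversion_genotypes=d["inversion_genotypes"],
            drift=d["drift"],
            ld_lambda=d["ld_lambda"],
            z_chrom=d["z_chrom"],
            z_density_scale=d["z_density_scale"],
        )


def _region_key(inv: InversionSpec) -> str:
    return f"{inv.chrom}:{inv.start}-{inv.end}"


def _bn_draw(rng: np.random.Generator, p0: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols frequency draw; F=0 is the no-drift degenerate limit."""
    if f == 0.0:
        return p0.copy()
    scale = (1.0 - f) / f
    return rng.beta(p0 * scale, (1.0 - p0) * scale)


def draw_site_frequencies(config: SimConfig) -> pd.DataFrame:
    """Sample segregating-site positions and per-population frequencies.

    Returns one row per site with columns ``chrom``, ``pos`` (1-based),
    ``p0``, one ``p_<pop>`` column per population, and ``marker`` flagging
    inversion-marker SNPs (their genotypes are overridden downstream).
    """
    rng = np.random.default_rng(config.seed)
    frames: list[pd.DataFrame] = []
    for chrom, length in config.chromosomes.items():
        rate = config.snp_density
        if chrom == config.z_chrom:
            rate *= config.z_density_scale
        # one Bernoulli per bp: positions unique and sorted by construction
        pos = np.flatnonzero(rng.random(length) < rate) + 1
        n = pos.size
        eps = config.freq_floor
        # inverse-CDF sample from density c/x on [eps, 1-eps]
        p0 = eps * ((1.0 - eps) / eps) ** rng.random(n)
        cols: dict[str, np.ndarray] = {"chrom": np.full(n, chrom, dtype=object), "pos": pos, "p0": p0}
        for pop in config.populations:
            cols[f"p_{pop}"] = _bn_draw(rng, p0, config.drift[pop])
        frame = pd.DataFrame(cols)
        for sw in config.sweeps:
            if sw.chrom != chrom:
                continue
            in_region = (pos >= sw.start) & (pos <= sw.end)
            if in_region.any():
                frame.loc[in_region, f"p_{sw.population}"] = _bn_draw(
                    rng, p0[in_region], sw.f_sweep
                )
        marker = np.zeros(n, dtype=bool)
        for inv in config.inversions:
            if inv.chrom != chrom:
                continue
            in_region = (pos >= inv.start) & (pos <= inv.end)
            marker |= in_region & (rng.random(n) < inv.marker_frac)
        frame["marker"] = marker
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _copula_haplotypes(
    rng: np.random.Generator,
    pos: np.ndarray,
    p_site: np.ndarray,
    n_haplotypes: int,
    lam: float,
) -> np.ndarray:
    """Haplotype alleles with latent-Gaussian correlation exp(-d/lambda).

    ``p_site`` is (n_sites, n_haplotypes): the marginal alt frequency each
    haplotype's population assigns to each site.  The latent chain is AR(1)
    in physical distance, so the correlation between any two sites is the
    product of the per-gap factors, i.e. exp(-total distance / lambda).
    """
    n_sites = pos.size
    z = np.empty((n_sites, n_haplotypes))
    z[0] = rng.standard_normal(n_haplotypes)
    rho = np.exp(-np.diff(pos) / lam)
    innov = rng.standard_normal((n_sites - 1, n_haplotypes)) if n_sites > 1 else None
    for i in range(1, n_sites):
        z[i] = rho[i - 1] * z[i - 1] + math.sqrt(1.0 - rho[i - 1] ** 2) * innov[i - 1]
    thresh = ndtri(np.clip(p_site, 1e-12, 1.0 - 1e-12))
    return (z < thresh).astype(np.int8)


def simulate_genotypes(
    freq_table: pd.DataFrame, config: SimConfig
) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw diploid genotypes from the site-frequency table.

    Independent mode draws ``Binomial(2, p_k)`` per site (Hardy–Weinberg);
    copula mode builds two correlated haplotypes per sample.  Inversion
    regions override marker-SNP genotypes from each sample's inversion
    genotype.  A second RNG stream keyed off the seed keeps the genotype
    draw reproducible regardless of how the frequency table was produced.
    """
    rng = np.random.default_rng(config.seed + 1)
    samples: list[str] = []
    pops: list[str] = []
    for pop, n in config.populations.items():
        samples.extend(f"{pop}_{i:03d}" for i in range(n))
        pops.extend([pop] * n)
    pop_arr = np.asarray(pops, dtype=object)
    n_samples = len(samples)

    for inv in config.inversions:
        n_in = int(
            (
                (freq_table["chrom"] == inv.chrom)
                & (freq_table["pos"] >= inv.start)
                & (freq_table["pos"] <= inv.end)
            ).sum()
        )
        if n_in < 20:
            raise ValueError(
                f"inversion {_region_key(inv)} spans only {n_in} SNPs; "
                "at least 20 are required to support 100-SNP-window detection"
            )

    geno = np.empty((len(freq_table), n_samples), dtype=np.int8)
    chrom_order = list(dict.fromkeys(freq_table["chrom"]))
    for chrom in chrom_order:
        rows = np.flatnonzero(freq_table["chrom"].to_numpy() == chrom)
        pos = freq_table["pos"].to_numpy()[rows]
        p_pop = {
            pop: freq_table[f"p_{pop}"].to_numpy()[rows] for pop in config.populations
        }
        p_site = np.column_stack([p_pop[p] for p in pop_arr])  # sites x samples
        if config.ld_mode == "independent":
            geno[rows] = rng.binomial(2, p_site).astype(np.int8)
        else:
            p_hap = np.repeat(p_site, 2, axis=1)
            haps = _copula_haplotypes(rng, pos, p_hap, 2 * n_samples, config.ld_lambda)
            geno[rows] = (haps[:, 0::2] + haps[:, 1::2]).astype(np.int8)

    # plant inversions: marker SNPs track each sample's inversion genotype
    inversion_genotypes: dict[str, dict[str, int]] = {}
    marker = freq_table["marker"].to_numpy()
    chrom_col = freq_table["chrom"].to_numpy()
    pos_col = freq_table["pos"].to_numpy()
    for inv in config.inversions:
        g_inv = rng.binomial(2, inv.freq, size=n_samples)
        inversion_genotypes[_region_key(inv)] = {
            s: int(g) for s, g in zip(samples, g_inv)
        }
        rows = np.flatnonzero(
            marker & (chrom_col == inv.chrom) & (pos_col >= inv.start) & (pos_col <= inv.end)
        )
        if rows.size == 0:
            continue
        hap1 = (g_inv >= 1).astype(np.int8)
        hap2 = (g_inv == 2).astype(np.int8)
        base = np.broadcast_to(hap1 + hap2, (rows.size, n_samples))
        if inv.marker_error > 0:
            flip1 = rng.random((rows.size, n_samples)) < inv.marker_error
            flip2 = rng.random((rows.size, n_samples)) < inv.marker_error
            a1 = np.where(flip1, 1 - hap1, hap1)
            a2 = np.where(flip2, 1 - hap2, hap2)
            geno[rows] = (a1 + a2).astype(np.int8)
        else:
            geno[rows] = base.astype(np.int8)

    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = MISSING

    missense = rng.random(len(freq_table)) < config.missense_prob
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=len(freq_table))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(freq_table))) % 4
    variants = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": pos_col,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "missense": missense,
        }
    )
    gm = GenotypeMatrix(
        samples=samples, populations=pop_arr, variants=variants, genotypes=geno
    )
    truth = SimTruth(
        sweeps=list(config.sweeps),
        inversions=list(config.inversions),
        inversion_genotypes=inversion_genotypes,
        drift=dict(config.drift),
        ld_lambda=config.ld_lambda,
        z_chrom=config.z_chrom,
        z_density_scale=config.z_density_scale,
    )
    return gm, truth


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Convenience: frequencies + genotypes in one call."""
    return simulate_genotypes(draw_site_frequencies(config), config)


def _tile_genes(config: SimConfig) -> pd.DataFrame:
    """Tile genes along each chromosome (0-based half-open BED records)."""
    rows = []
    for chrom, length in config.chromosomes.items():
        start1, i = 1, 0
        while start1 + config.gene_length - 1 <= length:
            rows.append(
                {
                    "chrom": chrom,
                    "start": start1 - 1,
                    "end": start1 - 1 + config.gene_length,
                    "gene_id": f"gene_{chrom}_{i:05d}",
                }
            )
            start1 += config.gene_length + config.intergenic_gap
            i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def write_dataset(
    genotypes: GenotypeMatrix,
    truth: SimTruth,
    config: SimConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write VCF + popmap + gene BED + chromosome lengths + truth JSON.

    Output is deterministic: rerunning with the same config/seed produces
    byte-identical files.
    """
    from .io import write_vcf  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "data.vcf",
        "popmap": outdir / "popmap.tsv",
        "genes": outdir / "genes.bed",
        "chrom_lengths": outdir / "chrom_lengths.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(genotypes, paths["vcf"], contig_lengths=config.chromosomes)
    with open(paths["popmap"], "w") as fh:
        for s, p in zip(genotypes.samples, genotypes.populations):
            fh.write(f"{s}\t{p}\n")
    genes = _tile_genes(config)
    genes.to_csv(paths["genes"], sep="\t", header=False, index=False)
    with open(paths["chrom_lengths"], "w") as fh:
        for chrom, length in config.chromosomes.items():
            fh.write(f"{chrom}\t{length}\n")
    truth.to_json(paths["truth"])
    return paths


def analytic_expectations(config: SimConfig) -> dict:
    """Closed-form expectations implied by the generative model.

    Under the 1/x ancestral spectrum on [eps, 1-eps] the mean ancestral
    heterozygosity is ``E[2 p0 (1-p0)] = (1-2 eps) / ln((1-eps)/eps)``; drift
    multiplies it by ``(1-F)``, and per-bp diversity multiplies by SNP
    density (times the Z scaling on the Z chromosome).  Two populations with
    drift F1, F2 have expected F_ST ~ (F1+F2)/2; a sweep region's expected
    diversity ratio in the target population is (1-F_sweep)/(1-F_bg).
    """
    eps = config.freq_floor
    e_het0 = (1.0 - 2.0 * eps) / math.log((1.0 - eps) / eps)
    pops = list(config.populations)
    pi: dict[str, dict[str, float]] = {}
    for pop in pops:
        f = config.drift[pop]
        base = config.snp_density * e_het0 * (1.0 - f)
        pi[pop] = {"autosome": base, "z": base * config.z_density_scale}
    fst = {
        f"{a}__{b}": 0.5 * (config.drift[a] + config.drift[b])
        for i, a in enumerate(pops)
        for b in pops[i + 1 :]
    }
    sweep_ratios = {
        f"{sw.chrom}:{sw.start}-{sw.end}": (1.0 - sw.f_sweep)
        / (1.0 - config.drift[sw.population])
        for sw in config.sweeps
    }
    return {
        "ancestral_het": e_het0,
        "pi_per_bp": pi,
        "fst": fst,
        "sweep_pi_ratio": sweep_ratios,
        "pi_z_over_a": config.z_density_scale,
    }
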