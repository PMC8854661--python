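"""Core in-memory containers shared across the package.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open ``[start, end)``; everything
user-facing (VCF positions, reported window bounds) is 1-based inclusive.
:class:`WindowSpec` stores the internal convention and exposes ``start1`` /
``end1`` for reports.  Genotypes are stored as alt-allele counts
(0, 1, 2) with ``-1`` for missing, in a variants x samples int8 array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = ["MISSING", "GenotypeMatrix", "WindowSpec", "make_windows"]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic variants with per-variant metadata.

    Parameters
    ----------
    samples
        Sample identifiers, one per column of ``genotypes``.
    populations
        Population label per sample (aligned with ``samples``).
    variants
        One row per variant with at least ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt`` and a boolean ``missense`` column; an optional
        ``depth`` column carries per-site mean depth.
    genotypes
        ``(n_variants, n_samples)`` int8 array of alt-allele counts,
        ``-1`` meaning missing.
    """

    samples: list[str]
    populations: np.ndarray
    variants: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"genotype array {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if len(self.populations) != len(self.samples):
            raise ValueError("population labels must cover all samples")
        self.variants = self.variants.reset_index(drop=True)
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def sample_indices(self, population: str | Sequence[str]) -> np.ndarray:
        """Column indices of samples belonging to ``population``."""
        if isinstance(population, str):
            idx = np.flatnonzero(self.populations == population)
            if idx.size == 0:
                raise ValueError(f"no samples in population {population!r}")
            return idx
        pops = set(population)
        idx = np.flatnonzero([p in pops for p in self.populations])
        if idx.size == 0:
            raise ValueError(f"no samples in populations {sorted(pops)!r}")
        return idx

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given variant rows (bool mask or ints)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            populations=self.populations.copy(),
            variants=self.variants.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index],
        )

    def variant_indices_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Row indices of variants inside 0-based half-open [start, end) on chrom."""
        on = self.variants["chrom"].to_numpy() == chrom
        rows = np.flatnonzero(on)
        pos0 = self.variants["pos"].to_numpy()[rows] - 1
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        return rows[lo:hi]

    def allele_counts(self, population: str | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-site alt-allele count ``j`` and called-allele count ``n``.

        ``population`` may be a label or an explicit array of column indices.
        """
        if isinstance(population, str):
            cols = self.sample_indices(population)
        else:
            cols = np.asarray(population)
        g = self.genotypes[:, cols]
        called = g >= 0
        n = 2 * called.sum(axis=1)
        j = np.where(called, g, 0).sum(axis=1)
        return j.astype(np.int64), n.astype(np.int64)


@dataclass(frozen=True)
class WindowSpec:
    """A genomic window, stored 0-based half-open."""

    chrom: str
    start: int
    end: int

    @property
    def start1(self) -> int:
        """1-based inclusive start."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """1-based inclusive end."""
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(
    chrom_lengths: Mapping[str, int],
    size: int = 50_000,
    step: int = 10_000,
    emit_truncated: bool = False,
) -> list[WindowSpec]:
    """Sliding windows tiling each chromosome from its first base.

    Windows start at 1, 1+step, ... (1-based); by default only windows that
    fit entirely on the chromosome are emitted; with ``emit_truncated`` the
    trailing partial windows (>= 1 bp) are included, truncated at the
    chromosome end.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if size <= 0:
        raise ValueError("size must be positive")
    if step > size:
        raise ValueError("step must not exceed window size")
    windows: list[WindowSpec] = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            end = start + size
            if end <= length:
                windows.append(WindowSpec(chrom, start, end))
            elif emit_truncated:
                windows.append(WindowSpec(chrom, start, length))
            start += step
    return windows
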