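"""Zygosity calling and kernel-density localization of the causal mutation.

In a phenotype-sorted F2 mutant pool the mutagenized haplotype is fixed at
the causal locus, so strain-diagnostic SNPs near it read as homozygous for
the alternate allele while unlinked SNPs segregate 1:1.  Plotting the
density of homozygous SNP positions along each chromosome therefore peaks
over the mutation.  This module calls pool zygosity from allele depths and
builds equal-weight Gaussian kernel density profiles per chromosome and
zygosity class, plus the classic smoothed allele-frequency curve.

The kernel is Gaussian with a megabase-scale default bandwidth (the
mapping resolution of a 30-embryo pool); no boundary correction is applied,
so a little kernel mass is lost off the chromosome ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .variant_io import Variant, VariantTable

DEFAULT_MIN_DEPTH = 5
DEFAULT_HOM_THRESHOLD = 0.9
DEFAULT_BANDWIDTH = 1_000_000  # bp
DEFAULT_GRID_STEP = 10_000  # bp

_SQRT2PI = float(np.sqrt(2.0 * np.pi))


class MappingError(ValueError):
    """No variants of the requested zygosity class are available."""


@dataclass(frozen=True)
class KDEProfile:
    """Smoothed density of variant positions of one zygosity class.

    ``density`` has units 1/bp; its integral over the chromosome is at
    most 1 (mass beyond the ends is truncated, not reflected).
    """

    chrom: str
    grid: np.ndarray  # positions, bp
    density: np.ndarray  # 1/bp
    bandwidth: float
    zygosity_class: str

    def peak(self) -> tuple[int, float]:
        """(position, height) of the profile maximum; leftmost on ties."""
        i = int(np.argmax(self.density))
        return int(self.grid[i]), float(self.density[i])


@dataclass(frozen=True)
class MappingResult:
    """Per-chromosome KDE profiles with the global peak and its interval."""

    profiles: dict[tuple[str, str], KDEProfile]  # (chrom, zygosity_class)
    peak: tuple[str, int, float]  # chrom, pos bp, height
    interval: tuple[str, int, int]  # chrom, start bp, end bp

    def profile(self, chrom: str, zygosity_class: str = "hom_alt") -> KDEProfile:
        return self.profiles[(chrom, zygosity_class)]


def call_zygosity(
    v: Variant,
    min_depth: int = DEFAULT_MIN_DEPTH,
    hom_threshold: float = DEFAULT_HOM_THRESHOLD,
) -> str:
    """Call pool zygosity from allele depths.

    ``low_confidence`` below ``min_depth`` total reads (including zero
    depth); ``hom_alt`` when the alt read fraction reaches
    ``hom_threshold``; ``het`` otherwise.
    """
    depth = v.total_depth
    if depth < min_depth:
        return "low_confidence"
    if v.alt_depth / depth >= hom_threshold:
        return "hom_alt"
    return "het"


def assign_zygosity(
    table: VariantTable,
    min_depth: int = DEFAULT_MIN_DEPTH,
    hom_threshold: float = DEFAULT_HOM_THRESHOLD,
) -> VariantTable:
    """Return a table with zygosity called on every record."""
    return VariantTable.from_records(
        v.with_zygosity(call_zygosity(v, min_depth, hom_threshold)) for v in table
    )


def _grid(chrom_length: int, grid_step: int) -> np.ndarray:
    return np.arange(1, chrom_length + 1, grid_step, dtype=np.int64)


def _gaussian_density(
    positions: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Equal-weight Gaussian mixture evaluated at grid points, chunked."""
    n = len(positions)
    density = np.zeros(len(grid), dtype=np.float64)
    gridf = grid.astype(np.float64)
    for start in range(0, n, 512):
        block = positions[start : start + 512].astype(np.float64)
        z = (gridf[:, None] - block[None, :]) / bandwidth
        density += np.exp(-0.5 * z * z).sum(axis=1)
    density /= n * bandwidth * _SQRT2PI
    return density


def kde_profile(
    positions: Sequence[int],
    chrom_length: int,
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_step: int = DEFAULT_GRID_STEP,
    chrom: str = "",
    zygosity_class: str = "hom_alt",
) -> KDEProfile:
    """Gaussian kernel density of variant positions on one chromosome.

    Equal weights 1/n, no boundary correction; evaluated at grid points
    1, 1+step, ... up to the chromosome length.
    """
    if len(positions) == 0:
        raise MappingError("no variants of requested class on chromosome")
    pos = np.asarray(positions, dtype=np.int64)
    if pos.min() < 1 or pos.max() > chrom_length:
        raise ValueError("positions outside [1, chrom_length]")
    grid = _grid(chrom_length, grid_step)
    density = _gaussian_density(pos, grid, float(bandwidth))
    return KDEProfile(chrom, grid, density, float(bandwidth), zygosity_class)


def _half_height_interval(profile: KDEProfile) -> tuple[int, int]:
    """Maximal contiguous grid run around the peak at >= half peak height."""
    i = int(np.argmax(profile.density))
    half = 0.5 * profile.density[i]
    lo = i
    while lo > 0 and profile.density[lo - 1] >= half:
        lo -= 1
    hi = i
    while hi < len(profile.grid) - 1 and profile.density[hi + 1] >= half:
        hi += 1
    return int(profile.grid[lo]), int(profile.grid[hi])


def mapping_profiles(
    table: VariantTable,
    chrom_lengths: Mapping[str, int],
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_step: int = DEFAULT_GRID_STEP,
) -> MappingResult:
    """Build hom/het density profiles per chromosome and locate the peak.

    The peak is the global argmax over the hom_alt profiles (leftmost grid
    point on ties; lexicographic chromosome order on cross-chromosome
    ties); the interval is the contiguous grid run around the peak with
    hom_alt density at least half the peak height.
    """
    profiles: dict[tuple[str, str], KDEProfile] = {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        for zcls in ("hom_alt", "het"):
            positions = [v.pos for v in table if v.chrom == chrom and v.zygosity == zcls]
            if positions:
                profiles[(chrom, zcls)] = kde_profile(
                    positions, length, bandwidth, grid_step, chrom=chrom,
                    zygosity_class=zcls,
                )
    hom_profiles = {c: p for (c, z), p in profiles.items() if z == "hom_alt"}
    if not hom_profiles:
        raise MappingError("no hom_alt variants on any chromosome")
    best: tuple[str, int, float] | None = None
    for chrom in sorted(hom_profiles):
        pos, height = hom_profiles[chrom].peak()
        if best is None or height > best[2]:
            best = (chrom, pos, height)
    assert best is not None
    lo, hi = _half_height_interval(hom_profiles[best[0]])
    return MappingResult(profiles, best, (best[0], lo, hi))


def export_profiles_tsv(
    result: MappingResult,
    path,
    alt_fraction: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
    header_lines: Sequence[str] = (),
) -> None:
    """Write profiles as TSV: chrom, pos, hom_density, het_density,
    smoothed_alt_fraction (empty where a class has no variants)."""
    chroms = sorted({c for c, _ in result.profiles})
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# chrom\tpos\thom_density\thet_density\tsmoothed_alt_fraction\n")
        for chrom in chroms:
            hom = result.profiles.get((chrom, "hom_alt"))
            het = result.profiles.get((chrom, "het"))
            grid = (hom or het).grid
            af = alt_fraction.get(chrom) if alt_fraction else None
            for i, pos in enumerate(grid):
                hom_d = f"{hom.density[i]:.6e}" if hom is not None else ""
                het_d = f"{het.density[i]:.6e}" if het is not None else ""
                af_v = f"{af[1][i]:.6f}" if af is not None else ""
                fh.write(f"{chrom}\t{pos}\t{hom_d}\t{het_d}\t{af_v}\n")


def allele_frequency_profile(
    table: VariantTable,
    chrom_lengths: Mapping[str, int],
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_step: int = DEFAULT_GRID_STEP,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Smoothed per-variant alt-allele fraction along each chromosome.

    Classic variant-discovery-mapping mode: Nadaraya–Watson regression of
    the alt read fraction on position with the same Gaussian kernel,
    returned as {chrom: (grid, smoothed fraction)}.
    """
    if len(table) == 0:
        raise MappingError("empty variant table")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in sorted(chrom_lengths):
        recs = [v for v in table if v.chrom == chrom]
        if not recs:
            continue
        pos = np.array([v.pos for v in recs], dtype=np.float64)
        frac = np.array([v.alt_fraction for v in recs], dtype=np.float64)
        grid = _grid(chrom_lengths[chrom], grid_step)
        gridf = grid.astype(np.float64)
        num = np.zeros(len(grid))
        den = np.zeros(len(grid))
        for start in range(0, len(pos), 512):
            p = pos[start : start + 512]
            f = frac[start : start + 512]
            z = (gridf[:, None] - p[None, :]) / float(bandwidth)
            w = np.exp(-0.5 * z * z)
            num += (w * f[None, :]).sum(axis=1)
            den += w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            smooth = np.where(den > 0, num / den, np.nan)
        out[chrom] = (grid, smooth)
    return out
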