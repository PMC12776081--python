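"""Genomic filter masks for recurrent-SCNA scanning.

The scan for recurrently altered loci excludes territory prone to
artefactual copy-number calls or confounded by cohort composition:
centromeres, the 5 Mb adjacent to each telomere, the HLA region, the short
arms of the acrocentric chromosomes (13, 14, 15, 21, 22), and the X and Y
chromosomes.  A default mask with GRCh38-like coordinates is built from the
embedded tables below; any mask can be overridden with a BED file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._intervals import merge, overlap_length, subtract, total_length

TELOMERE_PAD = 5_000_000

# GRCh38 chromosome lengths and approximate centromere spans (bp).
GRCH38_CHROMS = {
    "chr1": (248_956_422, (121_700_000, 125_100_000)),
    "chr2": (242_193_529, (91_800_000, 96_000_000)),
    "chr3": (198_295_559, (87_800_000, 94_000_000)),
    "chr4": (190_214_555, (48_200_000, 51_800_000)),
    "chr5": (181_538_259, (46_100_000, 50_000_000)),
    "chr6": (170_805_979, (58_500_000, 62_600_000)),
    "chr7": (159_345_973, (58_100_000, 62_100_000)),
    "chr8": (145_138_636, (43_200_000, 47_200_000)),
    "chr9": (138_394_717, (42_200_000, 45_500_000)),
    "chr10": (133_797_422, (38_000_000, 41_600_000)),
    "chr11": (135_086_622, (51_000_000, 55_800_000)),
    "chr12": (133_275_309, (33_200_000, 37_800_000)),
    "chr13": (114_364_328, (16_500_000, 18_900_000)),
    "chr14": (107_043_718, (16_100_000, 18_200_000)),
    "chr15": (101_991_189, (17_500_000, 20_500_000)),
    "chr16": (90_338_345, (35_300_000, 38_400_000)),
    "chr17": (83_257_441, (22_700_000, 27_400_000)),
    "chr18": (80_373_285, (15_400_000, 21_500_000)),
    "chr19": (58_617_616, (24_200_000, 28_100_000)),
    "chr20": (64_444_167, (25_700_000, 30_400_000)),
    "chr21": (46_709_983, (10_900_000, 13_000_000)),
    "chr22": (50_818_468, (13_700_000, 17_400_000)),
    "chrX": (156_040_895, (58_100_000, 63_800_000)),
    "chrY": (57_227_415, (10_300_000, 10_600_000)),
}
GRCH38_HLA = ("chr6", 28_510_000, 33_480_000)
ACROCENTRIC = ("chr13", "chr14", "chr15", "chr21", "chr22")


@dataclass
class FilterMask:
    """Excluded genomic territory, held per chromosome as merged
    non-overlapping half-open intervals, plus the chromosome sizes of the
    genome it applies to."""

    chrom_lengths: dict
    excluded: dict = field(default_factory=dict)

    def __post_init__(self):
        self.excluded = {c: merge(iv) for c, iv in self.excluded.items() if iv}

    @property
    def autosomes(self):
        return [c for c in self.chrom_lengths
                if c not in ("chrX", "chrY")]

    def retained(self, chrom: str):
        """Unmasked intervals of one chromosome."""
        if chrom in ("chrX", "chrY"):
            return []
        full = [(0, self.chrom_lengths[chrom])]
        return subtract(full, self.excluded.get(chrom, []))

    def retained_length(self, chrom: str) -> int:
        return total_length(self.retained(chrom))

    def total_retained(self) -> int:
        return sum(self.retained_length(c) for c in self.autosomes)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom in ("chrX", "chrY") or chrom not in self.chrom_lengths:
            return True
        return any(overlap_length(start, end, a, b) > 0
                   for a, b in self.excluded.get(chrom, []))

    def clip(self, chrom: str, start: int, end: int):
        """Intersect an interval with the retained territory."""
        if chrom in ("chrX", "chrY") or chrom not in self.chrom_lengths:
            return []
        out = []
        for a, b in self.retained(chrom):
            lo, hi = max(start, a), min(end, b)
            if hi > lo:
                out.append((lo, hi))
        return out

    @classmethod
    def from_bed(cls, path: str, chrom_lengths: dict) -> "FilterMask":
        bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                          usecols=[0, 1, 2],
                          names=["chrom", "start", "end"])
        excluded: dict[str, list] = {}
        for _, row in bed.iterrows():
            chrom = row["chrom"] if str(row["chrom"]).startswith("chr") \
                else "chr" + str(row["chrom"])
            excluded.setdefault(chrom, []).append(
                (int(row["start"]), int(row["end"])))
        return cls(chrom_lengths=dict(chrom_lengths), excluded=excluded)

    def to_bed(self, path: str):
        with open(path, "w") as handle:
            for chrom, intervals in sorted(self.excluded.items()):
                for start, end in intervals:
                    handle.write(f"{chrom}\t{start}\t{end}\n")


def standard_mask(chrom_lengths: dict, centromeres: dict,
                  hla: tuple | None = None,
                  acrocentric: tuple = ACROCENTRIC,
                  telomere_pad: int = TELOMERE_PAD) -> FilterMask:
    """Build the exclusion mask from its component loci."""
    excluded: dict[str, list] = {c: [] for c in chrom_lengths}
    for chrom, length in chrom_lengths.items():
        if chrom in ("chrX", "chrY"):
            excluded[chrom].append((0, length))
            continue
        cen = centromeres.get(chrom)
        if cen is not None:
            excluded[chrom].append(tuple(cen))
        excluded[chrom].append((0, min(telomere_pad, length)))
        excluded[chrom].append((max(0, length - telomere_pad), length))
        if chrom in acrocentric and cen is not None:
            excluded[chrom].append((0, cen[1]))   # whole short arm
    if hla is not None:
        chrom, start, end = hla
        excluded.setdefault(chrom, []).append((start, end))
    return FilterMask(chrom_lengths=dict(chrom_lengths), excluded=excluded)


def default_grch38_mask() -> FilterMask:
    lengths = {c: l for c, (l, _) in GRCH38_CHROMS.items()}
    centromeres = {c: cen for c, (_, cen) in GRCH38_CHROMS.items()}
    return standard_mask(lengths, centromeres, hla=GRCH38_HLA)


# ---------------------------------------------------------------------------
# Miniature genome for simulation and fast scans

MINI_CHROM_MB = 100
MINI_N_CHROMS = 22


def miniature_genome(n_chroms: int = MINI_N_CHROMS,
                     chrom_mb: int = MINI_CHROM_MB) -> dict:
    """Chromosome lengths of the scaled-down simulation genome
    (autosomes only; 22 x 100 Mb by default)."""
    mb = 1_000_000
    return {f"chr{i}": chrom_mb * mb for i in range(1, n_chroms + 1)}


def miniature_mask(n_chroms: int = MINI_N_CHROMS,
                   chrom_mb: int = MINI_CHROM_MB) -> FilterMask:
    """Scaled mask for the miniature genome: centromere at mid-chromosome,
    5 Mb telomere pads, an HLA-like block on chr6, and full short-arm
    exclusion for the acrocentric-like chromosomes present."""
    mb = 1_000_000
    lengths = miniature_genome(n_chroms, chrom_mb)
    mid = chrom_mb // 2 * mb
    centromeres = {c: (mid - 2 * mb, mid + 2 * mb) for c in lengths}
    acro = tuple(c for c in ACROCENTRIC if c in lengths)
    hla = ("chr6", 25 * mb, 30 * mb) if "chr6" in lengths else None
    return standard_mask(lengths, centromeres, hla=hla, acrocentric=acro)
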