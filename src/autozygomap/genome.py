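"""Genome model, marker panels and genotype matrices.

The genome is a set of named autosomes with physical lengths in bp
(default: 22 autosomes with lengths rounded from the human reference).
A :class:`MarkerPanel` emulates a genome-wide SNP genotyping array:
ordered 1-based marker positions with ref/alt alleles per chromosome.
Genotype calls use the 4-symbol code 0 = hom-ref, 1 = het, 2 = hom-alt,
-1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PanelError, SampleNotFoundError

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

#: Autosome lengths in Mb, rounded from the human reference assembly.
DEFAULT_CHROM_MB = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171,
    "7": 159, "8": 146, "9": 141, "10": 136, "11": 135, "12": 134,
    "13": 115, "14": 107, "15": 103, "16": 90, "17": 81, "18": 78,
    "19": 59, "20": 63, "21": 48, "22": 51,
}

DEFAULT_GENOME = {c: mb * 1_000_000 for c, mb in DEFAULT_CHROM_MB.items()}

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


def genome_length(genome: dict[str, int]) -> int:
    return int(sum(genome.values()))


@dataclass
class MarkerPanel:
    """Ordered marker positions (1-based bp) with alleles, per chromosome."""

    positions: dict[str, np.ndarray]
    ref: dict[str, np.ndarray] = field(default_factory=dict)
    alt: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.positions[chrom] = pos
            if pos.size < 2:
                raise PanelError(f"chromosome {chrom!r} has < 2 markers")
            if pos[0] < 1:
                raise PanelError(f"chromosome {chrom!r} has positions < 1")
            if np.any(np.diff(pos) <= 0):
                raise PanelError(f"positions on {chrom!r} not strictly increasing")
            if chrom not in self.ref:
                pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(pos.size)]
                self.ref[chrom] = np.array([p[0] for p in pairs])
                self.alt[chrom] = np.array([p[1] for p in pairs])

    @classmethod
    def uniform(cls, genome: dict[str, int], spacing_bp: int = 30_000) -> "MarkerPanel":
        """Evenly spaced panel: one marker every ``spacing_bp`` bp."""
        positions = {
            chrom: np.arange(spacing_bp, length + 1, spacing_bp, dtype=np.int64)
            for chrom, length in genome.items()
        }
        return cls(positions)

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    @property
    def n_markers(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    def require_chrom(self, chrom: str) -> np.ndarray:
        if chrom not in self.positions:
            raise PanelError(f"chromosome {chrom!r} absent from marker panel")
        return self.positions[chrom]

    def marker_ids(self, chrom: str) -> list[str]:
        return [f"{chrom}:{p}" for p in self.positions[chrom]]


@dataclass
class GenotypeMatrix:
    """Per-sample, per-marker genotype calls over a marker panel.

    ``data[chrom]`` is an int8 array of shape (n_samples, n_markers_chrom)
    with values in {0, 1, 2, -1}, rows ordered as ``samples``.
    """

    samples: list[str]
    panel: MarkerPanel
    data: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=np.int8)
            self.data[chrom] = arr
            npos = self.panel.require_chrom(chrom).size
            if arr.shape != (len(self.samples), npos):
                raise PanelError(
                    f"genotype block {chrom!r} shape {arr.shape} inconsistent "
                    f"with {len(self.samples)} samples x {npos} markers"
                )
            bad = ~np.isin(arr, (HOM_REF, HET, HOM_ALT, MISSING))
            if bad.any():
                raise PanelError(f"genotype block {chrom!r} has calls outside {{0,1,2,-1}}")

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise SampleNotFoundError(f"sample {sample!r} not in genotype matrix") from None

    def calls(self, sample: str, chrom: str) -> np.ndarray:
        """Genotype codes for one sample on one chromosome."""
        self.panel.require_chrom(chrom)
        if chrom not in self.data:
            raise PanelError(f"chromosome {chrom!r} absent from genotype matrix")
        return self.data[chrom][self.sample_index(sample)]

    def subset(self, samples: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeMatrix(
            samples=list(samples),
            panel=self.panel,
            data={c: a[idx] for c, a in self.data.items()},
        )
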