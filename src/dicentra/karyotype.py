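"""Reference human karyotype packaged as constants.

A 46,XX karyotype with GRCh38-scale chromosome lengths (Mbp) and
centromere midpoints (Mbp) is used for all genomic bookkeeping: chromosome
assignment probabilities, fragment intervals and centromere flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# (name, length in Mbp, centromere midpoint in Mbp), GRCh38 rounded to 0.1 Mbp
_HAPLOID_AUTOSOMES: list[tuple[str, float, float]] = [
    ("chr1", 249.0, 123.4),
    ("chr2", 242.2, 93.9),
    ("chr3", 198.3, 90.9),
    ("chr4", 190.2, 50.0),
    ("chr5", 181.5, 48.8),
    ("chr6", 170.8, 59.8),
    ("chr7", 159.3, 60.1),
    ("chr8", 145.1, 45.2),
    ("chr9", 138.4, 43.0),
    ("chr10", 133.8, 39.8),
    ("chr11", 135.1, 53.4),
    ("chr12", 133.3, 35.5),
    ("chr13", 114.4, 17.7),
    ("chr14", 107.0, 17.2),
    ("chr15", 102.0, 19.0),
    ("chr16", 90.3, 36.8),
    ("chr17", 83.3, 25.1),
    ("chr18", 80.4, 18.5),
    ("chr19", 58.6, 26.2),
    ("chr20", 64.4, 28.1),
    ("chr21", 46.7, 12.0),
    ("chr22", 50.8, 15.0),
]
_X = ("chrX", 156.0, 60.6)


@dataclass(frozen=True)
class Karyotype:
    """Ordered chromosome set: names, lengths and centromere positions.

    Invariants: one centromere strictly inside each chromosome, and
    ``total_mbp`` equal to the summed lengths.
    """

    names: tuple[str, ...]
    lengths_mbp: np.ndarray  # shape (n,)
    centromeres_mbp: np.ndarray  # shape (n,)
    total_mbp: float = field(init=False)

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths_mbp, dtype=float)
        cens = np.asarray(self.centromeres_mbp, dtype=float)
        if not (len(self.names) == lengths.shape[0] == cens.shape[0]):
            raise ValueError("names, lengths and centromeres must align")
        if np.any(lengths <= 0):
            raise ValueError("chromosome lengths must be positive")
        if np.any((cens <= 0) | (cens >= lengths)):
            raise ValueError("centromeres must lie strictly inside chromosomes")
        object.__setattr__(self, "lengths_mbp", lengths)
        object.__setattr__(self, "centromeres_mbp", cens)
        object.__setattr__(self, "total_mbp", float(lengths.sum()))

    def __len__(self) -> int:
        return len(self.names)

    @property
    def content_fractions(self) -> np.ndarray:
        """Per-chromosome DNA content fraction (sums to 1)."""
        return self.lengths_mbp / self.total_mbp

    @classmethod
    def human_female(cls) -> "Karyotype":
        """Diploid 46,XX karyotype (two copies of 1-22 and X)."""
        names: list[str] = []
        lengths: list[float] = []
        cens: list[float] = []
        for copy in ("a", "b"):
            for name, length, cen in _HAPLOID_AUTOSOMES + [_X]:
                names.append(f"{name}{copy}")
                lengths.append(length)
                cens.append(cen)
        return cls(tuple(names), np.array(lengths), np.array(cens))


HUMAN_FEMALE = Karyotype.human_female()
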