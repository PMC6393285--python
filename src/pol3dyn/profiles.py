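"""Average tag-density profiles (metagene plots) around locus anchors.

For a set of loci, the strand-oriented per-base weighted fragment coverage in
a window around the TSS is averaged across loci and depth-normalized to
fragments-per-million, then binned.  These are raw ChIP densities; no input
subtraction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import CoverageIndex

#: Half-width (bp) of the profile window around the anchor.
PROFILE_WINDOW = 2000
#: Averaging bin (bp).
PROFILE_BIN = 10


@dataclass
class Profile:
    """Binned average tag density around an anchor.

    ``offsets`` are bin start positions relative to the anchor (strand
    oriented: negative = upstream of the locus TSS); ``density`` is weighted
    fragment coverage per bp per locus per million fragments.
    """

    offsets: np.ndarray
    density: np.ndarray
    n_loci: int
    window: int
    bin_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "density": self.density})

    def half_integrals(self) -> tuple[float, float]:
        """(upstream, downstream) integrals of the density, in
        density x bp units."""
        up = self.density[self.offsets < 0].sum() * self.bin_size
        down = self.density[self.offsets >= 0].sum() * self.bin_size
        return float(up), float(down)


def tag_density_profile(frags, loci: pd.DataFrame,
                        chrom_sizes: dict[str, int] | None = None,
                        anchor: str = "tss",
                        window: int = PROFILE_WINDOW,
                        bin_size: int = PROFILE_BIN,
                        depth: float | None = None) -> Profile:
    """Average strand-oriented tag density around the loci's anchors.

    ``frags`` may be a fragment frame or a plain-coverage
    :class:`CoverageIndex` (``fractional=False``).  ``depth`` defaults to the
    sample's total weighted fragment mass and sets the per-million scale.
    """
    if len(loci) == 0:
        raise ValueError("empty locus set")
    if anchor != "tss":
        raise ValueError(f"unsupported anchor {anchor!r}")
    if 2 * window % bin_size != 0:
        raise ValueError("window must be a whole number of bins")
    if isinstance(frags, CoverageIndex):
        cov = frags
    else:
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required when passing raw fragments")
        cov = CoverageIndex(frags, chrom_sizes, fractional=False)
    if depth is None:
        depth = cov.total_mass
    if depth <= 0:
        depth = 1.0

    total = np.zeros(2 * window)
    for _, row in loci.iterrows():
        tss = int(row[anchor])
        arr = cov.density(row["chrom"], tss - window, tss + window)
        if row["strand"] == "-":
            arr = arr[::-1]
        total += arr
    mean = total / len(loci) / (depth / 1e6)
    binned = mean.reshape(-1, bin_size).mean(axis=1)
    offsets = np.arange(-window, window, bin_size)
    return Profile(offsets=offsets, density=binned, n_loci=len(loci),
                   window=window, bin_size=bin_size)
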