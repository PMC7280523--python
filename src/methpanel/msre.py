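"""MSRE-PCR amplicon design and band-pattern prediction.

An MSRE-PCR assay digests genomic DNA with a methylation-sensitive enzyme
(BstHHI, GCG/C) before PCR: a product amplifies from the digested template
only if every enzyme site inside it was methylated (protected). A usable
target therefore needs enough sites inside a small product (here >= 3 sites
within <= 200 bp) and site-free flanks (>= 50 bp) so primers can bind
sequence whose amplification does not itself depend on methylation.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from itertools import product as _cartesian
from math import prod
from typing import Sequence

BSTHHI_SITE = "GCGC"


@dataclass(frozen=True)
class AmpliconDesign:
    """A candidate PCR product interval with its enzyme-site bookkeeping."""

    chrom: str
    start: int
    end: int  # 0-based half-open
    site_positions: tuple[int, ...]
    left_clear_flank: int
    right_clear_flank: int
    overlaps_another: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)


def find_sites(seq: str, recognition: str = BSTHHI_SITE) -> list[int]:
    """Forward-strand occurrence start positions, overlapping occurrences
    included (GCGCGC contains two). The site is palindromic, so one strand
    suffices."""
    seq = seq.upper()
    recognition = recognition.upper()
    out = []
    i = seq.find(recognition)
    while i >= 0:
        out.append(i)
        i = seq.find(recognition, i + 1)
    return out


def find_amplicons(
    region: str,
    min_sites: int = 3,
    max_product_len: int = 200,
    min_clear_flank: int = 50,
    recognition: str = BSTHHI_SITE,
    chrom: str = "region",
) -> list[AmpliconDesign]:
    """All windows of the region satisfying the MSRE-PCR design constraints.

    A window [i, j) qualifies when (a) it fully contains at least
    ``min_sites`` occurrences of the recognition sequence, (b) its length is
    at most ``max_product_len``, and (c) the nearest occurrence outside the
    window (or the region edge, if none) is at least ``min_clear_flank`` bp
    from the window boundary on both sides. A site straddling a boundary
    yields a negative clearance and disqualifies the window. "At least"
    ``min_sites`` is deliberate: extra sites only add cleavage stringency.

    Designs are sorted by descending site count, then shorter product, then
    position; overlapping candidates are allowed but flagged.
    """
    m = len(recognition)
    n = len(region)
    sites = find_sites(region, recognition)
    designs: list[AmpliconDesign] = []
    for i in range(n):
        for j in range(max(i + 1, i + min_sites * m), min(n, i + max_product_len) + 1):
            lo = bisect_left(sites, i)
            hi = bisect_right(sites, j - m)
            inside = sites[lo:hi]
            if len(inside) < min_sites:
                continue
            left_clear = i - (sites[lo - 1] + m) if lo > 0 else i
            right_clear = (sites[hi] - j) if hi < len(sites) else n - j
            if left_clear < min_clear_flank or right_clear < min_clear_flank:
                continue
            designs.append(
                AmpliconDesign(
                    chrom=chrom,
                    start=i,
                    end=j,
                    site_positions=tuple(inside),
                    left_clear_flank=left_clear,
                    right_clear_flank=right_clear,
                )
            )
    # flag overlaps: d intersects another design iff the count of designs not
    # entirely left of d and not entirely right of d exceeds one (itself)
    starts = sorted(d.start for d in designs)
    ends = sorted(d.end for d in designs)
    flagged = []
    for d in designs:
        n_intersecting = (
            len(designs)
            - bisect_right(ends, d.start)  # entirely left
            - (len(designs) - bisect_left(starts, d.end))  # entirely right
        )
        flagged.append(
            AmpliconDesign(
                d.chrom, d.start, d.end, d.site_positions,
                d.left_clear_flank, d.right_clear_flank, n_intersecting > 1,
            )
        )
    flagged.sort(key=lambda d: (-d.n_sites, d.length, d.start))
    return flagged


def predict_bands(design: AmpliconDesign, state: Sequence[bool]) -> dict[str, bool]:
    """Gel bands expected for one locus and one methylation state.

    The mock (undigested) lane always shows a product; the digested lane
    shows one only if every site in the product is methylated — a single
    unmethylated site is cleaved and destroys the template (all-or-none
    rule).
    """
    if len(state) != design.n_sites:
        raise ValueError(
            f"state length {len(state)} does not match design with {design.n_sites} sites"
        )
    return {"mock": True, "digested": all(bool(s) for s in state)}


def protected_fraction(design: AmpliconDesign, site_meth_fractions: Sequence[float]) -> float:
    """Continuous-mode variant for heterogeneous templates: the fraction of
    template molecules surviving digestion, assuming independent sites."""
    if len(site_meth_fractions) != design.n_sites:
        raise ValueError("fraction vector length does not match design")
    if any(not 0.0 <= f <= 1.0 for f in site_meth_fractions):
        raise ValueError("fractions must lie in [0, 1]")
    return prod(site_meth_fractions)


def band_truth_table(n_sites: int) -> dict[tuple[bool, ...], bool]:
    """Digested-lane presence for every methylation state of ``n_sites``."""
    return {
        state: all(state) for state in _cartesian((False, True), repeat=n_sites)
    }
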