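"""In-silico reduced representation by XmaI digestion.

Models the library construction step of XmaI-RRBS: restriction digestion at
CCCGGG sites, selection of fragments in the sequencing-optimal 110-200 bp
band, and enumeration of the CpG dinucleotides those fragments interrogate.
Beta values are methylated/(methylated+unmethylated) count ratios subject to
a minimum-coverage filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import ReferenceSequence, XMAI_SITE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fragment:
    """An internal restriction fragment; both endpoints are cut positions
    (0-based, half-open interval)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must precede end")

    @property
    def length(self) -> int:
        return self.end - self.start


def _find_all(seq: str, motif: str) -> list[int]:
    out = []
    i = seq.find(motif)
    while i >= 0:
        out.append(i)
        i = seq.find(motif, i + 1)  # step 1: overlapping occurrences count
    return out


def digest(
    ref: ReferenceSequence | str,
    recognition: str = XMAI_SITE,
    cut_offset: int = 1,
    chrom: str | None = None,
) -> list[Fragment]:
    """Digest the forward strand at every occurrence of ``recognition``.

    XmaI cuts C^CCGGG, i.e. one base into its palindromic site, so scanning a
    single strand finds every cut. Cut positions are site start + cut_offset;
    fragments are the intervals between consecutive cuts. The terminal pieces
    (before the first and after the last cut) are excluded: a library fragment
    needs a cut at both ends for adapter ligation.

    Positions holding non-ACGT characters are skipped with a logged warning.
    """
    if not recognition:
        raise ValueError("recognition sequence must be non-empty")
    if not 0 <= cut_offset <= len(recognition):
        raise ValueError("cut_offset must lie within the recognition sequence")
    if isinstance(ref, ReferenceSequence):
        seq, name = ref.seq, ref.name
    else:
        seq, name = ref, chrom or "seq"
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        logger.warning("sequence %s contains non-ACGT characters %s; those positions cannot match", name, sorted(bad))
    cuts = [p + cut_offset for p in _find_all(seq, recognition.upper())]
    return [Fragment(name, a, b) for a, b in zip(cuts, cuts[1:])]


def size_select(frags: list[Fragment], min_len: int = 110, max_len: int = 200) -> list[Fragment]:
    """Keep fragments with min_len <= length <= max_len (bounds inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    return [f for f in frags if min_len <= f.length <= max_len]


def enumerate_cpgs(
    frags: list[Fragment],
    ref: ReferenceSequence,
    overhang: int = 4,
) -> list[tuple[str, int]]:
    """Forward-strand CpG 'C' positions interrogated by the fragments.

    Each fragment is scanned from cut to cut plus the ``overhang`` bases of
    the downstream site remnant (the filled-in 4-nt 5' overhang of the XmaI
    cut), so both terminal CCGGG remnants contribute their CpG. Results are
    deduplicated and sorted.
    """
    seq = ref.seq.upper()
    positions: set[int] = set()
    for f in frags:
        stop = min(len(seq), f.end + overhang)
        seg = seq[f.start : stop]
        i = seg.find("CG")
        while i >= 0:
            positions.add(f.start + i)
            i = seg.find("CG", i + 1)
    return [(ref.name, p) for p in sorted(positions)]


def call_beta(meth: int, unmeth: int, min_coverage: int = 5) -> float:
    """Beta value meth/(meth+unmeth), or NaN below the coverage floor."""
    if meth < 0 or unmeth < 0:
        raise ValueError("counts must be non-negative")
    total = meth + unmeth
    if total < min_coverage:
        return float("nan")
    return meth / total


def fragment_coverage_summary(frags: list[Fragment]) -> dict[str, float]:
    """Small descriptive summary used by the analysis drivers."""
    if not frags:
        return {"n": 0, "mean_length": float("nan"), "total_bp": 0}
    lengths = np.array([f.length for f in frags])
    return {
        "n": int(lengths.size),
        "mean_length": float(lengths.mean()),
        "total_bp": int(lengths.sum()),
    }
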