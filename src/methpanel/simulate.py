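"""Synthetic reference sequences, methylation cohorts and degraded assay calls.

This module emulates the data-generating process the rest of the pipeline
assumes: a CpG-island-bearing reference with planted XmaI (CCCGGG) and BstHHI
(GCGC) recognition sites, a two-group cohort of per-CpG beta values whose
sample-level background clusters into a highly methylated and a moderately
methylated group enriched for responders and non-responders respectively, and
a lossy binarization step that emulates transferring markers from a sequencing
readout to an MSRE-PCR readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

XMAI_SITE = "CCCGGG"
BSTHHI_SITE = "GCGC"

#: integer codes used throughout for binary methylation calls
METHYLATED = 1
UNMETHYLATED = 0
INVALID = -1

_BASES = np.array(list("ACGT"))
# base composition inside CpG islands (GC-rich) and outside (AT-rich)
_ISLAND_P = np.array([0.16, 0.34, 0.34, 0.16])
_BACKGROUND_P = np.array([0.30, 0.20, 0.20, 0.30])


class TssSite(NamedTuple):
    pos: int
    gene: str


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference chromosome with CpG-island and TSS annotation.

    ``islands`` are 0-based half-open intervals, sorted and non-overlapping;
    every TSS position lies inside an island.
    """

    name: str
    seq: str
    islands: tuple[tuple[int, int], ...]
    tss: tuple[TssSite, ...]

    def __post_init__(self) -> None:
        n = len(self.seq)
        prev_end = 0
        for start, end in self.islands:
            if not (0 <= start < end <= n):
                raise ValueError(f"island ({start}, {end}) outside [0, {n})")
            if start < prev_end:
                raise ValueError("island intervals must be sorted and non-overlapping")
            prev_end = end
        for site in self.tss:
            if not any(s <= site.pos < e for s, e in self.islands):
                raise ValueError(f"TSS {site} not inside any island")

    def tss_position(self, gene: str) -> int:
        for site in self.tss:
            if site.gene == gene:
                return site.pos
        raise KeyError(gene)


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample clinical annotation; only the response label is mandatory."""

    sample_id: str
    response: str  # "PR" (partial response) or "SD" (stable disease)
    age: int | None = None
    tumor_size: str | None = None
    node_status: str | None = None
    regimen: str | None = None

    def __post_init__(self) -> None:
        if self.response not in ("PR", "SD"):
            raise ValueError(f"response must be PR or SD, got {self.response!r}")


@dataclass
class CohortConfig:
    """Parameters of the synthetic two-group methylation cohort.

    ``marker_specs`` maps marker loci (gene names of the reference TSS
    annotation) to per-group methylation frequencies: the fraction of samples
    whose beta at the marker CpG is >= 0.5 in the responder (PR) and
    non-responder (SD) group respectively.
    """

    n_responders: int = 27
    n_nonresponders: int = 10
    marker_specs: list[tuple[str, float, float]] = field(default_factory=list)
    #: Beta-distribution shapes of the two background mixture components
    background_beta_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"high": (8.0, 2.0), "low": (1.5, 8.5)}
    )
    #: probability that a background CpG of a given sample cluster draws from
    #: the "high" mixture component
    high_component_weight: dict[str, float] = field(
        default_factory=lambda: {"high": 0.80, "low": 0.30}
    )
    n_background_cpgs: int = 200
    #: probability that a PR sample sits in the highly methylated background
    #: cluster (and an SD sample in the moderately methylated one)
    enrichment: float = 0.8
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ValueError("group sizes must be >= 1")
        for gene, f_pr, f_sd in self.marker_specs:
            if not (0.0 <= f_pr <= 1.0 and 0.0 <= f_sd <= 1.0):
                raise ValueError(f"marker {gene}: frequencies must lie in [0, 1]")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must lie in [0, 1]")


def _plant(arr: np.ndarray, pos: int, motif: str) -> tuple[int, int]:
    arr[pos : pos + len(motif)] = list(motif)
    return (pos, pos + len(motif))


def _scrub(arr: np.ndarray, motif: str, zone: tuple[int, int], protected: list[tuple[int, int]]) -> None:
    """Destroy chance occurrences of ``motif`` inside ``zone`` by mutating one
    base (to T, which occurs in no planted motif) outside any protected slot."""
    seq = "".join(arr[zone[0] : zone[1]])
    changed = True
    while changed:
        changed = False
        start = 0
        while True:
            i = seq.find(motif, start)
            if i < 0:
                break
            abs_i = zone[0] + i
            span = range(abs_i, abs_i + len(motif))
            target = next(
                (p for p in span if not any(s <= p < e for s, e in protected)), None
            )
            if target is None:
                start = i + 1  # fully protected occurrence (a planted site)
                continue
            arr[target] = "T"
            seq = "".join(arr[zone[0] : zone[1]])
            changed = True
            break


def _sample_slots(rng: np.random.Generator, n: int, motif_len: int, free: list[tuple[int, int]], taken: list[tuple[int, int]]) -> list[int]:
    """Pick ``n`` non-overlapping motif start positions inside the ``free``
    intervals, avoiding ``taken`` slots. Best-effort: gives up after retries."""
    starts: list[int] = []
    candidates = [
        (s, e - motif_len) for s, e in free if e - motif_len > s
    ]
    if not candidates:
        return starts
    weights = np.array([hi - lo for lo, hi in candidates], dtype=float)
    weights /= weights.sum()
    occupied = list(taken)
    tries = 0
    while len(starts) < n and tries < 50 * max(n, 1):
        tries += 1
        lo, hi = candidates[rng.choice(len(candidates), p=weights)]
        p = int(rng.integers(lo, hi))
        slot = (p, p + motif_len)
        if any(s < slot[1] and slot[0] < e for s, e in occupied):
            continue
        occupied.append(slot)
        starts.append(p)
    return starts


def generate_reference(
    n_islands: int = 12,
    island_len: int = 600,
    inter_island_len: int = 800,
    xmai_density: float = 4.0,
    bsthhi_density: float = 8.0,
    seed: int = 0,
    name: str = "chrS",
) -> ReferenceSequence:
    """Generate a CpG-island-bearing reference with planted enzyme sites.

    Each island carries one TSS at its centre. When the island is large enough
    (>= 400 bp) the TSS neighbourhood is structured so that downstream stages
    are guaranteed to see it: an XmaI site pair 150 bp apart brackets the TSS
    (so the TSS CpG lands on a size-selectable library fragment) and a trio of
    BstHHI sites spaced 30 bp apart straddles the TSS with >= 50 bp of
    site-free flank (so an MSRE-PCR amplicon can be designed). Chance motif
    occurrences inside those reserved windows are scrubbed; additional sites
    are planted elsewhere in the island at approximately the requested
    densities. Densities are in sites per kilobase of island sequence.

    Deterministic for a fixed seed.
    """
    if island_len < len(XMAI_SITE):
        raise ValueError(f"island_len must be >= {len(XMAI_SITE)} to hold an XmaI site")
    if n_islands < 0 or inter_island_len < 0:
        raise ValueError("counts and lengths must be non-negative")
    if xmai_density < 0 or bsthhi_density < 0:
        raise ValueError("site densities must be non-negative")

    rng = np.random.default_rng(seed)
    parts: list[str] = []
    islands: list[tuple[int, int]] = []
    tss: list[TssSite] = []
    offset = 0

    def background(n: int) -> str:
        return "".join(rng.choice(_BASES, size=n, p=_BACKGROUND_P))

    parts.append(background(inter_island_len))
    offset += inter_island_len

    n_x_target = int(round(island_len * xmai_density / 1000.0))
    n_b_target = int(round(island_len * bsthhi_density / 1000.0))

    for k in range(n_islands):
        arr = rng.choice(_BASES, size=island_len, p=_ISLAND_P)
        protected: list[tuple[int, int]] = []
        c = island_len // 2
        structured = island_len >= 400
        if structured:
            # XmaI pair bracketing the TSS: cuts at c-69 and c+81, fragment 150 bp
            protected.append(_plant(arr, c - 70, XMAI_SITE))
            protected.append(_plant(arr, c + 80, XMAI_SITE))
            # BstHHI trio around the TSS; the first one supplies the TSS CpG
            for p in (c - 1, c + 29, c + 59):
                protected.append(_plant(arr, p, BSTHHI_SITE))
            _scrub(arr, XMAI_SITE, (max(0, c - 75), min(island_len, c + 86)), protected)
            _scrub(arr, BSTHHI_SITE, (max(0, c - 125), min(island_len, c + 190)), protected)
            reserve = (c - 125, c + 190)
            free = [(0, max(0, reserve[0])), (min(island_len, reserve[1]), island_len)]
            n_extra_x = max(0, n_x_target - 2)
            n_extra_b = max(0, n_b_target - 3)
        else:
            protected.append(_plant(arr, max(0, c - 1), BSTHHI_SITE))
            free = [(0, island_len)]
            n_extra_x = n_x_target
            n_extra_b = max(0, n_b_target - 1)
        for p in _sample_slots(rng, n_extra_x, len(XMAI_SITE), free, protected):
            protected.append(_plant(arr, p, XMAI_SITE))
        for p in _sample_slots(rng, n_extra_b, len(BSTHHI_SITE), free, protected):
            protected.append(_plant(arr, p, BSTHHI_SITE))
        islands.append((offset, offset + island_len))
        tss.append(TssSite(pos=offset + c, gene=f"GENE_{k + 1:02d}"))
        parts.append("".join(arr))
        offset += island_len
        parts.append(background(inter_island_len))
        offset += inter_island_len

    return ReferenceSequence(name=name, seq="".join(parts), islands=tuple(islands), tss=tuple(tss))


def default_marker_specs(ref: ReferenceSequence, n_markers: int = 10) -> list[tuple[str, float, float]]:
    """Default informative-marker panel: the first ``n_markers`` genes of the
    reference with PR/SD methylation-frequency pairs spanning deltas 0.3-0.7,
    PR more methylated (the structure of the published 10-marker panel)."""
    freqs = [
        (0.85, 0.30), (0.81, 0.10), (0.78, 0.30), (0.74, 0.20), (0.70, 0.40),
        (0.67, 0.10), (0.63, 0.30), (0.59, 0.20), (0.56, 0.40), (0.52, 0.10),
    ]
    genes = [site.gene for site in ref.tss[:n_markers]]
    if len(genes) < n_markers:
        raise ValueError("reference has fewer TSS than requested markers")
    return [(g, f_pr, f_sd) for g, (f_pr, f_sd) in zip(genes, freqs)]


def _island_cg_positions(ref: ReferenceSequence) -> list[int]:
    out = []
    for s, e in ref.islands:
        seg = ref.seq[s:e + 1]
        i = seg.find("CG")
        while i >= 0:
            if s + i + 1 < e:  # CG fully inside the island
                out.append(s + i)
            i = seg.find("CG", i + 1)
    return out


def generate_cohort(
    ref: ReferenceSequence,
    config: CohortConfig,
    positions: Sequence[tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, list[SampleAnnotation]]:
    """Draw a two-group cohort beta-value matrix with planted marker loci.

    Returns a DataFrame indexed by (chrom, pos) with one column per sample,
    plus the sample annotations. Marker CpGs sit at the TSS positions of the
    genes named in ``config.marker_specs``; their per-sample methylation
    indicator is Bernoulli with the configured group frequency, and the beta
    value is then drawn above or below 0.5 accordingly, so the fraction of
    samples with beta >= 0.5 matches the configured frequency in expectation.
    Background CpGs (``positions`` if given, else CG positions inside islands)
    are drawn from a two-component mixture whose component weight depends on
    the sample's background cluster; PR samples join the highly methylated
    cluster with probability ``config.enrichment``.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_pr, n_sd = config.n_responders, config.n_nonresponders
    width = max(2, len(str(max(n_pr, n_sd))))
    samples = [f"PR{i + 1:0{width}d}" for i in range(n_pr)] + [
        f"SD{i + 1:0{width}d}" for i in range(n_sd)
    ]
    responses = ["PR"] * n_pr + ["SD"] * n_sd

    annotations = [
        SampleAnnotation(
            sample_id=sid,
            response=resp,
            age=int(np.clip(rng.normal(48, 8), 28, 75)),
            tumor_size=str(rng.choice(["T1", "T2", "T3", "T4"], p=[0.22, 0.70, 0.04, 0.04])),
            node_status=str(rng.choice(["N0", "N1", "N2", "N3"], p=[0.35, 0.55, 0.05, 0.05])),
            regimen=str(rng.choice(["FAC", "CAX", "Taxotere", "CMX"], p=[0.45, 0.25, 0.20, 0.10])),
        )
        for sid, resp in zip(samples, responses)
    ]

    # background-cluster assignment: PR -> "high" w.p. enrichment, SD -> "low"
    clusters = [
        ("high" if rng.random() < config.enrichment else "low")
        if resp == "PR"
        else ("low" if rng.random() < config.enrichment else "high")
        for resp in responses
    ]

    marker_pos = {gene: ref.tss_position(gene) for gene, _, _ in config.marker_specs}
    if positions is None:
        pool = [(ref.name, p) for p in _island_cg_positions(ref)]
    else:
        pool = [tuple(p) for p in positions]
    pool = [p for p in pool if p[1] not in marker_pos.values()]
    n_bg = min(config.n_background_cpgs, len(pool))
    bg_idx = rng.choice(len(pool), size=n_bg, replace=False) if n_bg else np.array([], int)
    bg_positions = [pool[i] for i in sorted(bg_idx)]

    rows: dict[tuple[str, int], np.ndarray] = {}
    for gene, f_pr, f_sd in config.marker_specs:
        freq = np.where(np.array(responses) == "PR", f_pr, f_sd)
        meth = rng.random(len(samples)) < freq
        beta = np.where(
            meth,
            0.5 + 0.5 * rng.beta(5.0, 1.5, size=len(samples)),
            0.5 * rng.beta(1.5, 5.0, size=len(samples)),
        )
        rows[(ref.name, marker_pos[gene])] = beta

    a_hi, b_hi = config.background_beta_params["high"]
    a_lo, b_lo = config.background_beta_params["low"]
    if bg_positions:
        for j, cl in enumerate(clusters):
            w = config.high_component_weight[cl]
            hi = rng.random(len(bg_positions)) < w
            vals = np.where(
                hi,
                rng.beta(a_hi, b_hi, size=len(bg_positions)),
                rng.beta(a_lo, b_lo, size=len(bg_positions)),
            )
            for i, key in enumerate(bg_positions):
                rows.setdefault(key, np.full(len(samples), np.nan))[j] = vals[i]

    index = pd.MultiIndex.from_tuples(sorted(rows), names=["chrom", "pos"])
    betas = pd.DataFrame(
        [rows[key] for key in sorted(rows)], index=index, columns=samples, dtype=float
    )
    if config.missing_rate > 0:
        mask = rng.random(betas.shape) < config.missing_rate
        betas = betas.mask(mask)
    return betas, annotations


def degrade_to_binary_calls(
    betas: pd.DataFrame,
    call_threshold: float = 0.5,
    flip_prob: float = 0.0,
    seed: int = 0,
    loci: dict[tuple[str, int], str] | None = None,
) -> pd.DataFrame:
    """Binarize a beta matrix and flip calls independently with ``flip_prob``.

    A beta exactly at ``call_threshold`` is called methylated (the boundary is
    closed on the methylated side). Missing betas become ``INVALID`` and are
    never flipped. ``loci`` optionally relabels (chrom, pos) rows to locus
    names. Deterministic for a fixed seed; emulates the imperfect concordance
    of transferring sequencing-derived calls to an MSRE-PCR readout.
    """
    if not 0.0 <= flip_prob <= 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    meth = (betas.to_numpy() >= call_threshold).astype(np.int8)
    flips = rng.random(betas.shape) < flip_prob
    calls = np.where(flips, 1 - meth, meth).astype(np.int8)
    calls[np.isnan(betas.to_numpy())] = INVALID
    out = pd.DataFrame(calls, index=betas.index, columns=betas.columns)
    if loci is not None:
        out.index = pd.Index([loci.get(key, f"{key[0]}:{key[1]}") for key in betas.index], name="locus")
    return out
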