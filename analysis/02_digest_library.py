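"""In-silico XmaI digestion of the reference and size selection to the
110-200 bp sequencing band; enumerates the CpGs the library interrogates."""

import argparse
from pathlib import Path

from methpanel.config import PipelineConfig
from methpanel.io import read_reference, write_bed
from methpanel.rrbs import digest, enumerate_cpgs, fragment_coverage_summary, size_select


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    r = args.results

    cfg = PipelineConfig.from_yaml(r / "config.yaml")
    ref = read_reference(r / "reference.fa", r / "islands.bed", r / "tss.bed")
    frags = digest(ref)
    kept = size_select(frags, cfg.min_fragment_len, cfg.max_fragment_len)
    assayed = enumerate_cpgs(kept, ref)
    write_bed([(f.chrom, f.start, f.end) for f in kept], r / "fragments.bed")
    write_bed([(c, p, p + 2) for c, p in assayed], r / "assayed_cpgs.bed")

    total = fragment_coverage_summary(frags)
    sel = fragment_coverage_summary(kept)
    print(f"digest: {total['n']} internal fragments (mean {total['mean_length']:.0f} bp); "
          f"{sel['n']} retained in the {cfg.min_fragment_len}-{cfg.max_fragment_len} bp band")
    print(f"library interrogates {len(assayed)} CpG dinucleotides "
          f"({sel['total_bp']:,} bp of reduced representation)")
    print(f"wrote fragments.bed, assayed_cpgs.bed to {r}/")


if __name__ == "__main__":
    main()
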