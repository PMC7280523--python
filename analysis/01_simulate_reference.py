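"""Generate the synthetic reference: CpG islands with planted XmaI (CCCGGG)
and BstHHI (GCGC) sites and one TSS per island, written as FASTA + BED."""

import argparse
from pathlib import Path

from methpanel.config import PipelineConfig
from methpanel.io import write_bed, write_fasta
from methpanel.pipeline import build_reference


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    cfg = PipelineConfig(seed=args.seed)
    cfg.to_yaml(args.results / "config.yaml")
    ref = build_reference(cfg)
    write_fasta(ref, args.results / "reference.fa")
    write_bed([(ref.name, s, e) for s, e in ref.islands], args.results / "islands.bed")
    write_bed([(ref.name, t.pos, t.pos + 1, t.gene) for t in ref.tss], args.results / "tss.bed")

    n_cg = ref.seq.count("CG")
    print(f"reference {ref.name}: {len(ref.seq):,} bp, {len(ref.islands)} CpG islands, "
          f"{len(ref.tss)} TSS, {n_cg} CpG dinucleotides genome-wide")
    print(f"wrote reference.fa, islands.bed, tss.bed, config.yaml to {args.results}/")


if __name__ == "__main__":
    main()
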