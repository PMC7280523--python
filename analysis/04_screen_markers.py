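"""Differential-methylation screen: per-CpG Mann-Whitney test (p < 0.01),
TSS restriction, CpG clustering (Manhattan / ward.D2) and the two-cluster
sample structure."""

import argparse
import json
from pathlib import Path

from methpanel.config import PipelineConfig
from methpanel.io import read_beta_matrix, read_reference, read_sample_sheet
from methpanel.screen import cluster_cpgs, cluster_samples, differential_cpgs, filter_tss


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    r = args.results

    cfg = PipelineConfig.from_yaml(r / "config.yaml")
    ref = read_reference(r / "reference.fa", r / "islands.bed", r / "tss.bed")
    betas = read_beta_matrix(r / "betas.tsv")
    ann = read_sample_sheet(r / "samples.tsv")

    sig = differential_cpgs(betas, ann, alpha=cfg.alpha)
    sig_tss = filter_tss(sig, ref, window=cfg.tss_window)
    sig_tss.to_csv(r / "significant_tss_cpgs.tsv", sep="\t", index=False)

    labels, summary = cluster_samples(betas, ann, k=2)
    summary.to_csv(r / "sample_clusters.tsv", sep="\t", index=False)

    print(f"screen: {len(sig)} CpGs significant at p < {cfg.alpha}; "
          f"{len(sig_tss)} within +/-{cfg.tss_window} bp of a TSS "
          f"({sig_tss['gene'].nunique()} genes)")
    print("sample clusters (1 = highly methylated):")
    print(summary.to_string(index=False))
    if len(sig_tss) >= 2:
        dendro = cluster_cpgs(
            betas.loc[[(c, p) for c, p in zip(sig_tss["chrom"], sig_tss["pos"])]]
        )
        with open(r / "cpg_dendrogram.json", "w") as fh:
            json.dump(dendro.to_nested_lists(), fh, default=str)
        print(f"CpG dendrogram (ward.D2 on Manhattan) -> cpg_dendrogram.json")
    print(f"wrote significant_tss_cpgs.tsv, sample_clusters.tsv to {r}/")


if __name__ == "__main__":
    main()
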