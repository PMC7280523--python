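"""MSRE-PCR assay design for each marker TSS region: >= 3 BstHHI (GCGC)
sites inside a <= 200 bp product with >= 50 bp site-free flanks."""

import argparse
import json
from pathlib import Path

from methpanel.config import PipelineConfig
from methpanel.io import read_reference, write_bed
from methpanel.pipeline import design_assays
from methpanel.simulate import default_marker_specs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    r = args.results

    cfg = PipelineConfig.from_yaml(r / "config.yaml")
    ref = read_reference(r / "reference.fa", r / "islands.bed", r / "tss.bed")
    specs = default_marker_specs(ref, n_markers=cfg.n_markers)
    designs = design_assays(cfg, ref, specs)

    payload = {}
    bed_rows = []
    for gene, d in designs.items():
        if d is None:
            payload[gene] = None
            continue
        t = ref.tss_position(gene)
        lo = max(0, t - 150)
        payload[gene] = {
            "product_start": lo + d.start, "product_end": lo + d.end,
            "length": d.length, "n_sites": d.n_sites,
            "site_positions": [lo + s for s in d.site_positions],
            "left_clear_flank": d.left_clear_flank,
            "right_clear_flank": d.right_clear_flank,
        }
        bed_rows.append((ref.name, lo + d.start, lo + d.end, gene))
    with open(r / "designs.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    write_bed(bed_rows, r / "designs.bed")

    ok = [g for g, d in designs.items() if d is not None]
    print(f"designed MSRE-PCR amplicons for {len(ok)}/{len(designs)} marker loci")
    for g in ok:
        p = payload[g]
        print(f"  {g}: {p['length']} bp product, {p['n_sites']} BstHHI sites, "
              f"flanks {p['left_clear_flank']}/{p['right_clear_flank']} bp clear")
    print(f"wrote designs.json, designs.bed to {r}/")


if __name__ == "__main__":
    main()
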