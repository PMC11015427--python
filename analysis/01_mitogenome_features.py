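"""Feature arithmetic on the two published Phthorimaea mitogenome annotations.

Reconstructs each genome's length from its printed coordinates and terminal
spacer, tabulates feature sizes, and locates the intergenic spacers and gene
overlaps.  Key findings: P. absoluta closes at 15,295 bp and P. operculella
at 15,269 bp; ND5 is the longest protein-coding gene (1,735 / 1,732 bp) and
ATP8 the shortest (171 / 165 bp); both annotations carry four short gene
overlaps (down to -8 bp), and the largest spacers are 69 bp (P. absoluta,
before tRNA-Ala) and 57 bp (P. operculella, before ND2).

Writes results/mitogenome_features.json and a per-feature size table.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mitoniche.annotation import feature_length, load_reference_annotation
from mitoniche.workflow import mitogenome_feature_summary


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summary = mitogenome_feature_summary()
    with open(out / "mitogenome_features.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    rows = []
    for species in ("P_absoluta", "P_operculella"):
        genome, _ = load_reference_annotation(species)
        for f in genome.features:
            rows.append({
                "species": species, "feature": f.name, "category": f.category,
                "strand": f.strand, "start": f.start, "stop": f.stop,
                "size_bp": feature_length(f, genome.length),
            })
    pd.DataFrame(rows).to_csv(out / "mitogenome_feature_sizes.csv", index=False)

    for species, s in summary.items():
        print(f"{species}: {s['genome_length_bp']} bp, "
              f"{s['n_features']} features, ND5 {s['nd5_length_bp']} bp, "
              f"ATP8 {s['atp8_length_bp']} bp, {s['n_overlaps']} overlaps, "
              f"largest spacer {s['largest_spacer'][2]} bp before "
              f"{s['largest_spacer'][1]}")


if __name__ == "__main__":
    main()
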