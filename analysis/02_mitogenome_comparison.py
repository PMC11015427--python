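"""Pairwise mitogenome comparison on a simulated pair with planted truth.

A Phthorimaea-like template genome is mutated codon-aware with a known
per-gene ledger of SNPs and non-synonymous substitutions; the comparison
stage (per-gene global alignment, SNP counting, codon-wise syn/nonsyn
classification under the invertebrate mitochondrial code) then recovers the
ledger.  On the default ledger the recovery is exact, and whole-genome
identity reflects the planted divergence.

Writes results/gene_comparison.tsv and results/comparison_summary.json.
"""

import argparse
import json
from pathlib import Path

from mitoniche.compare import align_global, identity_stats, write_comparison_tsv
from mitoniche.workflow import comparison_recovery


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    res = comparison_recovery(args.seed)
    write_comparison_tsv(res["summaries"], out / "gene_comparison.tsv")
    ga, gb = res["genomes"]
    aln = align_global(ga.sequence, gb.sequence, label_a=ga.organism,
                       label_b=gb.organism)
    identical, columns, pct = identity_stats(aln)
    summary = {
        "planted": res["planted"],
        "recovered": res["recovered"],
        "recovery_exact": res["exact"],
        "identical_sites": identical,
        "alignment_columns": columns,
        "identity_pct": round(pct, 3),
        "total_pcg_snps": sum(s.snps for s in res["summaries"]),
        "total_nonsynonymous": sum(s.nonsyn for s in res["summaries"]),
    }
    with open(out / "comparison_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    print(f"planted ledger recovered exactly: {res['exact']}")
    print(f"whole-genome identity: {pct:.2f}% "
          f"({identical}/{columns} identical sites)")
    print(f"total PCG SNPs {summary['total_pcg_snps']}, "
          f"non-synonymous {summary['total_nonsynonymous']}")


if __name__ == "__main__":
    main()
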