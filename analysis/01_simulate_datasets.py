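#!/usr/bin/env python
"""Generate the three synthetic datasets the analysis runs on.

1. A single-class "no methylation" transcriptome (2000 genes, transcript GC
   36.25%, long-run CpG[o/e] calibrated to 0.70) — the unimodal scenario.
2. A 50/50 two-class transcriptome (components calibrated to 0.35/0.85) —
   the bimodal, intact-methylation scenario.
3. A uniform background genome (3 Mb over 3 scaffolds, genome GC 33.4%,
   CpG[o/e] calibrated to 0.79) for the 1-kb fragment analysis, plus an
   annotated toy genome (FASTA + GFF3) exercising the extraction route.

Sequence data goes to scratch/data/ (bulky, regenerable); the truth tables
are small and land there too. Everything is reproducible from --seed.
"""

import argparse
from pathlib import Path

from cpgoe.sequence_io import write_fasta
from cpgoe.simulate import (
    collembolan_like_spec,
    generate_annotated_genome,
    generate_background_genome,
    generate_gene_set,
    honeybee_like_spec,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=2017)
    parser.add_argument("--n-genes", type=int, default=2000)
    args = parser.parse_args()
    out = ROOT / "scratch" / "data"
    out.mkdir(parents=True, exist_ok=True)

    for name, spec_fn in [
        ("unimodal", collembolan_like_spec),
        ("bimodal", honeybee_like_spec),
    ]:
        spec = spec_fn(n_genes=args.n_genes, seed=args.seed)
        records, truth = generate_gene_set(spec)
        write_fasta(records, out / f"{name}.transcripts.fa")
        truth.to_csv(out / f"{name}.truth.tsv", sep="\t", index=False)
        targets = {c.label: round(c.expected_oe, 3) for c in spec.classes}
        print(f"{name}: {len(records)} transcripts, class targets {targets}")

    scaffolds = generate_background_genome(total_bp=3_000_000, seed=args.seed)
    write_fasta(scaffolds, out / "background.genome.fa")
    print(f"background genome: {len(scaffolds)} scaffolds, 3.0 Mb, target o/e 0.79")

    bundle = generate_annotated_genome(
        collembolan_like_spec(n_genes=300, seed=args.seed)
    )
    bundle.write(out / "toy")
    print(f"annotated toy genome: 300 genes on {len(bundle.genome)} scaffolds")
    print(f"all datasets under {out}")


if __name__ == "__main__":
    main()
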