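#!/usr/bin/env python
"""Collate the headline numbers of the whole analysis into one table.

Reads the JSON reports written by 02_gene_body_analysis.py and
03_genome_windows.py and writes results/summary.tsv: one row per dataset
with the number of regions analyzed, mean and sd of CpG[o/e], the BIC-best
component count, and the modality verdict.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    rows = []
    for label, path in [
        ("gene_bodies_unimodal", ROOT / "results/gene_body/unimodal.report.json"),
        ("gene_bodies_bimodal", ROOT / "results/gene_body/bimodal.report.json"),
        ("genome_1kb_windows", ROOT / "results/windows/windows.report.json"),
    ]:
        if not path.exists():
            raise SystemExit(f"{path} missing - run the earlier analysis steps first")
        report = json.loads(path.read_text())
        call = report.get("call")
        rows.append(
            {
                "dataset": label,
                "n_regions": report["n_values"],
                "mean_cpg_oe": round(report["overall_mean"], 4),
                "sd_cpg_oe": round(report["overall_sd"], 4),
                "best_k": call["best_fit"]["k"] if call else "",
                "verdict": call["verdict"] if call else "",
            }
        )
    table = pd.DataFrame(rows)
    out = ROOT / "results" / "summary.tsv"
    table.to_csv(out, sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
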