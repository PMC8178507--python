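#!/usr/bin/env python
"""Step 5 — differential expression across clinicopathological groups.

Median-of-ratios normalization, then per-entry negative-binomial Wald tests
for grade III vs I (with and without ER adjustment) and ER- vs ER+, with BH
FDR over the presence-filtered entries and normal-prior fold-change shrinkage.
Estimated log2 fold-changes are compared with the planted truth.
"""

import json
from pathlib import Path

import pandas as pd

from piratrue import expression as ex

SIM = Path("results/analysis/sim")
OUT = Path("results/analysis")

CONTRASTS = [
    ("gradeIII_vs_gradeI", "grade", "III", "I", None),
    ("gradeIII_vs_gradeI_adjER", "grade", "III", "I", "er"),
    ("ERneg_vs_ERpos", "er", "neg", "pos", None),
]


def main() -> None:
    counts = pd.read_csv(OUT / "counts.tsv", sep="\t", index_col=0)
    presence = pd.read_csv(OUT / "presence.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(SIM / "sample_metadata.tsv", sep="\t").set_index("sample_id")
    truth = json.loads((SIM / "truth.json").read_text())

    present = presence.index[presence["tier"] == "present"]
    factors = ex.size_factors(counts)
    normalized = ex.normalize(counts, factors)
    normalized.round(6).to_csv(OUT / "normalized.tsv", sep="\t")

    for name, col, case_level, ref_level, adjust_col in CONTRASTS:
        case = meta.index[meta[col] == case_level].tolist()
        ref = meta.index[meta[col] == ref_level].tolist()
        adjust = meta.loc[case + ref, adjust_col].to_dict() if adjust_col else None
        contrast = ex.Contrast(name, case, ref, adjust)
        res = ex.nb_wald_de(counts.loc[present], contrast, factors=factors)
        res.round(6).to_csv(OUT / f"de_{name}.tsv", sep="\t")
        sig = res[res["padj"] < 0.05]
        print(f"\n{name} (n={len(case)} vs {len(ref)}): "
              f"{len(sig)} / {len(res)} entries at padj < 0.05")
        for acc in sig.index:
            link = truth["entries"][acc].get("condition_link")
            planted = link[1] if link else 0.0
            print(f"  {acc}: log2FC {res.loc[acc, 'log2fc']:+.2f} "
                  f"(shrunk {res.loc[acc, 'shrunk_log2fc']:+.2f}, "
                  f"planted {planted:+.2f}), padj {res.loc[acc, 'padj']:.2e}")


if __name__ == "__main__":
    main()
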