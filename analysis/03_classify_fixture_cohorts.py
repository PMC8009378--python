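#!/usr/bin/env python
"""Classify the packaged colony-PCR cohort tables through the decision key.

Each packaged cohort encodes a published 30-colony class composition as
canonical PCR patterns; pushing them through genotype classification must
return exactly the encoded composition (a round-trip identity for the exact
57.7 kb panel; the remaining panels are approximate encodings of
qualitative statements). Writes results/fig4_cohort_classes.tsv.
"""

from pathlib import Path

import pandas as pd

from bfbsim import PACKAGED_COHORTS, fig4_cohort, summarize_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    (ROOT / "results").mkdir(exist_ok=True)
    rows = []
    for label, spec in sorted(PACKAGED_COHORTS.items()):
        df = summarize_cohort(fig4_cohort(spec))
        for cls, row in df.iterrows():
            rows.append({
                "cohort": label,
                "approximate": spec.approximate,
                "repair_class": cls,
                "count": int(row["count"]),
                "percent": round(row["percent"], 1),
            })
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "results" / "fig4_cohort_classes.tsv", sep="\t",
               index=False)
    exact = out[out.cohort == "57.7kb-fig4a"]
    print(out.to_string(index=False))
    print(
        "\n57.7 kb panel (exact composition): "
        + ", ".join(
            f"{r.repair_class} {r.percent}%" for r in exact.itertuples()
        )
    )


if __name__ == "__main__":
    main()
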