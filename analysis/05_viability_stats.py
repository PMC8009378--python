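#!/usr/bin/env python
"""Viability assays and genotype comparisons on simulated platings.

Emulates the plating design: for each distance and genotype, three
replicate platings of 100 founders each; viability = colonies on glucose
(dicentric active, from the simulator) over colonies plated (galactose
proxy). Each mutant is compared with WT at the same distance by a pooled
Student's t-test. Writes results/viability.tsv and
results/viability_tests.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bfbsim import (
    GENOTYPES,
    GenomeConfig,
    PAPER_KB_LABELS,
    PlatingResult,
    SimParams,
    build_reference,
    simulate_plating,
    t_test,
    viability,
)

ROOT = Path(__file__).resolve().parents[1]
N_PER_PLATE = 100
N_REPLICATES = 3
SEED = 31


def main() -> None:
    (ROOT / "results").mkdir(exist_ok=True)
    params = SimParams()
    rows = []
    for insertion, label in PAPER_KB_LABELS.items():
        ref = build_reference(GenomeConfig(insertion_pos=insertion, seed=1))
        for gname, genotype in GENOTYPES.items():
            for rep in range(N_REPLICATES):
                fates = simulate_plating(
                    ref, params, genotype, N_PER_PLATE,
                    seed=SEED + 1000 * rep
                )
                n_glu = sum(f.viable for f in fates)
                plate = PlatingResult(
                    f"{label}kb-{gname}", gname, float(label), rep,
                    n_glu, N_PER_PLATE,
                )
                rows.append({
                    "strain": plate.strain, "genotype": gname,
                    "distance_kb": float(label), "replicate": rep,
                    "n_ypd": n_glu, "n_ypg": N_PER_PLATE,
                    "viability_percent": viability(plate),
                })
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "viability.tsv", sep="\t", index=False)

    tests = []
    for dist in sorted(df.distance_kb.unique()):
        wt = df[(df.distance_kb == dist)
                & (df.genotype == "WT")].viability_percent.tolist()
        for gname in ("lif1", "rad52", "mrc1"):
            mut = df[(df.distance_kb == dist)
                     & (df.genotype == gname)].viability_percent.tolist()
            res = t_test(wt, mut, variant="student",
                         labels=(f"WT-{dist}", f"{gname}-{dist}"))
            tests.append({
                "distance_kb": dist, "mutant": gname,
                "wt_mean": np.mean(wt), "mutant_mean": np.mean(mut),
                "t": round(res.t_statistic, 3),
                "df": res.degrees_of_freedom,
                "p": res.p_value, "significant": res.significant,
            })
    tdf = pd.DataFrame(tests)
    tdf.to_csv(ROOT / "results" / "viability_tests.tsv", sep="\t",
               index=False)
    print(df.groupby(["distance_kb", "genotype"])
            .viability_percent.mean().unstack().round(1).to_string())
    print("\nmutant vs WT comparisons with p < 0.05:")
    print(tdf[tdf.significant].to_string(index=False))


if __name__ == "__main__":
    main()
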