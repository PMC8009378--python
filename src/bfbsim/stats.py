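"""Viability statistics and deterministic report rendering.

Viability of a dicentric strain is measured by plating: colonies formed on
glucose (dicentric active) divided by colonies on galactose (dicentric
inactive), as a percentage. Genotypes are compared with a two-sided
two-sample t-test (pooled-variance Student by default; Welch available).
No multiple-testing correction is applied.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats as sps

__all__ = [
    "PlatingResult",
    "ComparisonResult",
    "viability",
    "t_test",
    "render_report",
]


@dataclass(frozen=True)
class PlatingResult:
    strain: str
    genotype: str
    distance_kb: float
    replicate: int
    n_glucose_colonies: int
    n_galactose_colonies: int

    def __post_init__(self):
        if self.n_glucose_colonies < 0 or self.n_galactose_colonies < 0:
            raise ValueError("colony counts must be >= 0")


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def viability(r: PlatingResult) -> float:
    """Percent viability = 100 x glucose colonies / galactose colonies.

    May exceed 100% with plating noise; reported verbatim.
    """
    if r.n_galactose_colonies == 0:
        raise ValueError("galactose colony count is zero; viability undefined")
    return 100.0 * r.n_glucose_colonies / r.n_galactose_colonies


def t_test(group_a: list[float], group_b: list[float],
           variant: str = "student", alpha: float = 0.05,
           labels: tuple[str, str] = ("A", "B")) -> ComparisonResult:
    """Two-sided two-sample t-test on viability percentages.

    ``student`` pools variances (the default, matching the published
    analysis); ``welch`` drops the equal-variance assumption. Two identical
    zero-variance groups return p = 1 by convention.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    equal_var = variant == "student"
    res = sps.ttest_ind(group_a, group_b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if pd.isna(t):  # both groups constant
        if float(pd.Series(group_a).mean()) == float(pd.Series(group_b).mean()):
            t, p = 0.0, 1.0
        else:
            t, p = float("inf"), 0.0
    return ComparisonResult(labels[0], labels[1], t, df, p, p < alpha, alpha)


def render_report(out_dir: str | Path,
                  colony_table: pd.DataFrame | None = None,
                  class_table: pd.DataFrame | None = None,
                  junction_table: pd.DataFrame | None = None,
                  viability_table: pd.DataFrame | None = None,
                  config: dict | None = None) -> dict:
    """Write a machine-readable JSON summary plus human TSVs.

    Sections with no data are omitted. Re-running on identical inputs is
    byte-identical. Colony ids appearing in ``class_table`` must be a subset
    of those in ``colony_table`` when both are given.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config or {}}
    if (colony_table is not None and class_table is not None
            and "colony_id" in colony_table and "colony_id" in class_table):
        known = set(colony_table["colony_id"])
        offenders = sorted(set(class_table["colony_id"]) - known)
        if offenders:
            raise ValueError(f"unknown colony ids in class table: {offenders}")

    def emit(name: str, df: pd.DataFrame | None):
        if df is None or df.empty:
            return
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        summary[name] = json.loads(df.to_json(orient="records"))

    emit("colonies", colony_table)
    emit("classes", class_table)
    emit("junctions", junction_table)
    emit("viability", viability_table)
    if class_table is not None and "percent" in getattr(
            class_table, "columns", []):
        summary["class_percent_total"] = float(class_table["percent"].sum())
    blob = json.dumps(summary, sort_keys=True, indent=1).encode()
    summary["config_hash"] = hashlib.sha256(blob).hexdigest()
    (out / "report.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1)
    )
    return summary
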