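"""In-silico colony PCR and repair-class calling.

Four diagnostic assays probe a colony's pooled chromosomes: eCEN3 (eC1/eC2),
GALCEN3 (GC1/GC2), the rearrangement product GC1/eC2 and the reciprocal
product eC1/GC2. The presence/size pattern of the four amplicons is mapped to
a repair class (HR, SSA, EJ, unrearranged, aneuploid, SSA+EJ) by a fixed
decision list; patterns outside the key are reported as unclassified rather
than forced into a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome import (
    Karyotype,
    PRIMERS,
    ReferenceGenome,
    realize_sequence,
    reverse_complement,
)

__all__ = [
    "PrimerPanel",
    "PCRPattern",
    "REPAIR_CLASSES",
    "ASSAYS",
    "insilico_pcr",
    "genotype_colony",
    "classify_pattern",
    "summarize_cohort",
    "circle_contiguity",
    "make_tile_primers",
    "patterns_to_table",
    "table_to_patterns",
]

ASSAYS = ("eCEN3", "GALCEN3", "rearrangement", "reciprocal")
REPAIR_CLASSES = (
    "HR", "SSA", "EJ", "unrearranged", "aneuploid", "SSA_plus_EJ",
    "unclassified",
)

ABSENT, WILDTYPE, REDUCED = "absent", "wildtype_size", "reduced_size"


@dataclass(frozen=True)
class PrimerPanel:
    GC1: str = PRIMERS["GC1"]
    GC2: str = PRIMERS["GC2"]
    eC1: str = PRIMERS["eC1"]
    eC2: str = PRIMERS["eC2"]
    max_amplicon: int = 6000
    #: a parental band this much shorter than wild type scores reduced_size
    reduced_margin: int = 50

    def __post_init__(self):
        for p in (self.GC1, self.GC2, self.eC1, self.eC2):
            if len(p) < 15:
                raise ValueError("primers must be >= 15 nt")

    @property
    def pairs(self) -> dict[str, tuple[str, str]]:
        return {
            "eCEN3": (self.eC1, self.eC2),
            "GALCEN3": (self.GC1, self.GC2),
            "rearrangement": (self.GC1, self.eC2),
            "reciprocal": (self.eC1, self.GC2),
        }


@dataclass(frozen=True)
class PCRPattern:
    """Presence/size state of the four diagnostic amplicons for one colony."""

    colony_id: str
    states: dict[str, str] = field(default_factory=dict)
    lengths: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self):
        for assay in ASSAYS:
            self.states.setdefault(assay, ABSENT)
            self.lengths.setdefault(assay, None)

    def present(self, assay: str) -> bool:
        return self.states[assay] != ABSENT


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def insilico_pcr(template: str, fwd: str, rev: str,
                 max_amplicon: int = 6000,
                 topology: str = "linear") -> list[tuple[int, int, int]]:
    """Predict amplicons by exact primer matching.

    Searches ``fwd`` and the reverse complement of ``rev`` (and the swapped
    orientation) and reports every convergent pair within ``max_amplicon``
    as (start, end, length), 1-based on the given template. Circular
    templates are searched across the origin; wrapped products have
    end > len(template).
    """
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be >= 15 nt")
    L = len(template)
    if L == 0:
        return []
    if topology == "circular":
        search = template + template[: min(max_amplicon, L)]
    else:
        search = template
    products: set[tuple[int, int, int]] = set()
    for left, right in ((fwd, rev), (rev, fwd)):
        right_rc = reverse_complement(right)
        left_hits = [i for i in _find_all(search, left) if i < L]
        right_hits = _find_all(search, right_rc)
        for i in left_hits:
            for j in right_hits:
                if j < i:
                    continue
                length = j + len(right_rc) - i
                if length <= max_amplicon:
                    products.add((i + 1, i + length, length))
    return sorted(products)


def genotype_colony(karyotype: Karyotype, ref: ReferenceGenome,
                    panel: PrimerPanel | None = None,
                    colony_id: str = "colony") -> PCRPattern:
    """Run the four assays over the pooled chromosomes of a colony.

    A parental amplicon at (within ``reduced_margin`` of) its wild-type
    length scores wildtype_size; any shorter product scores reduced_size.
    Hybrid products have no wild-type length and score wildtype_size when
    present.
    """
    panel = panel or PrimerPanel()
    expected = {
        "eCEN3": ref.config.ecen_amplicon_len,
        "GALCEN3": ref.config.galcen_amplicon_len,
    }
    states: dict[str, str] = {}
    lengths: dict[str, int | None] = {}
    for assay, (f, r) in panel.pairs.items():
        pooled: list[int] = []
        for chrom in karyotype:
            seq = realize_sequence(chrom, ref)
            pooled.extend(
                p[2] for p in insilico_pcr(
                    seq, f, r, panel.max_amplicon, chrom.topology
                )
            )
        if not pooled:
            states[assay], lengths[assay] = ABSENT, None
        elif assay in expected:
            wt = expected[assay]
            if any(x >= wt - panel.reduced_margin for x in pooled):
                states[assay], lengths[assay] = WILDTYPE, wt
            else:
                states[assay], lengths[assay] = REDUCED, min(pooled)
        else:
            states[assay], lengths[assay] = WILDTYPE, min(pooled)
    return PCRPattern(colony_id, states, lengths)


def classify_pattern(p: PCRPattern) -> str:
    """Map one PCR pattern to its repair class.

    Deterministic decision list; a parental centromere counts as present
    only at wild-type size (a reduced band means the centromere itself was
    deleted). Patterns outside the key fall through to unclassified.
    """
    rearr = p.present("rearrangement")
    recip = p.present("reciprocal")
    gal = p.states["GALCEN3"] == WILDTYPE
    ecen = p.states["eCEN3"] == WILDTYPE
    if rearr and recip and not gal and not ecen:
        return "HR"
    if rearr and (gal or ecen):
        return "aneuploid"
    if rearr and not recip and not gal and not ecen:
        return "SSA"
    if recip and ecen and not rearr and not gal:
        return "SSA_plus_EJ"
    if gal and ecen and not rearr and not recip:
        return "unrearranged"
    if (gal != ecen) and not rearr and not recip:
        return "EJ"
    return "unclassified"


def summarize_cohort(patterns: list[PCRPattern]) -> pd.DataFrame:
    """Counts and percentages per repair class over a cohort."""
    if not patterns:
        raise ValueError("empty cohort")
    classes = [classify_pattern(p) for p in patterns]
    counts = pd.Series(classes).value_counts()
    df = pd.DataFrame({
        "count": counts,
        "percent": 100.0 * counts / counts.sum(),
    })
    df.index.name = "repair_class"
    return df.sort_values("count", ascending=False)


# ---------------------------------------------------------------------------
# circular-derivative contiguity mapping


@dataclass(frozen=True)
class ContiguityReport:
    chromosome: str
    circumference: int
    n_tiles: int
    n_amplified: int
    covered_fraction: float
    gaps: tuple[tuple[int, int], ...]

    @property
    def full_coverage(self) -> bool:
        return not self.gaps and self.n_tiles > 0


def make_tile_primers(seq: str, tile_len: int = 20, step: int = 1500,
                      overlap: int = 200) -> list[tuple[str, str]]:
    """Tiling primer pairs around a circular sequence: each pair amplifies
    ~(step + overlap) bp, overlapping the next tile by ``overlap``."""
    L = len(seq)
    doubled = seq + seq
    pairs = []
    for start in range(0, L, step):
        amp_end = start + min(step + overlap, L)
        fwd = doubled[start: start + tile_len]
        rev = reverse_complement(doubled[amp_end - tile_len: amp_end])
        pairs.append((fwd, rev))
    return pairs


def circle_contiguity(karyotype: Karyotype, ref: ReferenceGenome,
                      tile_primers: list[tuple[str, str]] | None = None,
                      step: int = 1500,
                      overlap: int = 200) -> list[ContiguityReport]:
    """Check that overlapping amplicons cover the full circumference of each
    circular chromosome (empty list when no circle is present)."""
    reports = []
    for chrom in karyotype:
        if chrom.topology != "circular":
            continue
        seq = realize_sequence(chrom, ref)
        L = len(seq)
        pairs = tile_primers or make_tile_primers(seq, step=step,
                                                  overlap=overlap)
        max_amp = step + overlap + 100
        covered: list[tuple[int, int]] = []  # 0-based half-open, may wrap
        n_amplified = 0
        for f, r in pairs:
            prods = insilico_pcr(seq, f, r, max_amp, "circular")
            if prods:
                n_amplified += 1
                s, _, length = min(prods, key=lambda p: p[2])
                covered.append((s - 1, s - 1 + length))
        mask = bytearray(L)
        for s, e in covered:
            for i in range(s, e):
                mask[i % L] = 1
        frac = sum(mask) / L if L else 0.0
        gaps = _runs_of_zero(mask)
        reports.append(
            ContiguityReport(chrom.name, L, len(pairs), n_amplified, frac,
                             tuple(gaps))
        )
    return reports


def _runs_of_zero(mask: bytearray) -> list[tuple[int, int]]:
    gaps, start = [], None
    for i, v in enumerate(mask):
        if v == 0 and start is None:
            start = i
        elif v == 1 and start is not None:
            gaps.append((start, i))
            start = None
    if start is not None:
        gaps.append((start, len(mask)))
    return gaps


# ---------------------------------------------------------------------------
# cohort TSV round-trip


def patterns_to_table(patterns: list[PCRPattern]) -> pd.DataFrame:
    rows = []
    for p in patterns:
        row: dict[str, object] = {"colony_id": p.colony_id}
        for assay in ASSAYS:
            key = {"eCEN3": "eCEN3", "GALCEN3": "GALCEN3",
                   "rearrangement": "rearr", "reciprocal": "recip"}[assay]
            row[f"{key}_state"] = p.states[assay]
            row[f"{key}_len"] = p.lengths[assay]
        rows.append(row)
    return pd.DataFrame(rows)


def table_to_patterns(df: pd.DataFrame) -> list[PCRPattern]:
    out = []
    key_map = {"eCEN3": "eCEN3", "GALCEN3": "GALCEN3",
               "rearr": "rearrangement", "recip": "reciprocal"}
    for _, row in df.iterrows():
        states, lengths = {}, {}
        for key, assay in key_map.items():
            states[assay] = row[f"{key}_state"]
            val = row[f"{key}_len"]
            lengths[assay] = None if pd.isna(val) else int(val)
        out.append(PCRPattern(str(row["colony_id"]), states, lengths))
    return out


def write_pattern_tsv(patterns: list[PCRPattern], path: str | Path) -> None:
    patterns_to_table(patterns).to_csv(path, sep="\t", index=False)


def read_pattern_tsv(path: str | Path) -> list[PCRPattern]:
    return table_to_patterns(pd.read_csv(path, sep="\t"))
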