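"""Synthetic fixtures: PCR cohort tables and junction sequence pairs.

Every fixture the pipeline consumes is generated here with planted ground
truth, so each downstream stage can be round-trip tested without any external
data: cohort tables whose class composition is known by construction, and
reference/derivative allele pairs whose deletion size, junction
microhomology, and inserted bases are planted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assay import ABSENT, PCRPattern, REDUCED, WILDTYPE
from .genome import random_dna

__all__ = [
    "CohortSpec",
    "JunctionSpec",
    "JunctionTruth",
    "PACKAGED_COHORTS",
    "fig4_cohort",
    "random_junction",
    "generate_junction_fixtures",
    "random_sequence",
]


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a colony-PCR cohort (counts per repair class)."""

    label: str
    n_colonies: int
    composition: dict[str, int]
    approximate: bool = False

    def __post_init__(self):
        if sum(self.composition.values()) != self.n_colonies:
            raise ValueError(
                f"{self.label}: composition sums to "
                f"{sum(self.composition.values())}, not {self.n_colonies}"
            )
        unknown = set(self.composition) - set(_CANONICAL_PATTERNS)
        if unknown:
            raise ValueError(
                f"{self.label}: no canonical pattern for classes {unknown}"
            )


# Canonical assay pattern per repair class, as
# (eCEN3, GALCEN3, rearrangement, reciprocal) states. Parental lengths use
# the published wild-type product sizes; a reduced GALCEN3 band stands in for
# a typical ~400 bp centromere deletion.
_WT_GAL, _WT_ECEN = 932, 900
_CANONICAL_PATTERNS: dict[str, dict[str, tuple[str, int | None]]] = {
    "HR": {"eCEN3": (ABSENT, None), "GALCEN3": (ABSENT, None),
           "rearrangement": (WILDTYPE, 925), "reciprocal": (WILDTYPE, 907)},
    "SSA": {"eCEN3": (ABSENT, None), "GALCEN3": (ABSENT, None),
            "rearrangement": (WILDTYPE, 925), "reciprocal": (ABSENT, None)},
    "EJ": {"eCEN3": (WILDTYPE, _WT_ECEN), "GALCEN3": (REDUCED, _WT_GAL - 400),
           "rearrangement": (ABSENT, None), "reciprocal": (ABSENT, None)},
    "unrearranged": {"eCEN3": (WILDTYPE, _WT_ECEN),
                     "GALCEN3": (WILDTYPE, _WT_GAL),
                     "rearrangement": (ABSENT, None),
                     "reciprocal": (ABSENT, None)},
    "aneuploid": {"eCEN3": (WILDTYPE, _WT_ECEN), "GALCEN3": (ABSENT, None),
                  "rearrangement": (WILDTYPE, 925),
                  "reciprocal": (ABSENT, None)},
    "SSA_plus_EJ": {"eCEN3": (WILDTYPE, _WT_ECEN), "GALCEN3": (ABSENT, None),
                    "rearrangement": (ABSENT, None),
                    "reciprocal": (WILDTYPE, 907)},
}

#: Packaged cohort compositions (30 colonies each). Only the 57.7 kb
#: wild-type panel is printed as exact percentages (40/33/20/7 -> counts
#: 12/10/6/2); the other panels are described approximately in the text and
#: are flagged accordingly.
PACKAGED_COHORTS: dict[str, CohortSpec] = {
    "6.5kb-fig4a": CohortSpec("6.5kb-fig4a", 30, {"SSA": 29, "EJ": 1}, True),
    "9.8kb-fig4a": CohortSpec(
        "9.8kb-fig4a", 30, {"EJ": 28, "SSA": 1, "unrearranged": 1}, True),
    "12.3kb-fig4a": CohortSpec(
        "12.3kb-fig4a", 30, {"EJ": 28, "SSA": 1, "unrearranged": 1}, True),
    "18.2kb-fig4a": CohortSpec(
        "18.2kb-fig4a", 30, {"EJ": 28, "HR": 1, "unrearranged": 1}, True),
    "46.3kb-fig4a": CohortSpec(
        "46.3kb-fig4a", 30, {"HR": 21, "EJ": 6, "SSA": 3}, True),
    "57.7kb-fig4a": CohortSpec(
        "57.7kb-fig4a", 30,
        {"EJ": 12, "HR": 10, "SSA_plus_EJ": 6, "unrearranged": 2}, False),
    "6.5kb-lif1-fig4b": CohortSpec(
        "6.5kb-lif1-fig4b", 30, {"SSA": 29, "unrearranged": 1}, True),
    "9.8kb-lif1-fig4b": CohortSpec(
        "9.8kb-lif1-fig4b", 30, {"aneuploid": 20, "HR": 10}, True),
    "12.3kb-lif1-fig4b": CohortSpec(
        "12.3kb-lif1-fig4b", 30, {"HR": 27, "SSA": 2, "unrearranged": 1},
        True),
    "18.2kb-lif1-fig4b": CohortSpec(
        "18.2kb-lif1-fig4b", 30, {"HR": 26, "SSA": 3, "unrearranged": 1},
        True),
}


def fig4_cohort(spec: CohortSpec) -> list[PCRPattern]:
    """Emit exactly the specified counts of each class's canonical pattern."""
    patterns = []
    i = 0
    for cls in sorted(spec.composition):
        template = _CANONICAL_PATTERNS[cls]
        for _ in range(spec.composition[cls]):
            i += 1
            states = {a: st for a, (st, _) in template.items()}
            lengths = {a: ln for a, (_, ln) in template.items()}
            patterns.append(
                PCRPattern(f"{spec.label}-{i:03d}", states, lengths)
            )
    return patterns


# ---------------------------------------------------------------------------
# junction fixtures


@dataclass(frozen=True)
class JunctionSpec:
    n: int = 12
    del_range: tuple[int, int] = (278, 585)
    mh_range: tuple[int, int] = (1, 9)
    p_insertion: float = 0.1
    insertion_len_range: tuple[int, int] = (1, 3)
    mh_zero_inflation: float = 0.0
    ref_len: int = 1200
    gc_content: float = 0.38
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.del_range, self.mh_range,
                       self.insertion_len_range):
            if lo > hi:
                raise ValueError("empty range")
        for p in (self.p_insertion, self.mh_zero_inflation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.ref_len < self.del_range[1] + self.mh_range[1] + 4:
            raise ValueError("ref_len too short for the largest deletion")


@dataclass(frozen=True)
class JunctionTruth:
    deletion_interval: tuple[int, int]
    deletion_size: int
    mh_total: int
    inserted_bases: str


def random_junction(
    ref_allele: str, spec: JunctionSpec, rng: np.random.Generator
) -> tuple[str, str, JunctionTruth]:
    """Plant one deletion junction with exactly the drawn microhomology.

    The drawn microhomology is realized by copying mh bases across the
    junction *inside the to-be-deleted span* before deleting, and the bases
    bounding the copy are forced to mismatch so the planted microhomology is
    maximal. Returns (adjusted reference allele, derivative allele, truth);
    the adjusted reference differs from the input only inside the deleted
    interval, so the derivative is unchanged by the adjustment.
    """
    n = len(ref_allele)
    size = int(rng.integers(spec.del_range[0], spec.del_range[1] + 1))
    if spec.mh_zero_inflation and rng.random() < spec.mh_zero_inflation:
        mh = 0
    else:
        mh = int(rng.integers(spec.mh_range[0], spec.mh_range[1] + 1))
    if n < size + mh + 3:
        raise ValueError("reference allele too short for the drawn deletion")
    a = int(rng.integers(2, n - size - mh + 1))  # 1-based deletion start
    seq = list(ref_allele)

    def force_diff(pos0: int, avoid: set[str]) -> None:
        choices = [b for b in "ACGT" if b not in avoid]
        seq[pos0] = choices[int(rng.integers(len(choices)))]

    # copy mh bases from just after the deletion onto its first mh bases
    for i in range(mh):
        seq[a - 1 + i] = seq[a + size - 1 + i]
    # cap the right-hand microhomology at exactly mh
    if mh < size:
        force_diff(a - 1 + mh, {seq[a + size - 1 + mh]})
    # forbid left-hand microhomology (makes the planted interval leftmost)
    force_diff(a + size - 2, {seq[a - 2]})
    ref_out = "".join(seq)

    inserted = ""
    if rng.random() < spec.p_insertion:
        k = int(rng.integers(spec.insertion_len_range[0],
                             spec.insertion_len_range[1] + 1))
        bases = [str(b) for b in rng.choice(list("ACGT"), size=k)]
        # pin the insertion: its ends must not extend ref matches
        avoid_first = {ref_out[a - 1]}
        avoid_last = {ref_out[a + size - 2]}
        if k == 1:
            choices = [b for b in "ACGT" if b not in avoid_first | avoid_last]
            bases[0] = choices[int(rng.integers(len(choices)))]
        else:
            bases[0] = [b for b in "ACGT" if b not in avoid_first][
                int(rng.integers(3))]
            bases[-1] = [b for b in "ACGT" if b not in avoid_last][
                int(rng.integers(3))]
        inserted = "".join(bases)

    derived = ref_out[: a - 1] + inserted + ref_out[a + size - 1:]
    truth = JunctionTruth((a, a + size - 1), size, mh, inserted)
    return ref_out, derived, truth


def generate_junction_fixtures(
    spec: JunctionSpec,
) -> list[tuple[str, str, JunctionTruth]]:
    """Reproducible cohort of (reference, derivative, truth) triples."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n):
        base = random_dna(spec.ref_len, spec.gc_content, rng)
        out.append(random_junction(base, spec, rng))
    return out


def random_sequence(length: int, gc_content: float = 0.38,
                    seed: int = 0) -> str:
    """I.i.d. random DNA with the given GC content, deterministic per seed."""
    return random_dna(length, gc_content, np.random.default_rng(seed))
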