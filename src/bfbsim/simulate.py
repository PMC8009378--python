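"""Stochastic breakage-fusion-bridge simulation of a conditional dicentric.

Each division of a cell carrying an active dicentric has ~50% probability of
an anaphase bridge and chromosome breakage. A break between the two
centromeres is resolved by one of four routes:

* SSA — single-strand annealing of the 336 bp homology shared by GALCEN3 and
  eCEN3, yielding a linear monocentric chromosome deleted for the
  inter-homology interval;
* RCO — reciprocal crossover at the same homology, yielding the SSA-like
  linear chromosome plus a circular monocentric derivative carrying the full
  inter-centromeric segment (circularization is folded into one composite
  event);
* EJ — end joining after two cuts flanking one centromere core, deleting the
  entire core (278-585 bp) and sealing the junction over 1-9 bp of
  microhomology; GALCEN3 is deleted ~70% of the time;
* refusion — the ends rejoin, regenerating the dicentric and continuing the
  BFB cycle.

Pathway propensities are distance-labelled calibration (not mechanistic
prediction), with per-genotype multiplicative modifiers. A colony is
approximated by its founder lineage: divisions iterate until the karyotype is
stably monocentric, death, or a cycle cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genome import (
    Chromosome,
    Karyotype,
    ReferenceGenome,
    Segment,
    cen_cen_distance,
)

__all__ = [
    "SimParams",
    "Genotype",
    "GENOTYPES",
    "RepairEvent",
    "ColonyFate",
    "sample_break_position",
    "attempt_division",
    "repair_break",
    "audit_viability",
    "run_colony",
    "simulate_plating",
]

PATHWAYS = ("SSA", "RCO", "EJ", "refusion")

#: Distance-labelled pathway weights, calibrated so that simulated colony
#: classes reproduce the observed regime structure: SSA-dominant at 6.5 kb,
#: EJ-dominant at 9.8-18.2 kb, crossover-dominant at 46.3 kb, mixed at
#: 57.7 kb. Refusion weight only sets how long BFB cycling lasts; it does not
#: change the terminal product distribution.
DEFAULT_PROPENSITIES: dict[float, dict[str, float]] = {
    6.5: {"SSA": 0.86, "RCO": 0.02, "EJ": 0.07, "refusion": 0.05},
    9.8: {"SSA": 0.02, "RCO": 0.04, "EJ": 0.88, "refusion": 0.06},
    12.3: {"SSA": 0.02, "RCO": 0.04, "EJ": 0.88, "refusion": 0.06},
    18.2: {"SSA": 0.02, "RCO": 0.04, "EJ": 0.88, "refusion": 0.06},
    46.3: {"SSA": 0.08, "RCO": 0.62, "EJ": 0.24, "refusion": 0.06},
    57.7: {"SSA": 0.12, "RCO": 0.38, "EJ": 0.42, "refusion": 0.08},
}


@dataclass(frozen=True)
class SimParams:
    p_break: float = 0.5
    break_locality_weight: float = 0.5
    locality_window: int = 10_000
    pathway_propensities: dict[float, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_PROPENSITIES.items()
        }
    )
    ej_galcen_bias: float = 0.7
    ej_del_range: tuple[int, int] = (278, 585)
    ej_mh_range: tuple[int, int] = (1, 9)
    p_nondisjunction: float = 0.01
    max_cycles: int = 20

    def __post_init__(self):
        for p in (self.p_break, self.break_locality_weight,
                  self.ej_galcen_bias, self.p_nondisjunction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.ej_del_range[0] > self.ej_del_range[1]:
            raise ValueError("empty ej_del_range")
        if self.ej_mh_range[0] > self.ej_mh_range[1] or self.ej_mh_range[0] < 0:
            raise ValueError("bad ej_mh_range")
        for label, weights in self.pathway_propensities.items():
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"negative propensity at {label} kb")

    def propensities_for(self, distance_kb: float) -> dict[str, float]:
        label = min(self.pathway_propensities,
                    key=lambda k: abs(k - distance_kb))
        return self.pathway_propensities[label]


@dataclass(frozen=True)
class Genotype:
    """Pathway availability of a repair-gene background.

    ``pathway_modifiers`` multiply the distance-labelled propensities before
    the pathway draw (renormalized). ``far_modifiers`` replace them when the
    CEN-CEN distance exceeds ``far_threshold_kb`` (used for the replication
    checkpoint mutant, whose defect is distance dependent).
    ``break_lethality`` is a per-break death probability by distance label —
    a phenomenological stand-in for the observed distance-dependent viability
    loss of recombination/checkpoint mutants, not a mechanistic claim.
    """

    name: str
    pathway_modifiers: dict[str, float] = field(default_factory=dict)
    far_modifiers: dict[str, float] | None = None
    far_threshold_kb: float = 20.0
    break_lethality: dict[float, float] = field(default_factory=dict)

    def __post_init__(self):
        for d in (self.pathway_modifiers, self.far_modifiers or {}):
            if any(v < 0 for v in d.values()):
                raise ValueError("modifiers must be >= 0")

    def modifiers_for(self, distance_kb: float) -> dict[str, float]:
        if self.far_modifiers is not None and distance_kb > self.far_threshold_kb:
            return self.far_modifiers
        return self.pathway_modifiers

    def lethality_for(self, distance_kb: float) -> float:
        if not self.break_lethality:
            return 0.0
        label = min(self.break_lethality, key=lambda k: abs(k - distance_kb))
        return self.break_lethality[label]


GENOTYPES: dict[str, Genotype] = {
    "WT": Genotype("WT"),
    "lif1": Genotype("lif1", pathway_modifiers={"EJ": 0.0}),
    "rad52": Genotype(
        "rad52",
        pathway_modifiers={"SSA": 0.0, "RCO": 0.0},
        break_lethality={6.5: 0.30, 9.8: 0.60, 12.3: 0.55, 18.2: 0.70,
                         46.3: 0.90, 57.7: 0.95},
    ),
    "mrc1": Genotype(
        "mrc1",
        far_modifiers={"SSA": 0.1, "RCO": 0.1},
        break_lethality={6.5: 0.0, 9.8: 0.0, 12.3: 0.0, 18.2: 0.0,
                         46.3: 0.85, 57.7: 0.90},
    ),
}


@dataclass(frozen=True)
class RepairEvent:
    pathway: str  # SSA | RCO | EJ | refusion | unrepaired
    break_pos: int
    deleted_interval: tuple[int, int] | None
    deleted_centromere: str  # GALCEN3 | eCEN3 | none
    mh_len: int
    products: tuple[Chromosome, ...]
    cycle_index: int = -1

    @property
    def deletion_size(self) -> int:
        if self.deleted_interval is None:
            return 0
        return self.deleted_interval[1] - self.deleted_interval[0] + 1


@dataclass(frozen=True)
class ColonyFate:
    viable: bool
    death_cause: str  # essential_gene_loss | unrepaired_after_max_cycles |
    # lethal_break | none
    fitness_flags: tuple[str, ...]
    final_karyotype: Karyotype
    event_log: tuple[RepairEvent, ...]


# ---------------------------------------------------------------------------
# break placement


def sample_break_position(ref: ReferenceGenome, params: SimParams,
                          rng: np.random.Generator) -> int:
    """Draw a break coordinate strictly between the two centromere cores.

    Mixture model: with weight ``break_locality_weight`` the position is
    uniform over the (clipped) windows within ``locality_window`` of either
    core; otherwise uniform over the whole inter-centromeric span.
    """
    cfg = ref.config
    left_core_end = cfg.galcen_core_interval[1]
    right_core_start = cfg.ecen_core_interval[0]
    lo, hi = left_core_end + 1, right_core_start - 1  # inclusive span
    if hi - lo + 1 < 1:
        raise ValueError("inter-centromeric span too small to break")
    w = params.break_locality_weight
    win = params.locality_window
    if rng.random() < w:
        left_hi = min(hi, left_core_end + win)
        right_lo = max(lo, right_core_start - win)
        if right_lo <= left_hi:  # windows cover the span
            return int(rng.integers(lo, hi + 1))
        n_left = left_hi - lo + 1
        n_right = hi - right_lo + 1
        k = int(rng.integers(n_left + n_right))
        return lo + k if k < n_left else right_lo + (k - n_left)
    return int(rng.integers(lo, hi + 1))


def locality_fraction(ref: ReferenceGenome, params: SimParams) -> float:
    """Closed-form probability that a sampled break lies within the locality
    windows (used as the analytical oracle for the mixture)."""
    cfg = ref.config
    lo = cfg.galcen_core_interval[1] + 1
    hi = cfg.ecen_core_interval[0] - 1
    span = hi - lo + 1
    left_hi = min(hi, cfg.galcen_core_interval[1] + params.locality_window)
    right_lo = max(lo, cfg.ecen_core_interval[0] - params.locality_window)
    if right_lo <= left_hi:
        window = span
    else:
        window = (left_hi - lo + 1) + (hi - right_lo + 1)
    w = params.break_locality_weight
    return w + (1.0 - w) * window / span


# ---------------------------------------------------------------------------
# repair


def _lcp(a: str, b: str, cap: int = 20) -> int:
    n = min(len(a), len(b), cap)
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _realized_mh(seq: str, a: int, size: int) -> int:
    """Microhomology the junction of deleting [a, a+size-1] (1-based) would
    show: matching run to the right of both cut sites plus matching run to
    the left of both."""
    right = _lcp(seq[a - 1:], seq[a + size - 1:])
    left = _lcp(seq[a - 2::-1], seq[a + size - 2::-1])
    return left + right


def _ej_deletion(ref: ReferenceGenome, which: str, params: SimParams,
                 rng: np.random.Generator) -> tuple[int, int, int]:
    """Choose an EJ deletion interval covering one whole centromere core.

    Two-cut abscission model: the deletion size is uniform on
    ``ej_del_range`` and the interval must cover the 125 bp core while
    leaving the flanking diagnostic primer sites intact. Placement is
    resampled until the junction's realized microhomology falls inside
    ``ej_mh_range`` — end joining preferentially seals where terminal
    microhomology exists. Returns (start, size, mh).
    """
    cfg = ref.config
    if which == "GALCEN3":
        core = cfg.galcen_core_interval
        region = cfg.cassette_interval
        margin_l, margin_r = 20, 20  # GC1 / GC2 site lengths
    else:
        core = cfg.ecen_core_interval
        region = cfg.ecen_region_interval
        margin_l, margin_r = 23, 21  # eC1 / eC2 site lengths
    size = int(rng.integers(params.ej_del_range[0],
                            params.ej_del_range[1] + 1))
    a_min = max(region[0] + margin_l, core[1] + 1 - size)
    a_max = min(core[0], region[1] - margin_r - size + 1)
    if a_min > a_max:
        raise ValueError(
            f"EJ deletion of {size} bp cannot cover the {which} core"
        )
    mh_lo, mh_hi = params.ej_mh_range
    best = None
    for _ in range(400):
        a = int(rng.integers(a_min, a_max + 1))
        mh = _realized_mh(ref.sequence, a, size)
        if mh_lo <= mh <= mh_hi:
            return a, size, mh
        if mh <= mh_hi and best is None:
            best = (a, mh)
    if best is None:  # pragma: no cover - not reachable on random sequence
        a = a_min
        best = (a, _realized_mh(ref.sequence, a, size))
    return best[0], size, best[1]


def repair_break(break_pos: int, ref: ReferenceGenome, params: SimParams,
                 genotype: Genotype,
                 rng: np.random.Generator) -> RepairEvent:
    """Resolve one dicentric break into a repair event and its products."""
    cfg = ref.config
    L = len(ref.sequence)
    dist = cen_cen_distance(ref)
    base = params.propensities_for(dist)
    mods = genotype.modifiers_for(dist)
    weights = {p: base.get(p, 0.0) * mods.get(p, 1.0) for p in PATHWAYS}
    total = sum(weights.values())
    if total <= 0.0:
        return RepairEvent("unrepaired", break_pos, None, "none", 0, ())
    pathway = str(
        rng.choice(PATHWAYS, p=[weights[p] / total for p in PATHWAYS])
    )

    hom_gal = cfg.cassette_homology_interval
    hom_ecen = cfg.ecen_homology_interval
    linear_deletion = Chromosome(
        "chrIII-linear-derivative",
        (Segment(1, hom_gal[1]), Segment(hom_ecen[1] + 1, L)),
        "linear",
    )
    if pathway == "SSA":
        deleted = (hom_gal[1] + 1, hom_ecen[1])
        return RepairEvent("SSA", break_pos, deleted, "none", 0,
                           (linear_deletion,))
    if pathway == "RCO":
        circle = Chromosome(
            "chrIII-reciprocal-circle",
            (Segment(hom_gal[1] + 1, hom_ecen[1]),),
            "circular",
        )
        return RepairEvent("RCO", break_pos, None, "none", 0,
                           (linear_deletion, circle))
    if pathway == "EJ":
        which = "GALCEN3" if rng.random() < params.ej_galcen_bias else "eCEN3"
        a, size, mh = _ej_deletion(ref, which, params, rng)
        product = Chromosome(
            "chrIII-ej-derivative",
            (Segment(1, a - 1), Segment(a + size, L)),
            "linear",
        )
        return RepairEvent("EJ", break_pos, (a, a + size - 1), which, mh,
                           (product,))
    # refusion: the ends rejoin and the dicentric persists.
    parent = Chromosome("chrIII-dicentric", (Segment(1, L),), "linear")
    return RepairEvent("refusion", break_pos, None, "none", 0, (parent,))


# ---------------------------------------------------------------------------
# division / colony


def attempt_division(
    karyotype: Karyotype, ref: ReferenceGenome, params: SimParams,
    genotype: Genotype, rng: np.random.Generator,
) -> tuple[list[Karyotype], RepairEvent | None]:
    """One division of the founder lineage.

    At most one dicentric breaks per division (each dicentric rolls
    ``p_break``; the first to break is repaired). With
    ``p_nondisjunction`` one chromosome is duplicated in the daughter.
    """
    chroms: list[Chromosome] = []
    event: RepairEvent | None = None
    for i, chrom in enumerate(karyotype):
        is_dicentric = chrom.centromere_count(ref) >= 2
        if is_dicentric and event is None and rng.random() < params.p_break:
            pos = sample_break_position(ref, params, rng)
            event = repair_break(pos, ref, params, genotype, rng)
            chroms.extend(event.products)
        else:
            chroms.append(chrom)
    if chroms and rng.random() < params.p_nondisjunction:
        chroms.append(chroms[int(rng.integers(len(chroms)))])
    return [Karyotype(tuple(chroms))], event


def audit_viability(karyotype: Karyotype,
                    ref: ReferenceGenome) -> tuple[bool, tuple[str, ...]]:
    """Viability and fitness flags of a (final) karyotype.

    Inviable iff an essential gene is absent from every chromosome or any
    chromosome lacks a centromere core. Loss of the fitness gene PGS1 flags
    slow growth without killing the colony.
    """
    if len(karyotype) == 0:
        return False, ()
    genes = [f for f in ref.features if f.kind == "gene"]
    flags: list[str] = []
    viable = True
    for g in genes:
        present = any(c.contains_interval(g.interval) for c in karyotype)
        if not present:
            if g.essentiality == "essential":
                viable = False
            elif g.essentiality == "fitness":
                flags.append("slow_growth")
    if any(c.centromere_count(ref) == 0 for c in karyotype):
        viable = False
    return viable, tuple(sorted(set(flags)))


def run_colony(ref: ReferenceGenome, params: SimParams, genotype: Genotype,
               rng: np.random.Generator) -> ColonyFate:
    """Iterate founder-lineage divisions until the karyotype is stably
    monocentric, the colony dies, or ``max_cycles`` is reached."""
    karyotype = ref.initial_karyotype()
    events: list[RepairEvent] = []
    dist = cen_cen_distance(ref)
    lethality = genotype.lethality_for(dist)
    for cycle in range(params.max_cycles):
        if not karyotype.dicentrics(ref):
            break
        daughters, event = attempt_division(
            karyotype, ref, params, genotype, rng
        )
        karyotype = daughters[0]
        if event is not None:
            events.append(replace(event, cycle_index=cycle))
            if event.pathway == "unrepaired":
                return ColonyFate(False, "unrepaired_after_max_cycles", (),
                                  karyotype, tuple(events))
            if lethality > 0.0 and rng.random() < lethality:
                return ColonyFate(False, "lethal_break", (), karyotype,
                                  tuple(events))
    viable, flags = audit_viability(karyotype, ref)
    cause = "none" if viable else "essential_gene_loss"
    return ColonyFate(viable, cause, flags, karyotype, tuple(events))


def simulate_plating(ref: ReferenceGenome, params: SimParams,
                     genotype: Genotype, n_colonies: int,
                     seed: int) -> list[ColonyFate]:
    """Simulate plating of ``n_colonies`` independent founder cells.

    Each colony gets its own substream derived from (seed, index), so cohorts
    are reproducible and order independent.
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    fates = []
    for i in range(n_colonies):
        rng = np.random.default_rng([seed, i])
        fates.append(run_colony(ref, params, genotype, rng))
    return fates
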