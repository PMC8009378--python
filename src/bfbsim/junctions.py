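"""Deletion-junction analysis of derivative alleles.

Given a reference allele and a shorter derivative (e.g. a sequenced
centromere-deletion PCR product), locate the deletion, recover any inserted
bases, and decompose the junction into flanking microhomology. Breakpoints
inside microhomology are ambiguous; the canonical call is the leftmost
placement (VCF-style left alignment) and ``placements`` counts the
equivalent positions (microhomology + 1 for insertion-free junctions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "JunctionCall",
    "JunctionCohortStats",
    "find_deletion",
    "microhomology",
    "label_mechanism",
    "junction_cohort_stats",
    "brute_force_placements",
]


@dataclass(frozen=True)
class JunctionCall:
    deletion_interval: tuple[int, int]  # 1-based inclusive, leftmost placement
    deletion_size: int
    inserted_bases: str
    mh_left: int
    mh_right: int
    mh_total: int
    placements: int
    mechanism_label: str = "unlabelled"

    def __post_init__(self):
        if not self.inserted_bases:
            assert self.placements == self.mh_total + 1


@dataclass(frozen=True)
class JunctionCohortStats:
    n: int
    deletion_min: int
    deletion_max: int
    deletion_median: float
    mh_histogram: dict[int, int]
    fraction_with_insertion: float
    all_cover_core: bool | None = None


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def find_deletion(ref_allele: str, derived_allele: str,
                  mmej_threshold: int = 5,
                  max_insertion: int | None = 50) -> JunctionCall:
    """Locate the deletion (and any insertion) turning ref into derived.

    The derivative must be shorter than the reference and explainable by a
    single deletion, optionally with novel inserted bases at the junction.
    The reported interval is the leftmost equivalent placement. An implied
    insertion longer than ``max_insertion`` indicates the alleles differ by
    more than one junction (multiple disjoint mismatch blocks) and raises —
    full realignment of such products is out of scope.
    """
    if not ref_allele or not derived_allele:
        raise ValueError("alleles must be non-empty")
    if len(derived_allele) >= len(ref_allele):
        raise ValueError("derived allele must be shorter than the reference")
    n_ref, n_der = len(ref_allele), len(derived_allele)
    s = min(_lcp(ref_allele[::-1], derived_allele[::-1]), n_der)
    p = min(_lcp(ref_allele, derived_allele), n_der - s)
    inserted = derived_allele[p: n_der - s]
    if max_insertion is not None and len(inserted) > max_insertion:
        raise ValueError(
            f"junction implies a {len(inserted)} bp insertion; the alleles "
            "likely differ by multiple mismatch blocks (realignment out of "
            "scope)"
        )
    d_start, d_end = p + 1, n_ref - s
    if not inserted:
        mh_left0, _, _, _ = microhomology(ref_allele, (d_start, d_end))
        d_start -= mh_left0
        d_end -= mh_left0
    mh_left, mh_right, mh_total, placements = microhomology(
        ref_allele, (d_start, d_end)
    )
    call = JunctionCall(
        (d_start, d_end), d_end - d_start + 1, inserted,
        mh_left, mh_right, mh_total,
        1 if inserted else placements,
    )
    return label_mechanism(call, mmej_threshold)


def microhomology(ref_allele: str,
                  interval: tuple[int, int]) -> tuple[int, int, int, int]:
    """Microhomology decomposition of a deletion interval.

    Returns (mh_left, mh_right, mh_total, placements): the matching run to
    the left of both breakpoints, the matching run to the right, their sum,
    and the count of equivalent same-size deletions (mh_total + 1).
    """
    d, e = interval
    if not (1 <= d <= e <= len(ref_allele)):
        raise ValueError(f"interval {interval} outside the reference")
    mh_right = _lcp(ref_allele[d - 1:], ref_allele[e:])
    mh_left = _lcp(ref_allele[d - 2:: -1], ref_allele[e - 1:: -1]) \
        if d > 1 else 0
    # equivalent placements form the contiguous run
    # [d - mh_left, d + mh_right]; both runs are bounded by the reference
    # ends through the slice lengths above
    placements = mh_left + mh_right + 1
    return mh_left, mh_right, mh_left + mh_right, placements


def brute_force_placements(ref_allele: str, derived_allele: str) -> int:
    """Oracle: count equal-length deletions of ref reproducing derived."""
    size = len(ref_allele) - len(derived_allele)
    if size <= 0:
        raise ValueError("derived must be shorter")
    count = 0
    for a in range(len(ref_allele) - size + 1):
        if ref_allele[:a] + ref_allele[a + size:] == derived_allele:
            count += 1
    return count


def label_mechanism(call: JunctionCall, threshold_mmej: int = 5) -> JunctionCall:
    """Label the joining mechanism from junction microhomology.

    >= threshold (default 5 bp) microhomology suggests MMEJ; <= 1 bp with no
    insertion suggests NHEJ; anything in between is ambiguous. The 1-9 bp
    homology range observed at such junctions does not dichotomize sharply,
    so the threshold is a configurable convention.
    """
    if call.mh_total >= threshold_mmej:
        label = "MMEJ"
    elif call.mh_total <= 1 and not call.inserted_bases:
        label = "NHEJ"
    else:
        label = "ambiguous"
    return JunctionCall(
        call.deletion_interval, call.deletion_size, call.inserted_bases,
        call.mh_left, call.mh_right, call.mh_total, call.placements, label,
    )


def junction_cohort_stats(
    calls: list[JunctionCall],
    core_interval: tuple[int, int] | None = None,
) -> JunctionCohortStats:
    """Aggregate deletion sizes and microhomology over a junction cohort.

    When ``core_interval`` is given (reference-allele coordinates of the
    centromere core), also audits that every deletion removes the whole
    core — every placement of an ambiguous junction deletes the same
    multiset of bases, so the audit uses the maximal slid extent.
    """
    if not calls:
        raise ValueError("empty cohort")
    sizes = np.array([c.deletion_size for c in calls])
    hist: dict[int, int] = {}
    for c in calls:
        hist[c.mh_total] = hist.get(c.mh_total, 0) + 1
    covers = None
    if core_interval is not None:
        covers = all(
            c.deletion_interval[0] <= core_interval[0]
            and core_interval[1] <= c.deletion_interval[1] + c.mh_total
            for c in calls
        )
    return JunctionCohortStats(
        n=len(calls),
        deletion_min=int(sizes.min()),
        deletion_max=int(sizes.max()),
        deletion_median=float(np.median(sizes)),
        mh_histogram=dict(sorted(hist.items())),
        fraction_with_insertion=float(
            np.mean([bool(c.inserted_bases) for c in calls])
        ),
        all_cover_core=covers,
    )


def calls_to_table(calls: list[JunctionCall],
                   ids: list[str] | None = None) -> pd.DataFrame:
    ids = ids or [f"junction_{i + 1}" for i in range(len(calls))]
    rows = []
    for cid, c in zip(ids, calls):
        rows.append({
            "id": cid,
            "del_start": c.deletion_interval[0],
            "del_end": c.deletion_interval[1],
            "del_size": c.deletion_size,
            "insertion": c.inserted_bases,
            "mh_left": c.mh_left,
            "mh_right": c.mh_right,
            "mh_total": c.mh_total,
            "placements": c.placements,
            "label": c.mechanism_label,
        })
    return pd.DataFrame(rows)
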