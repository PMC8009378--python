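"""Sequence/coordinate model for the engineered dicentric chromosome III.

Builds a synthetic chromosome-III-like reference carrying the endogenous
centromere (eCEN3, coordinate 114,300) and a conditional GAL-promoter
centromere cassette (GALCEN3) at one of six insertion coordinates. All public
coordinates are 1-based inclusive (SGD-style); BED export converts to 0-based
half-open.

The background sequence is random with configurable GC content; only the
engineered features (centromere cores, the 336 bp shared homology block, the
four diagnostic primer sites, the GAL promoter stub, gene and Ty-element
annotations) are placed at their published coordinates. The GALCEN3 cassette
*overwrites* a window of the background rather than lengthening the molecule,
so a single coordinate frame covers both centromeres.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "ConfigurationError",
    "GenomeConfig",
    "Feature",
    "ReferenceGenome",
    "Segment",
    "Chromosome",
    "Karyotype",
    "PRIMERS",
    "PAPER_KB_LABELS",
    "build_reference",
    "cen_cen_distance",
    "longest_shared_substring",
    "realize_sequence",
    "reverse_complement",
]


class ConfigurationError(ValueError):
    """Raised when a GenomeConfig cannot be realized as a valid reference."""


# Diagnostic primers. GC1/GC2 probe the GALCEN3 cassette, eC1/eC2 the
# endogenous centromere; the hybrid pairs GC1-eC2 (rearrangement) and eC1-GC2
# (reciprocal) detect recombinant centromeres.
PRIMERS: dict[str, str] = {
    "GC1": "TCGACTACGCGATCATGGCG",
    "GC2": "CACGATGCGTCCGGCGTAGA",
    "eC1": "TCAATAGCTTGCAGCGTAGCTAA",
    "eC2": "GGGTGGGAAACTGAAGAAATC",
}

#: Printed kb labels for the six published insertion coordinates. Two labels
#: (96,020 and 56,740) disagree with round-half-up arithmetic on the printed
#: coordinates; ``cen_cen_distance`` always reports the computed value and
#: this table preserves the published wording.
PAPER_KB_LABELS: dict[int, str] = {
    107_830: "6.5",
    104_458: "9.8",
    101_976: "12.3",
    96_020: "18.2",
    68_000: "46.3",
    56_740: "57.7",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# Locus layout, as offsets from the first base of each 125 bp centromere core.
# eCEN3 locus (native background except the written primer sites):
#   eC1 site, ~175 bp margin, 336 bp homology block containing the core at
#   internal offset 105, margin, reverse-complemented eC2 site. The amplicon
#   spans eC1 start .. eC2 end.
# GALCEN3 cassette (932 bp written verbatim over the background):
#   GC1 site, 200 bp GAL-promoter stub, a verbatim copy of the 336 bp eCEN3
#   homology block, spacer, reverse-complemented GC2 site.
_HOM_OFF = -105          # homology block start relative to core start
_HOM_LEN = 336
_CORE_IN_HOM = 105       # core offset inside the homology block
_GC1_OFF = -325          # cassette/amplicon start relative to core start
_GAL_PROM_LEN = 200
_EC1_OFF = -300          # eCEN3 amplicon start relative to core start


Essentiality = Literal["essential", "fitness", "neutral"]


@dataclass(frozen=True)
class GenomeConfig:
    """Parameters of one engineered dicentric configuration."""

    insertion_pos: int = 107_830
    ecen3_pos: int = 114_300
    cen_core_len: int = 125
    ssa_homology_len: int = 336
    galcen_amplicon_len: int = 932
    ecen_amplicon_len: int = 900
    ty2_span: tuple[int, int] = (84_811, 90_769)
    chrom_len: int = 316_620
    gc_content: float = 0.38
    gene_annotations: tuple[tuple[str, tuple[int, int], Essentiality], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not self.gene_annotations:
            object.__setattr__(
                self, "gene_annotations", _default_genes()
            )
        self.validate()

    def validate(self) -> None:
        if self.insertion_pos == self.ecen3_pos:
            raise ConfigurationError(
                "insertion coincides with eCEN3 (CEN-CEN distance 0)"
            )
        if not (self.insertion_pos < self.ecen3_pos):
            raise ConfigurationError("insertion_pos must lie left of ecen3_pos")
        if self.ssa_homology_len < self.cen_core_len:
            raise ConfigurationError(
                "shared homology must contain the centromere core"
            )
        if self.galcen_amplicon_len < 700 or self.ecen_amplicon_len < 700:
            raise ConfigurationError("diagnostic amplicons must be >= 700 bp")
        for iv in (self.cassette_interval, self.ecen_region_interval,
                   self.ty2_span):
            if iv[0] < 1 or iv[1] > self.chrom_len:
                raise ConfigurationError(f"interval {iv} outside chromosome")
        if _overlap(self.cassette_interval, self.ecen_region_interval):
            raise ConfigurationError(
                "GALCEN3 cassette collides with the eCEN3 locus"
            )
        for name, iv, _ in self.gene_annotations:
            if iv[0] > iv[1] or iv[0] < 1 or iv[1] > self.chrom_len:
                raise ConfigurationError(f"gene {name}: bad interval {iv}")
            for core in (self.galcen_core_interval, self.ecen_core_interval):
                if _overlap(iv, core):
                    raise ConfigurationError(
                        f"gene {name} overlaps a centromere core"
                    )
            if _overlap(iv, self.cassette_interval):
                raise ConfigurationError(
                    f"gene {name} overlaps the GALCEN3 cassette"
                )

    # -- derived intervals (all 1-based inclusive) --------------------------

    @property
    def galcen_core_interval(self) -> tuple[int, int]:
        return (self.insertion_pos, self.insertion_pos + self.cen_core_len - 1)

    @property
    def ecen_core_interval(self) -> tuple[int, int]:
        return (self.ecen3_pos, self.ecen3_pos + self.cen_core_len - 1)

    @property
    def cassette_interval(self) -> tuple[int, int]:
        start = self.insertion_pos + _GC1_OFF
        return (start, start + self.galcen_amplicon_len - 1)

    @property
    def cassette_homology_interval(self) -> tuple[int, int]:
        start = self.insertion_pos + _HOM_OFF
        return (start, start + self.ssa_homology_len - 1)

    @property
    def ecen_homology_interval(self) -> tuple[int, int]:
        start = self.ecen3_pos + _HOM_OFF
        return (start, start + self.ssa_homology_len - 1)

    @property
    def ecen_region_interval(self) -> tuple[int, int]:
        start = self.ecen3_pos + _EC1_OFF
        return (start, start + self.ecen_amplicon_len - 1)


def _default_genes() -> tuple[tuple[str, tuple[int, int], Essentiality], ...]:
    """NFS1/RRP7/PGS1 placed at the midpoints of their flanking intervals.

    Exact gene coordinates are not needed: only which repair deletions remove
    them matters, i.e. interval membership between insertion sites.
    """
    def mid(lo: int, hi: int, length: int = 1500) -> tuple[int, int]:
        c = (lo + hi) // 2
        return (c - length // 2, c - length // 2 + length - 1)

    return (
        ("RRP7", mid(56_740, 68_000), "essential"),
        ("NFS1", mid(68_000, 96_020), "essential"),
        ("PGS1", mid(107_830, 114_300), "fitness"),
    )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


@dataclass(frozen=True)
class Feature:
    name: str
    interval: tuple[int, int]
    kind: Literal[
        "centromere_core", "homology_block", "gal_promoter", "gene",
        "ty_element", "primer_site",
    ]
    essentiality: Essentiality | None = None
    strand: str = "+"

    def __post_init__(self):
        if self.interval[0] > self.interval[1]:
            raise ValueError(f"feature {self.name}: start > end")


@dataclass(frozen=True)
class Segment:
    """A contiguous oriented slice of the reference, 1-based inclusive."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, iv: tuple[int, int]) -> bool:
        return self.start <= iv[0] and iv[1] <= self.end


@dataclass(frozen=True)
class Chromosome:
    name: str
    segments: tuple[Segment, ...]
    topology: Literal["linear", "circular"] = "linear"

    def __post_init__(self):
        if not self.segments:
            raise ValueError("chromosome needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    def __len__(self) -> int:
        return sum(len(s) for s in self.segments)

    def contains_interval(self, iv: tuple[int, int]) -> bool:
        return any(s.contains(iv) for s in self.segments)

    def centromere_count(self, ref: "ReferenceGenome") -> int:
        return sum(
            1
            for f in ref.features
            if f.kind == "centromere_core" and self.contains_interval(f.interval)
        )


@dataclass(frozen=True)
class Karyotype:
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def dicentrics(self, ref: "ReferenceGenome") -> list[int]:
        """Indices of chromosomes carrying two or more centromere cores."""
        return [
            i for i, c in enumerate(self.chromosomes)
            if c.centromere_count(ref) >= 2
        ]


@dataclass(frozen=True)
class ReferenceGenome:
    sequence: str
    features: tuple[Feature, ...]
    primer_sites: dict[str, tuple[int, str]]
    config: GenomeConfig

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def subseq(self, iv: tuple[int, int]) -> str:
        return self.sequence[iv[0] - 1: iv[1]]

    @property
    def cassette_sequence(self) -> str:
        return self.subseq(self.config.cassette_interval)

    @property
    def ecen_region_sequence(self) -> str:
        return self.subseq(self.config.ecen_region_interval)

    def initial_karyotype(self) -> Karyotype:
        """The unbroken engineered dicentric as a single linear chromosome."""
        chrom = Chromosome(
            "chrIII-dicentric",
            (Segment(1, len(self.sequence)),),
            "linear",
        )
        return Karyotype((chrom,))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, gc_content: float, rng: np.random.Generator) -> str:
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[at, gc, gc, at])
    return "".join(bases)


def build_reference(config: GenomeConfig) -> ReferenceGenome:
    """Construct the engineered dicentric reference for one configuration.

    Deterministic for a fixed config (including its seed). The cassette's
    336 bp homology block is copied verbatim from the eCEN3 region, and the
    bases immediately flanking the copy are forced to mismatch their eCEN3
    counterparts so the shared block is exactly ``ssa_homology_len`` long.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    seq = np.frombuffer(
        random_dna(cfg.chrom_len, cfg.gc_content, rng).encode(), dtype="S1"
    ).copy()

    def write(pos: int, s: str) -> None:  # pos 1-based
        seq[pos - 1: pos - 1 + len(s)] = np.frombuffer(s.encode(), dtype="S1")

    def read(iv: tuple[int, int]) -> str:
        return seq[iv[0] - 1: iv[1]].tobytes().decode()

    # eCEN3 locus: write the convergent eC1 / eC2 sites into the background;
    # the homology block and core are native background sequence.
    ec_start, ec_end = cfg.ecen_region_interval
    write(ec_start, PRIMERS["eC1"])
    write(ec_end - len(PRIMERS["eC2"]) + 1, reverse_complement(PRIMERS["eC2"]))

    hom = read(cfg.ecen_homology_interval)

    # GALCEN3 cassette, written over the background in one piece.
    spacer_len = (
        cfg.galcen_amplicon_len
        - len(PRIMERS["GC1"]) - _GAL_PROM_LEN - cfg.ssa_homology_len
        - len(PRIMERS["GC2"])
    )
    if spacer_len < 10:
        raise ConfigurationError("galcen_amplicon_len too short for layout")
    gal_prom = random_dna(_GAL_PROM_LEN, cfg.gc_content, rng)
    spacer = random_dna(spacer_len, cfg.gc_content, rng)
    # Force mismatches at the bases flanking the homology copy so the longest
    # shared substring with the eCEN3 region is exactly the block.
    left_native = read((cfg.ecen_homology_interval[0] - 1,) * 2)
    right_native = read((cfg.ecen_homology_interval[1] + 1,) * 2)
    gal_prom = gal_prom[:-1] + _different_base(left_native, rng)
    spacer = _different_base(right_native, rng) + spacer[1:]
    cassette = (
        PRIMERS["GC1"] + gal_prom + hom + spacer
        + reverse_complement(PRIMERS["GC2"])
    )
    assert len(cassette) == cfg.galcen_amplicon_len
    write(cfg.cassette_interval[0], cassette)

    sequence = seq.tobytes().decode()

    features = _make_features(cfg)
    primer_sites = {
        "GC1": (cfg.cassette_interval[0], "+"),
        "GC2": (cfg.cassette_interval[1] - len(PRIMERS["GC2"]) + 1, "-"),
        "eC1": (ec_start, "+"),
        "eC2": (ec_end - len(PRIMERS["eC2"]) + 1, "-"),
    }
    ref = ReferenceGenome(sequence, features, primer_sites, cfg)
    _verify_reference(ref)
    return ref


def _different_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(len(choices)))]


def _make_features(cfg: GenomeConfig) -> tuple[Feature, ...]:
    feats: list[Feature] = [
        Feature("GALCEN3_core", cfg.galcen_core_interval, "centromere_core"),
        Feature("eCEN3_core", cfg.ecen_core_interval, "centromere_core"),
        Feature("GALCEN3_homology", cfg.cassette_homology_interval,
                "homology_block"),
        Feature("eCEN3_homology", cfg.ecen_homology_interval,
                "homology_block"),
        Feature(
            "GAL_promoter",
            (cfg.cassette_interval[0] + len(PRIMERS["GC1"]),
             cfg.cassette_homology_interval[0] - 1),
            "gal_promoter",
        ),
        Feature("Ty2-1", cfg.ty2_span, "ty_element"),
    ]
    for name, iv, ess in cfg.gene_annotations:
        feats.append(Feature(name, iv, "gene", essentiality=ess))
    for name, length, pos, strand in (
        ("GC1", len(PRIMERS["GC1"]), cfg.cassette_interval[0], "+"),
        ("GC2", len(PRIMERS["GC2"]),
         cfg.cassette_interval[1] - len(PRIMERS["GC2"]) + 1, "-"),
        ("eC1", len(PRIMERS["eC1"]), cfg.ecen_region_interval[0], "+"),
        ("eC2", len(PRIMERS["eC2"]),
         cfg.ecen_region_interval[1] - len(PRIMERS["eC2"]) + 1, "-"),
    ):
        feats.append(
            Feature(f"primer_{name}", (pos, pos + length - 1), "primer_site",
                    strand=strand)
        )
    return tuple(feats)


def _verify_reference(ref: ReferenceGenome) -> None:
    """Each diagnostic primer must occur exactly once (either strand)."""
    for name, primer in PRIMERS.items():
        hits = ref.sequence.count(primer) + ref.sequence.count(
            reverse_complement(primer)
        )
        if hits != 1:
            raise ConfigurationError(
                f"primer {name} occurs {hits} times in the built reference"
            )


def cen_cen_distance(ref: ReferenceGenome) -> float:
    """Distance between the two centromeres in kb, round-half-up, 1 decimal."""
    cores = [f for f in ref.features if f.kind == "centromere_core"]
    if len(cores) < 2:
        raise ValueError("reference is monocentric; no CEN-CEN distance")
    bp = abs(ref.config.ecen3_pos - ref.config.insertion_pos)
    kb = (Decimal(bp) / Decimal(1000)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(kb)


def longest_shared_substring(a: str, b: str) -> int:
    """Length of the longest exact common substring (forward strand)."""
    if not a or not b:
        raise ValueError("inputs must be non-empty")
    m = difflib.SequenceMatcher(None, a, b, autojunk=False)
    return m.find_longest_match(0, len(a), 0, len(b)).size


def realize_sequence(chrom: Chromosome, ref: ReferenceGenome) -> str:
    """Concatenated oriented sequence of a derivative chromosome.

    Circular chromosomes are returned at a declared rotation: the segment
    with the lowest source start coordinate comes first.
    """
    segs = list(chrom.segments)
    for s in segs:
        if s.start < 1 or s.end > len(ref.sequence):
            raise ValueError(f"segment {s} outside the reference")
    if chrom.topology == "circular" and len(segs) > 1:
        k = min(range(len(segs)), key=lambda i: segs[i].start)
        segs = segs[k:] + segs[:k]
    parts = []
    for s in segs:
        piece = ref.sequence[s.start - 1: s.end]
        parts.append(piece if s.strand == "+" else reverse_complement(piece))
    return "".join(parts)


def chromosome_feature_names(chrom: Chromosome, ref: ReferenceGenome,
                             kinds: Iterable[str] | None = None) -> set[str]:
    """Names of reference features wholly contained in the chromosome."""
    kinds = set(kinds) if kinds is not None else None
    return {
        f.name
        for f in ref.features
        if (kinds is None or f.kind in kinds)
        and chrom.contains_interval(f.interval)
    }
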