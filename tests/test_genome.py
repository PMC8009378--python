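"""Reference construction, coordinates, and sequence plumbing."""

import pytest

from bfbsim import (
    ConfigurationError,
    GenomeConfig,
    PAPER_KB_LABELS,
    PRIMERS,
    build_reference,
    cen_cen_distance,
    longest_shared_substring,
    realize_sequence,
    reverse_complement,
)
from bfbsim.genome import Chromosome, Segment
from bfbsim.io import (
    FastaParseError,
    read_bed,
    read_config,
    read_fasta,
    write_bed,
    write_config,
    write_fasta,
)
from bfbsim.simulate import GENOTYPES, SimParams, repair_break

import numpy as np


@pytest.mark.parametrize(
    "insertion,expected_kb",
    [
        (107_830, 6.5),
        (104_458, 9.8),
        (101_976, 12.3),
        (96_020, 18.3),   # printed label 18.2; computed round-half-up value
        (68_000, 46.3),
        (56_740, 57.6),   # printed label 57.7; computed round-half-up value
        (114_300 - 1000, 1.0),
    ],
)
def test_cen_cen_distance(insertion, expected_kb):
    ref = build_reference(GenomeConfig(insertion_pos=insertion, seed=0))
    assert cen_cen_distance(ref) == expected_kb


def test_paper_labels_cover_all_six_insertions():
    assert set(PAPER_KB_LABELS) == {
        107_830, 104_458, 101_976, 96_020, 68_000, 56_740,
    }


def test_zero_distance_insertion_rejected():
    with pytest.raises(ConfigurationError):
        GenomeConfig(insertion_pos=114_300)


def test_cassette_collision_with_ecen_locus_rejected():
    # a cassette ending inside the eCEN3 amplicon region is a broken design
    with pytest.raises(ConfigurationError):
        GenomeConfig(insertion_pos=114_300 - 400)


def test_gene_overlapping_core_rejected():
    genes = (("BAD", (114_250, 115_000), "essential"),)
    with pytest.raises(ConfigurationError):
        GenomeConfig(insertion_pos=68_000, gene_annotations=genes)


def test_longest_shared_substring_basics():
    assert longest_shared_substring("ACGTACGT", "ACGTACGT") == 8
    assert longest_shared_substring("AAAA", "CCCC") == 0
    with pytest.raises(ValueError):
        longest_shared_substring("", "ACGT")


def test_cassette_shares_exactly_336bp_with_ecen_region(ref463):
    assert longest_shared_substring(
        ref463.cassette_sequence, ref463.ecen_region_sequence
    ) == 336


def test_deleting_homology_block_breaks_the_shared_336bp(ref463):
    cfg = ref463.config
    cass_start = cfg.cassette_interval[0]
    h0 = cfg.cassette_homology_interval[0] - cass_start
    h1 = cfg.cassette_homology_interval[1] - cass_start + 1
    cassette = ref463.cassette_sequence
    gutted = cassette[:h0] + cassette[h1:]
    assert longest_shared_substring(
        gutted, ref463.ecen_region_sequence
    ) < 336


def test_build_is_deterministic_and_seed_sensitive():
    a = build_reference(GenomeConfig(insertion_pos=68_000, seed=7))
    b = build_reference(GenomeConfig(insertion_pos=68_000, seed=7))
    c = build_reference(GenomeConfig(insertion_pos=68_000, seed=8))
    assert a.sequence == b.sequence
    assert a.sequence != c.sequence


@pytest.mark.parametrize("insertion", [107_830, 96_020, 56_740])
def test_primers_occur_once_and_converge(insertion):
    ref = build_reference(GenomeConfig(insertion_pos=insertion, seed=3))
    for name, primer in PRIMERS.items():
        fwd = ref.sequence.count(primer)
        rev = ref.sequence.count(reverse_complement(primer))
        assert fwd + rev == 1, name
    # convergent orientation: upstream primers on +, downstream on -
    assert ref.primer_sites["GC1"][1] == "+"
    assert ref.primer_sites["GC2"][1] == "-"
    assert ref.primer_sites["eC1"][1] == "+"
    assert ref.primer_sites["eC2"][1] == "-"
    assert ref.primer_sites["GC1"][0] < ref.primer_sites["GC2"][0]
    assert ref.primer_sites["eC1"][0] < ref.primer_sites["eC2"][0]


def test_realize_full_and_reverse_segments(ref463):
    L = len(ref463.sequence)
    full = Chromosome("c", (Segment(1, L),))
    assert realize_sequence(full, ref463) == ref463.sequence
    rev = Chromosome("c", (Segment(100, 200, "-"),))
    assert realize_sequence(rev, ref463) == reverse_complement(
        ref463.sequence[99:200]
    )
    with pytest.raises(ValueError):
        realize_sequence(Chromosome("c", (Segment(1, L + 5),)), ref463)


def test_rco_circle_length_matches_cen_cen_distance(ref463):
    # oracle: the circular product carries exactly the inter-centromeric DNA
    rng = np.random.default_rng(0)
    while True:
        ev = repair_break(100_000, ref463, SimParams(), GENOTYPES["WT"], rng)
        if ev.pathway == "RCO":
            break
    circle = [c for c in ev.products if c.topology == "circular"][0]
    assert abs(len(circle) - 46_300) <= 336
    assert len(realize_sequence(circle, ref463)) == len(circle)


def test_fasta_round_trip(tmp_path, ref65):
    path = tmp_path / "ref.fa"
    write_fasta({"chrIII": ref65.sequence}, path)
    back = read_fasta(path)
    assert back == {"chrIII": ref65.sequence}


def test_malformed_fasta_reports_line_number(tmp_path):
    bad = tmp_path / "bad.fa"
    bad.write_text("ACGT\n>late_header\nACGT\n")
    with pytest.raises(FastaParseError, match="line 1"):
        read_fasta(bad)


def test_bed_export_uses_zero_based_half_open(tmp_path, ref65):
    path = tmp_path / "ref.bed"
    write_bed(ref65.features, path)
    rows = {name: (s, e) for _, s, e, name in read_bed(path)}
    assert rows["Ty2-1"] == (84_810, 90_769)


def test_empty_feature_list_yields_valid_empty_bed(tmp_path):
    path = tmp_path / "empty.bed"
    write_bed([], path)
    assert read_bed(path) == []


def test_config_yaml_round_trip(tmp_path):
    cfg = GenomeConfig(insertion_pos=96_020, seed=11)
    path = tmp_path / "cfg.yaml"
    write_config(cfg, path)
    assert read_config(path) == cfg
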