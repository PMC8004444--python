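"""Marker screen: pre-filter, flanks, mismatch-tolerant uniqueness,
conservation, and the planted ground-truth pipeline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kaspforge.genotype_io import ChromosomeMismatchError, Genome, SnpLocus, revcomp
from kaspforge.marker_screen import (
    AmbiguousFlankError,
    FlankEdgeError,
    InvalidQueryError,
    PanelVariantIndex,
    ScreenConfig,
    ScreenConfigError,
    count_genomic_matches,
    extract_flank,
    is_unique,
    prefilter_loci,
    primer_region_conserved,
    screen,
    write_candidates_tsv,
)
from kaspforge.snp_stats import LocusStats, SubstitutionClass, compute_all_stats


def _locus(chrom, pos, ref="A", alts=("G",), patterns=("A", "G")):
    return SnpLocus(chrom, pos, ref, tuple(alts), tuple(patterns))


def _stats(chrom, pos, pic_value):
    return LocusStats(
        chrom=chrom, pos=pos, ref="A", pattern_counts={}, pattern_freqs={},
        n_genotyped=100, n_missing=0, pic=pic_value,
        substitution=SubstitutionClass.TRANSITION, label="A>G",
    )


# ---------------------------------------------------------------------------
# Pre-filter
# ---------------------------------------------------------------------------

def test_prefilter_removes_only_high_missing_loci(make_matrix):
    """Planted missingness {5, 20, 25} at threshold 20 -> only 25 removed."""
    n = 50
    def calls(n_missing):
        return ["A"] * (n - n_missing - 10) + ["G"] * 10 + [None] * n_missing
    m = make_matrix(
        [
            ("chr1", 100, "A", calls(5)),
            ("chr1", 200, "A", calls(20)),
            ("chr1", 300, "A", calls(25)),
            ("chr1", 400, "A", calls(0)),
        ]
    )
    out = prefilter_loci(m, ScreenConfig(max_missing_samples=20))
    assert [l.pos for l in out.loci] == [100, 200, 400]


def test_prefilter_may_empty_the_panel(make_matrix):
    m = make_matrix([("chr1", 100, "A", ["A", "G", None, None])])
    out = prefilter_loci(m, ScreenConfig(max_missing_samples=1))
    assert out.n_loci == 0


# ---------------------------------------------------------------------------
# Flank extraction
# ---------------------------------------------------------------------------

def test_extract_flank_direct_indexing():
    genome = Genome({"chr1": "ACGTACGTAC"})
    flank = extract_flank(genome, _locus("chr1", 9), "upstream", 4)
    # upstream flank ends at snp_pos - 1: positions 5-8
    assert (flank.start, flank.end) == (5, 8)
    assert flank.seq == "ACGT"
    down = extract_flank(genome, _locus("chr1", 5), "downstream", 4)
    assert (down.start, down.end) == (6, 9) and down.seq == "CGTA"


def test_extract_flank_edge_rejection():
    genome = Genome({"chr1": "ACGTACGTAC"})
    with pytest.raises(FlankEdgeError):
        extract_flank(genome, _locus("chr1", 3), "upstream", 20)
    with pytest.raises(FlankEdgeError):
        extract_flank(genome, _locus("chr1", 9), "downstream", 4)


def test_extract_flank_ambiguity_rejection():
    genome = Genome({"chr1": "ACGTNCGTACGT"})
    with pytest.raises(AmbiguousFlankError):
        extract_flank(genome, _locus("chr1", 8), "upstream", 5)


# ---------------------------------------------------------------------------
# Uniqueness search
# ---------------------------------------------------------------------------

def test_single_copy_query_is_self_hit(random_genome_100kb):
    query = random_genome_100kb.seq("chr1")[5_000:5_020]
    assert count_genomic_matches(random_genome_100kb, query, 0) == 1
    assert is_unique(random_genome_100kb, query, 1)


def test_polya_run_sliding_hits():
    """A 24-base poly-A run holds 5 sliding windows for a 20xA query."""
    rng = np.random.default_rng(7)
    left = "".join("CG"[(i % 2)] for i in range(500))  # A-free filler
    right = "".join(np.array(list("CGT"))[rng.integers(0, 3, 500)])
    genome = Genome({"chr1": left + "A" * 24 + right})
    assert count_genomic_matches(genome, "A" * 20, 0) == 5


def test_strand_symmetry(random_genome_100kb):
    rng = np.random.default_rng(3)
    for _ in range(5):
        start = int(rng.integers(0, 99_000))
        q = random_genome_100kb.seq("chr1")[start : start + 20]
        for mm in (0, 1, 2):
            assert count_genomic_matches(
                random_genome_100kb, q, mm
            ) == count_genomic_matches(random_genome_100kb, revcomp(q), mm)


def test_query_validation():
    genome = Genome({"chr1": "ACGT" * 100})
    with pytest.raises(InvalidQueryError):
        count_genomic_matches(genome, "ACGTN" + "A" * 15, 1)
    with pytest.raises(InvalidQueryError):
        count_genomic_matches(genome, "ACGTACGT", 1)  # < 10 bp
    with pytest.raises(InvalidQueryError):
        count_genomic_matches(genome, "A" * 20, 3)


def test_two_copy_repeat_is_not_unique():
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))
    bg = "".join(bases[rng.integers(0, 4, 4_000)])
    unit = "".join(bases[rng.integers(0, 4, 60)])
    genome = Genome({"chr1": bg[:1000] + unit + bg[1000:2000] + unit + bg[2000:]})
    assert count_genomic_matches(genome, unit[10:30], 0) == 2
    assert not is_unique(genome, unit[10:30], 2)


def test_pigeonhole_matches_brute_force(brute_force_counts):
    """Seed-and-verify search agrees with a quadratic Hamming scan."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    genome = Genome({"chr1": "".join(bases[rng.integers(0, 4, 20_000)])})
    seq = genome.seq("chr1")
    for i in range(60):
        if i % 2 == 0:  # genuine genomic windows (guaranteed hits)
            start = int(rng.integers(0, 19_980))
            q = seq[start : start + 20]
        else:  # random queries (mostly zero hits)
            q = "".join(bases[rng.integers(0, 4, 20)])
        expected = brute_force_counts(genome, q)
        for mm in (0, 1, 2):
            assert count_genomic_matches(genome, q, mm) == expected[mm], (i, mm, q)


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

def test_primer_region_conserved_thresholds():
    index = PanelVariantIndex(
        [_stats("chr1", 105, 0.35), _stats("chr1", 205, 0.05), _stats("chr1", 305, None)]
    )
    assert not primer_region_conserved(("chr1", 100, 119), index, 0.2)
    assert primer_region_conserved(("chr1", 200, 219), index, 0.2)  # low-PIC tolerated
    assert primer_region_conserved(("chr1", 300, 319), index, 0.2)  # undefined PIC ignored
    assert primer_region_conserved(("chr1", 400, 419), index, 0.2)  # vacuous


# ---------------------------------------------------------------------------
# Full screen against planted truth
# ---------------------------------------------------------------------------

def _observed_outcomes(pfix, result):
    tiers = {c.locus.key: c.tier for c in result.candidates}
    out = {}
    for t in pfix.truth:
        if t.planted_kind is None:
            continue
        out[t.key] = tiers.get(t.key) or result.rejections.get(t.key)
    return out


def test_screen_matches_planted_truth_table(planted_bundle):
    """Every planted locus lands exactly where its prescription says."""
    _, _, pfix, result = planted_bundle
    observed = _observed_outcomes(pfix, result)
    expected = {
        t.key: t.expected_screen for t in pfix.truth if t.planted_kind is not None
    }
    assert observed == expected


def test_screen_core_subset_and_tally_conservation(planted_bundle):
    _, _, pfix, result = planted_bundle
    core = {c.locus.key for c in result.candidates if c.tier == "core"}
    standard = {c.locus.key for c in result.candidates}
    assert core <= standard
    assert result.conservation_check(pfix.matrix.n_loci)
    # candidates sorted by (chromosome order, position)
    keys = [(c.locus.chrom, c.locus.pos) for c in result.candidates]
    assert keys == sorted(keys)


def test_prefilter_drops_exactly_the_high_missing_planted_loci(planted_bundle):
    _, _, pfix, _ = planted_bundle
    filtered = prefilter_loci(pfix.matrix, ScreenConfig())
    kept = {l.key for l in filtered.loci}
    for t in pfix.truth:
        if t.planted_kind in ("fail_prefilter", "fail_genotyped"):
            assert t.key not in kept  # both exceed 20 missing calls
        elif t.planted_kind is not None:
            assert t.key in kept


@pytest.mark.parametrize(
    "tightened",
    [
        dict(min_pic=0.45),
        dict(min_genotyped=200),
        dict(max_mismatch_standard=2, max_mismatch_core=2),
        dict(conservation_pic_standard=0.1, conservation_pic_core=0.1),
    ],
)
def test_threshold_monotonicity(planted_bundle, tightened):
    """Tightening any single threshold never adds candidates."""
    _, gfix, pfix, baseline = planted_bundle
    strict = screen(pfix.matrix, gfix.genome, ScreenConfig(**tightened))
    assert {c.locus.key for c in strict.candidates} <= {
        c.locus.key for c in baseline.candidates
    }


def test_screen_determinism_byte_identical(planted_bundle, tmp_path):
    _, gfix, pfix, _ = planted_bundle
    paths = []
    for i in (1, 2):
        result = screen(pfix.matrix, gfix.genome, ScreenConfig())
        p = tmp_path / f"cand{i}.tsv"
        write_candidates_tsv(result.candidates, p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_screen_unknown_chromosome_raises(make_matrix):
    genome = Genome({"chr1": "ACGT" * 1000})
    m = make_matrix([("chrX", 100, "A", ["A", "G", "A", "G"])])
    with pytest.raises(ChromosomeMismatchError):
        screen(m, genome)


def test_screen_requires_genome(make_matrix):
    m = make_matrix([("chr1", 100, "A", ["A", "G"])])
    with pytest.raises(ScreenConfigError):
        screen(m, None)


def test_config_invariants():
    with pytest.raises(ScreenConfigError):
        ScreenConfig(max_mismatch_standard=2, max_mismatch_core=1)
    with pytest.raises(ScreenConfigError):
        ScreenConfig(conservation_pic_standard=0.1, conservation_pic_core=0.2)
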