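"""Polymorphism statistics: PIC, substitution classes, Ts/Tv, summaries."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kaspforge.snp_stats import (
    SubstitutionClass,
    UndefinedPicError,
    classify_substitution,
    compute_all_stats,
    pattern_spectrum,
    pic,
    summarize_panel,
    tstv_ratio,
)
from kaspforge.synthetic_fixtures import FixtureSpec, generate_fixture


@pytest.mark.parametrize(
    "freqs,expected",
    [
        ({"A": 0.5, "G": 0.5}, 0.50),  # bi-allelic maximum
        ({"A": 1.0}, 0.0),  # monomorphic
        ({"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}, 0.75),  # four-allele maximum
        ({"A": 0.7, "G": 0.3}, 0.42),  # 1 - (0.49 + 0.09)
    ],
)
def test_pic_closed_forms(freqs, expected):
    assert pic(freqs) == pytest.approx(expected, abs=1e-12)


def test_pic_errors():
    with pytest.raises(UndefinedPicError):
        pic({})
    with pytest.raises(ValueError):
        pic({"A": 0.6, "G": 0.6})
    with pytest.raises(ValueError):
        pic({"A": 1.2, "G": -0.2})


@given(
    st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=4)
)
def test_pic_bounded_by_equal_frequency_maximum(raw):
    """PIC <= 1 - 1/k for any k-pattern frequency vector (simplex draw)."""
    total = sum(raw)
    freqs = [v / total for v in raw]
    k = len(freqs)
    value = pic(freqs)
    assert -1e-12 <= value <= 1 - 1 / k + 1e-12


@given(st.permutations(["A", "C", "G", "T"]), st.lists(
    st.floats(min_value=0.01, max_value=1.0), min_size=4, max_size=4))
def test_pic_invariant_under_pattern_relabeling(perm, raw):
    total = sum(raw)
    freqs = [v / total for v in raw]
    direct = pic(dict(zip("ACGT", freqs)))
    relabeled = pic(dict(zip(perm, freqs)))
    assert direct == pytest.approx(relabeled, abs=1e-15)


# ---------------------------------------------------------------------------
# Substitution classification
# ---------------------------------------------------------------------------

def test_classify_directional_labels():
    assert classify_substitution("T", "C") == (SubstitutionClass.TRANSITION, "T>C")
    assert classify_substitution("A", "T") == (SubstitutionClass.TRANSVERSION, "A>T")
    assert classify_substitution("C", "T")[1] == "C>T"  # direction preserved


def test_classify_all_twelve_ordered_pairs():
    classes = [
        classify_substitution(r, a)[0]
        for r, a in itertools.permutations("ACGT", 2)
    ]
    assert classes.count(SubstitutionClass.TRANSITION) == 4
    assert classes.count(SubstitutionClass.TRANSVERSION) == 8


def test_classify_rejects_bad_input():
    with pytest.raises(ValueError):
        classify_substitution("N", "A")
    with pytest.raises(ValueError):
        classify_substitution("A", "A")


# ---------------------------------------------------------------------------
# Pattern spectrum
# ---------------------------------------------------------------------------

def test_pattern_spectrum_symmetric_site(make_matrix):
    m = make_matrix([("chr1", 10, "A", ["A", "A", "G", "G"])])
    s = pattern_spectrum(m, 0)
    assert s.pattern_freqs == {"A": 0.5, "G": 0.5}
    assert s.pic == pytest.approx(0.5)
    assert s.substitution is SubstitutionClass.TRANSITION and s.label == "A>G"


def test_pattern_spectrum_with_missing(make_matrix):
    m = make_matrix([("chr1", 10, "A", ["A", "A", "A", None])])
    s = pattern_spectrum(m, 0)
    assert s.pattern_freqs == {"A": 1.0}
    assert s.n_genotyped == 3 and s.n_missing == 1
    assert s.pic == 0.0


def test_pattern_spectrum_all_missing_flags_undefined_pic(make_matrix):
    m = make_matrix(
        [("chr1", 10, "A", [None, None]), ("chr1", 20, "C", ["C", "T"])]
    )
    s = pattern_spectrum(m, 0)
    assert s.n_genotyped == 0 and s.pic is None


def test_generator_frequency_within_binomial_interval():
    """Observed minor-pattern frequencies sit inside the 99% binomial band of
    the generator's targets (n = 200 samples)."""
    spec = FixtureSpec(seed=21, n_loci=50, n_samples=200, missing_rate=0.0)
    _, pfix = generate_fixture(spec, None)
    stats = compute_all_stats(pfix.matrix)
    truth = pfix.truth_by_key
    z = 2.576
    for s in stats:
        t = truth[(s.chrom, s.pos)]
        for p_target, pat in zip(t.target_freqs, t.patterns):
            if pat not in s.pattern_freqs:
                continue
            half = z * math.sqrt(p_target * (1 - p_target) / 200) + 1 / 200
            assert abs(s.pattern_freqs[pat] - p_target) <= half


# ---------------------------------------------------------------------------
# Ts/Tv
# ---------------------------------------------------------------------------

def test_tstv_basic(make_matrix):
    m = make_matrix(
        [
            ("chr1", 10, "A", ["A", "G"]),  # transition
            ("chr1", 20, "C", ["C", "T"]),  # transition
            ("chr1", 30, "A", ["A", "T"]),  # transversion
            ("chr1", 40, "G", ["G", "C"]),  # transversion
        ]
    )
    assert tstv_ratio(compute_all_stats(m)) == pytest.approx(1.0)


def test_tstv_no_transversions_is_infinite(make_matrix):
    m = make_matrix([("chr1", 10, "A", ["A", "G"])])
    assert math.isinf(tstv_ratio(compute_all_stats(m)))


def test_tstv_degenerate_input():
    with pytest.raises(ValueError):
        tstv_ratio([])


def test_tstv_simulation_recovery():
    """A panel generated at Ts:Tv 2:1 recovers the target within the 99%
    multinomial interval at 3,000 loci."""
    spec = FixtureSpec(
        seed=17, n_loci=3_000, n_chrom=4, chrom_len=540_000, tstv_target=2.0
    )
    _, pfix = generate_fixture(spec, None)
    stats = compute_all_stats(pfix.matrix)
    ratio = tstv_ratio(stats)
    n_bi = sum(1 for s in stats if s.substitution is not SubstitutionClass.NOT_BIALLELIC)
    p = 2.0 / 3.0
    half = 2.576 * math.sqrt(p * (1 - p) / n_bi)
    lo, hi = (p - half) / (1 - p + half), (p + half) / (1 - p - half)
    assert lo <= ratio <= hi


# ---------------------------------------------------------------------------
# Panel summary
# ---------------------------------------------------------------------------

def test_summary_histogram_conservation(make_matrix):
    m = make_matrix(
        [
            ("chr1", 10, "A", ["A", "G", "A", "G"]),
            ("chr1", 20, "C", ["C", "C", "C", "C"]),
            ("chr2", 30, "G", ["G", "T", "T", "T"]),
            ("chr2", 40, "T", ["T", "C", "G", "A"]),
        ]
    )
    summary = summarize_panel(m)
    assert sum(c for _, _, c in summary.pic_hist) == 4
    assert summary.per_chrom_counts == {"chr1": 2, "chr2": 2}
    assert sum(summary.pattern_count_fractions.values()) == pytest.approx(1.0)


def test_summary_biallelic_fraction(make_matrix):
    """92 bi-allelic of 100 loci -> pattern-count fraction 0.92."""
    loci = [("chr1", 10 * (i + 1), "A", ["A", "G", "A", "G"]) for i in range(92)]
    loci += [("chr1", 10_000 + 10 * i, "A", ["A", "G", "T", "T"]) for i in range(8)]
    summary = summarize_panel(make_matrix(loci))
    assert summary.pattern_count_fractions[2] == pytest.approx(0.92)
    assert summary.pattern_count_fractions[3] == pytest.approx(0.08)


def test_summary_mean_pic(make_matrix):
    m = make_matrix(
        [("chr1", 10, "A", ["A", "G"] * 2), ("chr1", 20, "C", ["C", "T"] * 2)]
    )
    stats = compute_all_stats(m)
    stats[0].pic, stats[1].pic = 0.1, 0.3
    assert summarize_panel(m, stats).mean_pic == pytest.approx(0.2)
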