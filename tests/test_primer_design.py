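"""Primer construction: allele-specific forwards, Tm model, reverse picker."""

from __future__ import annotations

import math

import numpy as np
import pytest

from kaspforge.genotype_io import Genome, SnpLocus, revcomp
from kaspforge.marker_screen import FlankSequence, PanelVariantIndex
from kaspforge.primer_design import (
    DesignConstraints,
    DesignFailure,
    allele_specific_forward,
    design_all,
    design_kasp,
    gc_content,
    melting_temperature,
    pick_common_reverse,
    write_order_sheet,
)
from kaspforge.snp_stats import LocusStats, SubstitutionClass


def _flank(seq, pos, chrom="chr1"):
    return FlankSequence(seq, chrom, pos - len(seq), pos - 1, "upstream")


def _stats(chrom, pos, pic_value):
    return LocusStats(
        chrom=chrom, pos=pos, ref="A", pattern_counts={}, pattern_freqs={},
        n_genotyped=100, n_missing=0, pic=pic_value,
        substitution=SubstitutionClass.TRANSITION, label="A>G",
    )


# ---------------------------------------------------------------------------
# Allele-specific forward primers
# ---------------------------------------------------------------------------

def test_forward_bodies_differ_only_at_three_prime_base():
    c = DesignConstraints()
    flank = _flank("ACGTACGTACGTACGTACGT", 100)
    fam, hexp = allele_specific_forward(flank, "A", "G", c)
    assert fam == c.tail_fam + flank.seq + "A"
    assert hexp == c.tail_hex + flank.seq + "G"
    assert len(fam) == len(c.tail_fam) + 21
    body_fam = fam[len(c.tail_fam):]
    body_hex = hexp[len(c.tail_hex):]
    assert body_fam[:-1] == body_hex[:-1] and body_fam[-1] != body_hex[-1]


def test_forward_dye_assignment_is_alphabetical():
    c = DesignConstraints()
    flank = _flank("ACGTACGTACGTACGTACGT", 100)
    fam_gA, hex_gA = allele_specific_forward(flank, "G", "A", c)
    fam_aG, hex_aG = allele_specific_forward(flank, "A", "G", c)
    assert fam_gA == fam_aG and hex_gA == hex_aG  # swap changes nothing
    assert fam_gA.endswith("A") and hex_gA.endswith("G")


def test_forward_short_flank_fails():
    with pytest.raises(DesignFailure):
        allele_specific_forward(_flank("ACGTACGT", 100), "A", "G")


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------

# Unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K), the same
# published table the implementation is configured with; this oracle computes
# the thermodynamic sum from scratch.
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_R = 1.987


def _oracle_tm(seq, na_mm=50.0, conc_nm=250.0):
    dh, ds = 0.0, 0.0
    for term in (seq[0], seq[-1]):
        h, s = _INIT_AT if term in "AT" else _INIT_GC
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        h, s = _NN[pair] if pair in _NN else _NN[revcomp(pair)]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mm / 1000.0)  # salt correction
    k = conc_nm * 1e-9
    return (1000.0 * dh) / (ds + _R * math.log(k)) - 273.15


def test_tm_agrees_with_independent_oracle():
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    for _ in range(10):
        seq = "".join(bases[rng.integers(0, 4, 20)])
        assert melting_temperature(seq) == pytest.approx(_oracle_tm(seq), abs=0.5)


def test_tm_gc_monotonicity_and_duplex_symmetry():
    at, gc = "AT" * 10, "GC" * 10
    assert melting_temperature(at) < melting_temperature(gc)
    seq = "ACGTTGCAGGTACCTAGGAT"
    assert melting_temperature(seq) == pytest.approx(
        melting_temperature(revcomp(seq)), abs=1e-6
    )


def test_tm_input_validation():
    with pytest.raises(ValueError):
        melting_temperature("ACGTN" + "ACGT" * 4)
    with pytest.raises(ValueError):
        melting_temperature("ACGTA")


# ---------------------------------------------------------------------------
# Common reverse primer picker
# ---------------------------------------------------------------------------

_ISLAND = "GATC" * 5  # GC 0.50; every shifted window drops below 0.48


def _one_window_genome(snp_pos=40, island_offset=10, fill="T"):
    """One admissible 20-bp window downstream of the SNP; all other windows
    fail the (narrow) GC constraint."""
    rng = np.random.default_rng(2)
    upstream = "".join(np.array(list("ACGT"))[rng.integers(0, 4, snp_pos)])
    downstream = fill * island_offset + _ISLAND + fill * 200
    return Genome({"chr1": upstream + downstream}), SnpLocus(
        "chr1", snp_pos, upstream[snp_pos - 1], ("G",) if upstream[snp_pos - 1] != "G" else ("A",),
        ("A", "G"),
    )


_NARROW = DesignConstraints(
    reverse_len_range=(20, 20),
    reverse_gc_range=(0.48, 0.52),
    reverse_tm_range=(0.0, 100.0),
    max_terminal_run=5,
)


def test_single_admissible_window_is_chosen():
    genome, locus = _one_window_genome()
    pick = pick_common_reverse(genome, locus, _NARROW)
    assert (pick.window_start, pick.window_end) == (51, 70)
    assert pick.primer == revcomp(_ISLAND)
    assert pick.gc == pytest.approx(0.5)


def test_reverse_window_with_polymorphic_snp_is_excluded():
    genome, locus = _one_window_genome()
    index = PanelVariantIndex([_stats("chr1", 60, 0.5)])  # inside the only window
    with pytest.raises(DesignFailure) as err:
        pick_common_reverse(genome, locus, _NARROW, index)
    assert err.value.rejections.get("conservation", 0) >= 1


def test_equal_tm_tie_broken_by_shorter_amplicon():
    rng = np.random.default_rng(2)
    upstream = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
    downstream = "T" * 10 + _ISLAND + "T" * 30 + _ISLAND + "T" * 100
    genome = Genome({"chr1": upstream + downstream})
    locus = SnpLocus("chr1", 40, upstream[39], ("G",) if upstream[39] != "G" else ("A",), ("A", "G"))
    pick = pick_common_reverse(genome, locus, _NARROW)
    assert pick.window_start == 51  # the nearer of two identical islands


def test_no_admissible_window_reports_counts():
    genome = Genome({"chr1": "ACGTACGTACGTACGTACGTA" + "T" * 200})
    locus = SnpLocus("chr1", 21, "A", ("G",), ("A", "G"))
    with pytest.raises(DesignFailure) as err:
        pick_common_reverse(genome, locus, _NARROW)
    assert sum(err.value.rejections.values()) > 0


# ---------------------------------------------------------------------------
# Full design
# ---------------------------------------------------------------------------

def test_design_yield_on_validation_style_candidates(design_bundle):
    """At least 90% of clean screened markers yield a full primer set."""
    gfix, _, result = design_bundle
    index = PanelVariantIndex(result.stats)
    designed, failures = design_all(result.candidates, gfix.genome, None, index)
    assert len(result.candidates) == 50
    assert len(designed) >= 45
    constraints = DesignConstraints()
    for ps in designed:
        body_fam = ps.fam_primer[len(constraints.tail_fam):]
        body_hex = ps.hex_primer[len(constraints.tail_hex):]
        assert body_fam[:-1] == body_hex[:-1] and body_fam[-1] != body_hex[-1]
        assert (
            ps.body_len + constraints.reverse_len_range[0]
            <= ps.amplicon_len
            <= ps.body_len + constraints.reverse_search_window
        )


def test_reverse_primer_self_consistency(design_bundle):
    """Each emitted reverse primer re-locates uniquely inside its amplicon."""
    gfix, _, result = design_bundle
    designed, _ = design_all(result.candidates[:10], gfix.genome)
    for ps in designed:
        chrom = ps.marker_id.split(":")[0]
        start, end = ps.reverse_window
        window = gfix.genome.fetch(chrom, start, end)
        assert revcomp(ps.common_reverse) == window
        pos = int(ps.marker_id.split(":")[1])
        amplicon = gfix.genome.fetch(chrom, pos - 20, end)
        assert amplicon.count(window) == 1


def test_design_determinism_byte_identical(design_bundle, tmp_path):
    gfix, _, result = design_bundle
    index = PanelVariantIndex(result.stats)
    paths = []
    for i in (1, 2):
        designed, _ = design_all(result.candidates, gfix.genome, None, index)
        p = tmp_path / f"primers{i}.csv"
        write_order_sheet(designed, p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_design_kasp_invariants(design_bundle):
    gfix, _, result = design_bundle
    index = PanelVariantIndex(result.stats)
    ps = design_kasp(result.candidates[0], gfix.genome, None, index)
    locus = result.candidates[0].locus
    # forward body 3' terminus sits on the SNP; amplicon spans body..window end
    assert ps.amplicon_len == ps.reverse_window[1] - (locus.pos - 20) + 1
    assert ps.fam_allele < ps.hex_allele
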