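"""KASP assay primer construction.

Each marker gets a primer triplet: two allele-specific forward primers whose
3' terminal base sits exactly on the SNP (one per allele, each carrying a
distinct universal tail read out as FAM or HEX), plus one common reverse
primer picked from the downstream sequence under explicit Primer3-style
constraints (length, melting temperature, GC content, 3' homopolymer clamp,
and absence of polymorphic panel SNPs in the primer footprint).

Melting temperatures use the nearest-neighbor model (Biopython's ``Tm_NN``
with its default unified parameter table) under fixed, documented conditions:
Na+ 50 mM, primer strand 250 nM (no template excess), SantaLucia 1998 salt
correction. Any single stated Tm convention works for constraint screening;
this one is pinned so designs are deterministic and cross-checkable.

Design is a pure function of (genome, candidate, constraints): reruns are
byte-identical.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqUtils import MeltingTemp, gc_fraction

from .genotype_io import Genome, SnpLocus, VALID_BASES, revcomp
from .marker_screen import FlankSequence, MarkerCandidate, PanelVariantIndex

logger = logging.getLogger(__name__)

__all__ = [
    "DesignConstraints",
    "PrimerSet",
    "ReversePick",
    "DesignFailure",
    "allele_specific_forward",
    "melting_temperature",
    "gc_content",
    "pick_common_reverse",
    "design_kasp",
    "design_all",
    "write_order_sheet",
    "FAM_TAIL",
    "HEX_TAIL",
]

# Standard published universal KASP tail pair (overridable in constraints).
FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"

# Fixed Tm conditions (see module docstring).
_TM_NA_MM = 50.0
_TM_DNAC1_NM = 250.0
_TM_SALTCORR = 5  # SantaLucia 1998 entropic correction


class DesignFailure(Exception):
    """No admissible primer under the given constraints.

    ``rejections`` maps constraint name -> number of windows it eliminated
    (first-failed attribution, fixed order).
    """

    def __init__(self, message: str, rejections: Mapping[str, int] | None = None) -> None:
        super().__init__(message)
        self.rejections = dict(rejections or {})


@dataclass(frozen=True)
class DesignConstraints:
    """Explicit, deterministic reverse-primer constraints.

    ``reverse_tm_range`` is midpoint-targeted: among admissible windows the
    one whose Tm is closest to the range midpoint wins, ties broken by
    shorter amplicon then lower window start.
    """

    tail_fam: str = FAM_TAIL
    tail_hex: str = HEX_TAIL
    reverse_len_range: tuple[int, int] = (18, 25)
    reverse_tm_range: tuple[float, float] = (57.0, 63.0)
    reverse_gc_range: tuple[float, float] = (0.30, 0.65)
    reverse_search_window: int = 150
    max_terminal_run: int = 3
    conservation_pic: float = 0.2
    min_body_len: int = 18

    def __post_init__(self) -> None:
        for tail in (self.tail_fam, self.tail_hex):
            if any(b not in VALID_BASES for b in tail):
                raise ValueError("KASP tails must be ACGT-only")
        for lo, hi in (self.reverse_len_range, self.reverse_tm_range, self.reverse_gc_range):
            if lo > hi:
                raise ValueError("constraint ranges must be non-empty")

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignConstraints":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown design constraint keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("reverse_len_range", "reverse_tm_range", "reverse_gc_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "DesignConstraints":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data.get("design", data))


@dataclass(frozen=True)
class ReversePick:
    """The selected common reverse primer and its plus-strand footprint."""

    primer: str  # reverse complement of the plus-strand window
    window_start: int  # 1-based inclusive, plus strand
    window_end: int
    tm: float
    gc: float


@dataclass(frozen=True)
class PrimerSet:
    """A complete KASP triplet with diagnostics."""

    marker_id: str
    fam_primer: str  # tail + allele-specific body (3' base = FAM allele)
    hex_primer: str
    fam_allele: str
    hex_allele: str
    common_reverse: str
    body_len: int
    body_tm: float
    reverse_tm: float
    reverse_gc: float
    amplicon_len: int
    reverse_window: tuple[int, int]  # plus-strand 1-based inclusive


# ---------------------------------------------------------------------------
# Sequence diagnostics
# ---------------------------------------------------------------------------

def melting_temperature(seq: str) -> float:
    """Nearest-neighbor Tm (degrees C) under the module's fixed conditions."""
    s = seq.upper()
    if len(s) < 8:
        raise ValueError(f"sequence too short for a meaningful Tm ({len(s)} < 8)")
    if any(b not in VALID_BASES for b in s):
        raise ValueError("Tm input must be ACGT-only")
    return float(
        MeltingTemp.Tm_NN(
            s,
            Na=_TM_NA_MM,
            dnac1=_TM_DNAC1_NM,
            dnac2=0,
            saltcorr=_TM_SALTCORR,
        )
    )


def gc_content(seq: str) -> float:
    return float(gc_fraction(seq))


def _terminal_run(seq: str) -> int:
    """Length of the identical-base run at the 3' end."""
    run = 1
    for i in range(len(seq) - 2, -1, -1):
        if seq[i] == seq[-1]:
            run += 1
        else:
            break
    return run


# ---------------------------------------------------------------------------
# Allele-specific forward primers
# ---------------------------------------------------------------------------

def allele_specific_forward(
    flank: FlankSequence,
    allele1: str,
    allele2: str,
    constraints: DesignConstraints | None = None,
) -> tuple[str, str]:
    """Build the tailed allele-specific forward primer pair.

    The primer body is the upstream flank plus the allele base, so the 3'
    terminus interrogates the SNP. Dye assignment is normalised: FAM gets the
    alphabetically first allele, HEX the second, regardless of input order.
    """
    constraints = constraints or DesignConstraints()
    if flank.side != "upstream":
        raise ValueError("allele-specific primers are built from the upstream flank")
    for a in (allele1, allele2):
        if a not in VALID_BASES:
            raise ValueError(f"invalid allele base {a!r}")
    if allele1 == allele2:
        raise ValueError("the two alleles must differ")
    if len(flank.seq) + 1 < constraints.min_body_len:
        raise DesignFailure(
            f"flank of {len(flank.seq)} bp is shorter than the minimum primer "
            f"body ({constraints.min_body_len}) minus the SNP base"
        )
    fam_allele, hex_allele = sorted((allele1, allele2))
    fam = constraints.tail_fam + flank.seq + fam_allele
    hexp = constraints.tail_hex + flank.seq + hex_allele
    return fam, hexp


# ---------------------------------------------------------------------------
# Common reverse primer
# ---------------------------------------------------------------------------

_REVERSE_REJECTION_ORDER = ("ambiguous", "conservation", "gc", "terminal_run", "tm")


def pick_common_reverse(
    genome: Genome,
    locus: SnpLocus,
    constraints: DesignConstraints | None = None,
    panel_index: PanelVariantIndex | None = None,
) -> ReversePick:
    """Scan downstream windows and return the best admissible reverse primer.

    All (start, length) windows whose plus-strand footprint lies within
    ``reverse_search_window`` bp strictly downstream of the SNP are tested
    against the constraints; the survivor with Tm closest to the Tm-range
    midpoint wins, ties broken by shorter amplicon then lower start. With no
    survivor a :class:`DesignFailure` carrying per-constraint rejection
    counts is raised.
    """
    constraints = constraints or DesignConstraints()
    chrom_len = genome.length(locus.chrom)
    lo_len, hi_len = constraints.reverse_len_range
    tm_lo, tm_hi = constraints.reverse_tm_range
    tm_mid = (tm_lo + tm_hi) / 2.0
    gc_lo, gc_hi = constraints.reverse_gc_range
    region_end = min(chrom_len, locus.pos + constraints.reverse_search_window)

    rejections = {k: 0 for k in _REVERSE_REJECTION_ORDER}
    best: tuple[float, int, int, ReversePick] | None = None  # (|Tm-mid|, end, start, pick)

    for start in range(locus.pos + 1, region_end - lo_len + 2):
        for length in range(lo_len, hi_len + 1):
            end = start + length - 1
            if end > region_end:
                break
            window = genome.fetch(locus.chrom, start, end)
            if any(b not in VALID_BASES for b in window):
                rejections["ambiguous"] += 1
                continue
            if panel_index is not None and not panel_index.conserved(
                locus.chrom, start, end, constraints.conservation_pic
            ):
                rejections["conservation"] += 1
                continue
            gc = gc_content(window)
            if not gc_lo <= gc <= gc_hi:
                rejections["gc"] += 1
                continue
            primer = revcomp(window)
            if _terminal_run(primer) > constraints.max_terminal_run:
                rejections["terminal_run"] += 1
                continue
            tm = melting_temperature(primer)
            if not tm_lo <= tm <= tm_hi:
                rejections["tm"] += 1
                continue
            key = (abs(tm - tm_mid), end, start)
            if best is None or key < best[:3]:
                best = (*key, ReversePick(primer, start, end, tm, gc))

    if best is None:
        raise DesignFailure(
            f"{locus.chrom}:{locus.pos}: no admissible reverse-primer window "
            f"within {constraints.reverse_search_window} bp downstream",
            rejections={k: v for k, v in rejections.items() if v},
        )
    return best[3]


# ---------------------------------------------------------------------------
# Full assay design
# ---------------------------------------------------------------------------

def design_kasp(
    candidate: MarkerCandidate,
    genome: Genome,
    constraints: DesignConstraints | None = None,
    panel_index: PanelVariantIndex | None = None,
) -> PrimerSet:
    """Compose the allele-specific forward pair and the common reverse primer.

    Raises :class:`DesignFailure` (with the reverse picker's per-constraint
    rejection counts) when no admissible reverse window exists.
    """
    constraints = constraints or DesignConstraints()
    locus = candidate.locus
    a1, a2 = candidate.alleles
    fam, hexp = allele_specific_forward(candidate.upstream_flank, a1, a2, constraints)
    fam_allele, hex_allele = sorted((a1, a2))
    pick = pick_common_reverse(genome, locus, constraints, panel_index)

    body = candidate.upstream_flank.seq + fam_allele
    body_start = candidate.upstream_flank.start
    amplicon_len = pick.window_end - body_start + 1

    return PrimerSet(
        marker_id=f"{locus.chrom}:{locus.pos}",
        fam_primer=fam,
        hex_primer=hexp,
        fam_allele=fam_allele,
        hex_allele=hex_allele,
        common_reverse=pick.primer,
        body_len=len(body),
        body_tm=melting_temperature(body),
        reverse_tm=pick.tm,
        reverse_gc=pick.gc,
        amplicon_len=amplicon_len,
        reverse_window=(pick.window_start, pick.window_end),
    )


def design_all(
    candidates: Sequence[MarkerCandidate],
    genome: Genome,
    constraints: DesignConstraints | None = None,
    panel_index: PanelVariantIndex | None = None,
) -> tuple[list[PrimerSet], dict[str, str]]:
    """Design every candidate; returns (primer sets, marker_id -> failure reason)."""
    designed: list[PrimerSet] = []
    failures: dict[str, str] = {}
    for cand in candidates:
        try:
            designed.append(design_kasp(cand, genome, constraints, panel_index))
        except DesignFailure as exc:
            failures[f"{cand.locus.chrom}:{cand.locus.pos}"] = str(exc)
    if failures:
        logger.info("primer design failed for %d/%d candidates", len(failures), len(candidates))
    return designed, failures


_SHEET_COLUMNS = [
    "marker_id", "fam_allele", "hex_allele", "fam_primer", "hex_primer",
    "common_reverse", "body_len", "body_tm", "reverse_tm", "reverse_gc",
    "amplicon_len",
]


def write_order_sheet(primer_sets: Sequence[PrimerSet], path: str | Path) -> None:
    """CSV order sheet, one row per marker, deterministic formatting."""
    rows = [
        {
            "marker_id": p.marker_id,
            "fam_allele": p.fam_allele,
            "hex_allele": p.hex_allele,
            "fam_primer": p.fam_primer,
            "hex_primer": p.hex_primer,
            "common_reverse": p.common_reverse,
            "body_len": p.body_len,
            "body_tm": f"{p.body_tm:.2f}",
            "reverse_tm": f"{p.reverse_tm:.2f}",
            "reverse_gc": f"{p.reverse_gc:.4f}",
            "amplicon_len": p.amplicon_len,
        }
        for p in primer_sets
    ]
    pd.DataFrame(rows, columns=_SHEET_COLUMNS).to_csv(path, index=False)
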