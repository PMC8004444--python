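"""Per-locus polymorphism statistics and panel-level summaries.

The central quantity is the polymorphism information content of a marker,

    PIC = 1 - sum_j p_j**2,

where ``p_j`` is the frequency of the j-th *pattern* (allelic state) among
the genotyped samples at that marker. PIC is 0 for a monomorphic site and is
maximised at equal pattern frequencies: 0.5 for two patterns, 0.75 for four.

Substitutions are classified directionally (ref -> alt, so "T>C" and "C>T"
are distinct tallies) into transitions (A<->G, C<->T) and transversions; the
transition/transversion ratio is computed over bi-allelic single-base loci
only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import VALID_BASES, GenotypeMatrix, SnpLocus

__all__ = [
    "SubstitutionClass",
    "LocusStats",
    "PanelSummary",
    "pic",
    "classify_substitution",
    "pattern_spectrum",
    "compute_all_stats",
    "tstv_ratio",
    "summarize_panel",
    "write_locus_table",
    "write_panel_summary",
]

PIC_HIST_BIN_WIDTH = 0.05  # right-closed bins, fixed so histograms reproduce bit-exactly


class SubstitutionClass(str, Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    NOT_BIALLELIC = "not_biallelic"


class UndefinedPicError(ValueError):
    """PIC requested for an empty frequency map (no genotyped samples)."""


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def pic(freqs: Mapping[str, float] | Sequence[float]) -> float:
    """Polymorphism information content, ``1 - sum(p**2)``.

    ``freqs`` is a pattern -> frequency mapping or a bare frequency sequence;
    frequencies must be non-negative and sum to 1.
    """
    values = list(freqs.values()) if isinstance(freqs, Mapping) else list(freqs)
    if not values:
        raise UndefinedPicError("PIC is undefined for an empty frequency map")
    if any(v < 0 for v in values):
        raise ValueError("pattern frequencies must be non-negative")
    total = math.fsum(values)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"pattern frequencies must sum to 1 (got {total})")
    return 1.0 - math.fsum(v * v for v in values)


def classify_substitution(ref: str, alt: str) -> tuple[SubstitutionClass, str]:
    """Classify a directional single-base substitution.

    Returns the class and the directional label ``"REF>ALT"`` (direction is
    preserved: T>C and C>T are different labels).
    """
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise ValueError(f"invalid allele in substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref})")
    pair = {ref, alt}
    cls = (
        SubstitutionClass.TRANSITION
        if pair <= _PURINES or pair <= _PYRIMIDINES
        else SubstitutionClass.TRANSVERSION
    )
    return cls, f"{ref}>{alt}"


@dataclass
class LocusStats:
    """Polymorphism statistics for one locus.

    ``pic`` is None when no sample is genotyped (flagged for later exclusion
    by screening). ``substitution`` is NOT_BIALLELIC unless the locus has
    exactly two observed patterns, both single bases.
    """

    chrom: str
    pos: int
    ref: str
    pattern_counts: dict[str, int]
    pattern_freqs: dict[str, float]
    n_genotyped: int
    n_missing: int
    pic: float | None
    substitution: SubstitutionClass
    label: str | None  # directional "REF>ALT", bi-allelic loci only

    @property
    def n_patterns(self) -> int:
        return len(self.pattern_counts)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def _directional_alt(locus: SnpLocus) -> str | None:
    """Deterministic alt base for the directional label of a bi-allelic locus.

    Normally the single observed non-reference pattern. If the reference
    base itself is unobserved (two alt patterns), the first alt in the
    locus's declared alt order that is observed is used.
    """
    non_ref = [p for p in locus.patterns if p != locus.ref]
    if len(non_ref) == 1:
        return non_ref[0]
    for a in locus.alts:
        if a in locus.patterns:
            return a
    return non_ref[0] if non_ref else None


def pattern_spectrum(matrix: GenotypeMatrix, locus_index: int) -> LocusStats:
    """Pattern frequencies, PIC and substitution class for one locus.

    Frequencies are computed over non-missing calls only, in deterministic
    lexicographic pattern order. An all-missing locus yields
    ``n_genotyped=0`` and ``pic=None``.
    """
    locus = matrix.loci[locus_index]
    counts = matrix.pattern_counts(locus_index)
    counts = {p: c for p, c in counts.items() if c > 0}
    n = sum(counts.values())
    if n > 0:
        freqs = {p: c / n for p, c in counts.items()}
        pic_value = pic(freqs)
    else:
        freqs = {}
        pic_value = None

    if len(counts) == 2 and all(len(p) == 1 for p in counts):
        alt = _directional_alt(locus)
        cls, label = classify_substitution(locus.ref, alt)
    else:
        cls, label = SubstitutionClass.NOT_BIALLELIC, None

    return LocusStats(
        chrom=locus.chrom,
        pos=locus.pos,
        ref=locus.ref,
        pattern_counts=counts,
        pattern_freqs=freqs,
        n_genotyped=n,
        n_missing=matrix.n_samples - n,
        pic=pic_value,
        substitution=cls,
        label=label,
    )


def compute_all_stats(matrix: GenotypeMatrix) -> list[LocusStats]:
    return [pattern_spectrum(matrix, i) for i in range(matrix.n_loci)]


def tstv_ratio(stats: Iterable[LocusStats]) -> float:
    """Transition/transversion ratio over bi-allelic loci.

    Returns ``inf`` when transversions are absent but transitions are not;
    raises on an input with no bi-allelic loci at all.
    """
    n_ts = n_tv = 0
    for s in stats:
        if s.substitution is SubstitutionClass.TRANSITION:
            n_ts += 1
        elif s.substitution is SubstitutionClass.TRANSVERSION:
            n_tv += 1
    if n_ts + n_tv == 0:
        raise ValueError("Ts/Tv is undefined: no bi-allelic loci in input")
    if n_tv == 0:
        return math.inf
    return n_ts / n_tv


# ---------------------------------------------------------------------------
# Panel summary
# ---------------------------------------------------------------------------

@dataclass
class PanelSummary:
    n_loci: int
    n_samples: int
    mean_pic: float | None
    pic_hist: list[tuple[float, float, int]]  # (low, high, count]; right-closed
    pattern_count_spectrum: dict[int, int]  # n_patterns -> locus count
    pattern_count_fractions: dict[int, float]
    n_over_four_patterns: int  # flagged: more than four patterns observed
    directional_counts: dict[str, int]  # over bi-allelic loci
    directional_fractions: dict[str, float]
    tstv: float | None
    per_chrom_counts: dict[str, int]

    def as_dict(self) -> dict:
        d = {
            "n_loci": self.n_loci,
            "n_samples": self.n_samples,
            "mean_pic": self.mean_pic,
            "pic_hist": [list(b) for b in self.pic_hist],
            "pattern_count_spectrum": {str(k): v for k, v in self.pattern_count_spectrum.items()},
            "pattern_count_fractions": {str(k): v for k, v in self.pattern_count_fractions.items()},
            "n_over_four_patterns": self.n_over_four_patterns,
            "directional_counts": self.directional_counts,
            "directional_fractions": self.directional_fractions,
            "tstv": None if self.tstv is None or math.isinf(self.tstv) else self.tstv,
            "tstv_infinite": self.tstv is not None and math.isinf(self.tstv),
            "per_chrom_counts": self.per_chrom_counts,
        }
        return d


def _pic_hist(pics: Sequence[float], width: float = PIC_HIST_BIN_WIDTH) -> list[tuple[float, float, int]]:
    """Right-closed histogram (lo, hi] with fixed bin width; PIC 0 goes in the
    first bin. Upper edge 0.75 (four-pattern maximum); anything above is
    clamped into the last bin (loci with >4 patterns are flagged separately).
    """
    n_bins = int(round(0.75 / width))
    counts = [0] * n_bins
    for v in pics:
        if v <= 0:
            k = 0
        else:
            k = min(n_bins - 1, int(math.ceil(v / width)) - 1)
        counts[k] += 1
    return [
        (round(k * width, 10), round((k + 1) * width, 10), c)
        for k, c in enumerate(counts)
    ]


def summarize_panel(matrix: GenotypeMatrix, stats: Sequence[LocusStats] | None = None) -> PanelSummary:
    """Panel-level aggregates: PIC histogram and mean, pattern-count spectrum,
    directional substitution fractions over bi-allelic loci, Ts/Tv, and
    per-chromosome locus counts.
    """
    if matrix.n_loci == 0:
        raise ValueError("cannot summarize an empty panel")
    if stats is None:
        stats = compute_all_stats(matrix)

    pics = [s.pic for s in stats if s.pic is not None]
    mean_pic = float(np.mean(pics)) if pics else None

    spectrum: dict[int, int] = {}
    n_over4 = 0
    for s in stats:
        spectrum[s.n_patterns] = spectrum.get(s.n_patterns, 0) + 1
        if s.n_patterns > 4:
            n_over4 += 1
    fractions = {k: v / len(stats) for k, v in sorted(spectrum.items())}

    directional: dict[str, int] = {}
    for s in stats:
        if s.substitution is not SubstitutionClass.NOT_BIALLELIC and s.label:
            directional[s.label] = directional.get(s.label, 0) + 1
    n_bi = sum(directional.values())
    directional = dict(sorted(directional.items()))
    dir_fracs = {k: v / n_bi for k, v in directional.items()} if n_bi else {}

    try:
        ratio = tstv_ratio(stats)
    except ValueError:
        ratio = None

    per_chrom: dict[str, int] = {}
    for s in stats:
        per_chrom[s.chrom] = per_chrom.get(s.chrom, 0) + 1

    return PanelSummary(
        n_loci=matrix.n_loci,
        n_samples=matrix.n_samples,
        mean_pic=mean_pic,
        pic_hist=_pic_hist(pics),
        pattern_count_spectrum=dict(sorted(spectrum.items())),
        pattern_count_fractions=fractions,
        n_over_four_patterns=n_over4,
        directional_counts=directional,
        directional_fractions=dir_fracs,
        tstv=ratio,
        per_chrom_counts=dict(sorted(per_chrom.items())),
    )


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def write_locus_table(stats: Sequence[LocusStats], path: str | Path) -> None:
    """One TSV row per locus: chrom, pos, ref, patterns, n_genotyped, PIC, class."""
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "ref": s.ref,
            "patterns": ",".join(s.pattern_counts),
            "n_genotyped": s.n_genotyped,
            "pic": "" if s.pic is None else f"{s.pic:.6f}",
            "class": s.substitution.value,
            "label": s.label or "",
        }
        for s in stats
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_panel_summary(summary: PanelSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
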