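"""Genotype-panel and reference-genome I/O.

The central container is :class:`GenotypeMatrix`, a samples x loci matrix of
*pattern* calls. A pattern is the allelic state observed for one sample at
one site: a single base (``"A"``) for homozygous/haploid calls, or a sorted
pair (``"A/G"``) for heterozygous diploid calls when ``het_policy="pattern"``.
Inbred panels (the intended use case) are effectively haploid, so patterns
are usually plain bases; the pattern abstraction exists because polymorphism
information content is defined over pattern frequencies, not allele
frequencies.

Coordinates are 1-based inclusive throughout the public data model (VCF
convention). Missing calls are encoded as :data:`MISSING` (-1) in the call
matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING: int = -1
VALID_BASES = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PanelError(Exception):
    """Base class for genotype-panel errors."""


class PanelParseError(PanelError):
    """Malformed input file; the message names the offending line/record."""


class EmptyPanelError(PanelError):
    """No usable SNP record survived reading."""


class DuplicateLocusError(PanelParseError):
    """The same (chrom, pos) occurs more than once in a genotype table."""


class ChromosomeMismatchError(PanelError):
    """A chromosome name is absent from the attached reference genome."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpLocus:
    """One single-base substitution site.

    Parameters
    ----------
    chrom, pos
        1-based position on ``chrom``.
    ref
        Reference base (A/C/G/T).
    alts
        Ordered alternate bases, each a single base distinct from ``ref``.
    patterns
        Lexicographically sorted distinct patterns observed in the panel.
        Empty only for the degenerate all-missing locus, which downstream
        screening excludes.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.chrom}:{self.pos}: position must be >= 1")
        if self.ref not in VALID_BASES:
            raise ValueError(f"{self.chrom}:{self.pos}: invalid ref allele {self.ref!r}")
        for a in self.alts:
            if a not in VALID_BASES:
                raise ValueError(f"{self.chrom}:{self.pos}: invalid alt allele {a!r}")
            if a == self.ref:
                raise ValueError(f"{self.chrom}:{self.pos}: alt equals ref ({a})")
        alleles = {self.ref, *self.alts}
        if not 1 <= len(alleles) <= 4:
            raise ValueError(f"{self.chrom}:{self.pos}: allele set size out of range")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def is_biallelic_snv(self) -> bool:
        """Exactly two observed patterns, both single bases."""
        return len(self.patterns) == 2 and all(len(p) == 1 for p in self.patterns)


@dataclass
class ReadReport:
    """Bookkeeping of records seen and skipped while reading a panel."""

    n_records: int = 0
    n_kept: int = 0
    n_skipped_indel: int = 0
    n_skipped_symbolic: int = 0
    n_skipped_qual: int = 0
    n_calls_depth_masked: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


class GenotypeMatrix:
    """Samples x loci matrix of pattern calls with a missing-data mask.

    ``calls`` is an int16 array of shape (n_loci, n_samples); entry (i, j) is
    an index into ``loci[i].patterns`` or :data:`MISSING`.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        loci: Sequence[SnpLocus],
        calls: np.ndarray,
        read_report: ReadReport | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.loci = list(loci)
        self.calls = np.asarray(calls, dtype=np.int16)
        self.read_report = read_report
        if self.calls.shape != (len(self.loci), len(self.sample_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.loci)} loci x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 2:
            raise PanelError("a genotype panel needs at least 2 samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise PanelError("sample ids must be unique")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def __len__(self) -> int:
        return self.n_loci

    # -- per-locus accessors ----------------------------------------------

    def pattern_at(self, locus_index: int, sample_index: int) -> str | None:
        code = int(self.calls[locus_index, sample_index])
        if code == MISSING:
            return None
        return self.loci[locus_index].patterns[code]

    def pattern_counts(self, locus_index: int) -> dict[str, int]:
        """Counts of each observed pattern at a locus (lexicographic order)."""
        locus = self.loci[locus_index]
        row = self.calls[locus_index]
        counts = np.bincount(row[row >= 0], minlength=len(locus.patterns))
        return {p: int(c) for p, c in zip(locus.patterns, counts)}

    def n_genotyped(self, locus_index: int) -> int:
        return int((self.calls[locus_index] >= 0).sum())

    def n_missing(self, locus_index: int) -> int:
        return self.n_samples - self.n_genotyped(locus_index)

    def n_genotyped_per_locus(self) -> np.ndarray:
        return (self.calls >= 0).sum(axis=1)

    def n_missing_per_locus(self) -> np.ndarray:
        return self.n_samples - self.n_genotyped_per_locus()

    # -- structure ---------------------------------------------------------

    def subset_loci(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            self.sample_ids,
            [self.loci[i] for i in keep],
            self.calls[keep],
            read_report=self.read_report,
        )

    def validate(self) -> None:
        """Check structural invariants; raises PanelError on violation."""
        for i, locus in enumerate(self.loci):
            row = self.calls[i]
            called = row[row >= 0]
            if called.size and called.max() >= len(locus.patterns):
                raise PanelError(f"{locus.chrom}:{locus.pos}: call code out of range")
            if called.size == 0 and locus.patterns:
                raise PanelError(f"{locus.chrom}:{locus.pos}: patterns listed but no calls")
            if (row < MISSING).any():
                raise PanelError(f"{locus.chrom}:{locus.pos}: invalid call code")


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

class Genome:
    """In-memory reference genome with FASTA-order chromosome names.

    Sequences are held uppercase. The whole genome is materialised: the
    mismatch-tolerant uniqueness search scans every chromosome, so lazy
    slicing buys nothing at the genome sizes this tool targets.
    """

    def __init__(self, seqs: Mapping[str, str]) -> None:
        self._seqs = {name: seq.upper() for name, seq in seqs.items()}
        self.names: list[str] = list(self._seqs)
        self._order = {name: i for i, name in enumerate(self.names)}

    @classmethod
    def from_fasta(cls, path: str | Path, rename: Mapping[str, str] | None = None) -> "Genome":
        """Load from FASTA via pyfaidx. ``rename`` maps file names -> panel names."""
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        seqs: dict[str, str] = {}
        for name in fa.keys():
            out_name = rename.get(name, name) if rename else name
            seqs[out_name] = str(fa[name][:])
        return cls(seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def seq(self, name: str) -> str:
        try:
            return self._seqs[name]
        except KeyError:
            raise ChromosomeMismatchError(
                f"chromosome {name!r} not in genome (have: {', '.join(self.names)}); "
                "chromosome matching is exact — supply a rename map if names differ"
            ) from None

    def length(self, name: str) -> int:
        return len(self.seq(name))

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def order(self, name: str) -> int:
        if name not in self._order:
            self.seq(name)  # raises with the informative message
        return self._order[name]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice; raises if out of range."""
        seq = self.seq(chrom)
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(f"{chrom}:{start}-{end} out of range (length {len(seq)})")
        return seq[start - 1 : end]


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF reader
# ---------------------------------------------------------------------------

def _het_pattern(a: str, b: str) -> str:
    return "/".join(sorted((a, b)))


def read_vcf_panel(
    path: str | Path,
    min_qual: float = 20.0,
    min_depth: int = 5,
    het_policy: str = "pattern",
    rename: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only single-base substitution records with QUAL >= ``min_qual`` are kept;
    indels and symbolic alleles are skipped and tallied in the read report.
    Sample calls whose FORMAT DP is present and below ``min_depth`` are set
    missing. ``het_policy`` is ``"pattern"`` (heterozygous call kept as its
    own sorted pattern, e.g. ``"A/G"``) or ``"missing"``.

    Record order is preserved as read (VCFs are coordinate-sorted).
    """
    import pysam

    if het_policy not in ("pattern", "missing"):
        raise ValueError(f"unknown het_policy {het_policy!r}")

    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise PanelParseError(f"malformed VCF {path}: {exc}") from exc

    samples = list(vcf.header.samples)
    if len(samples) < 2:
        raise PanelParseError(f"{path}: need >= 2 samples, found {len(samples)}")

    report = ReadReport()
    loci: list[SnpLocus] = []
    rows: list[np.ndarray] = []

    try:
        records = list(vcf)
    except (ValueError, OSError) as exc:
        raise PanelParseError(f"malformed VCF record in {path}: {exc}") from exc

    for rec in records:
        report.n_records += 1
        alts = tuple(rec.alts or ())
        if any(a.startswith("<") or a == "*" for a in alts):
            report.n_skipped_symbolic += 1
            continue
        if len(rec.ref) != 1 or any(len(a) != 1 for a in alts) or not alts:
            report.n_skipped_indel += 1
            continue
        if rec.ref not in VALID_BASES or any(a not in VALID_BASES for a in alts):
            report.n_skipped_symbolic += 1
            continue
        if rec.qual is None or rec.qual < min_qual:
            report.n_skipped_qual += 1
            continue

        allele_bases = (rec.ref,) + alts
        chrom = rename.get(rec.chrom, rec.chrom) if rename else rec.chrom

        raw: list[str | None] = []
        for name in samples:
            call = rec.samples[name]
            gt = call.get("GT")
            dp = call.get("DP") if "DP" in call else None
            if gt is None or len(gt) == 0 or any(a is None for a in gt):
                raw.append(None)
                continue
            if dp is not None and dp < min_depth:
                report.n_calls_depth_masked += 1
                raw.append(None)
                continue
            idx = [int(a) for a in gt]
            if len(set(idx)) == 1:
                raw.append(allele_bases[idx[0]])
            elif het_policy == "pattern":
                raw.append(_het_pattern(allele_bases[idx[0]], allele_bases[idx[1]]))
            else:
                raw.append(None)

        patterns = tuple(sorted({p for p in raw if p is not None}))
        code = {p: k for k, p in enumerate(patterns)}
        row = np.fromiter(
            (code[p] if p is not None else MISSING for p in raw),
            dtype=np.int16,
            count=len(raw),
        )
        loci.append(SnpLocus(chrom, rec.pos, rec.ref, alts, patterns))
        rows.append(row)
        report.n_kept += 1

    if not loci:
        raise EmptyPanelError(f"{path}: no usable SNP records (of {report.n_records} read)")

    calls = np.vstack(rows)
    logger.info("read %d loci x %d samples from %s", len(loci), len(samples), path)
    return GenotypeMatrix(samples, loci, calls, read_report=report)


# ---------------------------------------------------------------------------
# Tabular genotype panel
# ---------------------------------------------------------------------------

_TABLE_FIXED_COLS = ("chrom", "pos", "ref", "alt")
_TABLE_MISSING = {".", "N"}


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read a tab-separated genotype table.

    Layout: header ``chrom pos ref alt <sample ids...>``; one row per locus;
    cells hold a pattern (``A`` or ``A/G``) or ``.``/``N`` for missing.
    """
    loci: list[SnpLocus] = []
    rows: list[np.ndarray] = []
    seen: set[tuple[str, int]] = set()
    report = ReadReport()

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(h.lower() for h in header[:4]) != _TABLE_FIXED_COLS:
            raise PanelParseError(
                f"{path}: line 1: header must start with {'/'.join(_TABLE_FIXED_COLS)}"
            )
        samples = header[4:]
        if len(samples) < 2:
            raise PanelParseError(f"{path}: need >= 2 sample columns")
        width = len(header)

        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != width:
                raise PanelParseError(
                    f"{path}: line {lineno}: expected {width} fields, got {len(fields)}"
                )
            chrom, pos_s, ref, alt_s = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError:
                raise PanelParseError(f"{path}: line {lineno}: bad position {pos_s!r}") from None
            if (chrom, pos) in seen:
                raise DuplicateLocusError(f"{path}: line {lineno}: duplicate locus {chrom}:{pos}")
            seen.add((chrom, pos))
            alts = tuple(a for a in alt_s.split(",") if a and a != ".")

            report.n_records += 1
            cells = fields[4:]
            raw = [None if c in _TABLE_MISSING else c for c in cells]
            for c in raw:
                if c is not None and any(b not in VALID_BASES for b in c.split("/")):
                    raise PanelParseError(f"{path}: line {lineno}: bad call {c!r}")
            patterns = tuple(sorted({p for p in raw if p is not None}))
            code = {p: k for k, p in enumerate(patterns)}
            row = np.fromiter(
                (code[p] if p is not None else MISSING for p in raw),
                dtype=np.int16,
                count=len(raw),
            )
            loci.append(SnpLocus(chrom, pos, ref, alts, patterns))
            rows.append(row)
            report.n_kept += 1

    if not loci:
        raise EmptyPanelError(f"{path}: table holds no loci")
    return GenotypeMatrix(samples, loci, np.vstack(rows), read_report=report)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the deterministic tab-separated form read by read_genotype_table.

    Column order: chrom, pos, ref, alt, then samples in input order. Missing
    calls are written as ``.``.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_FIXED_COLS + tuple(matrix.sample_ids)) + "\n")
        for i, locus in enumerate(matrix.loci):
            alt = ",".join(locus.alts) if locus.alts else "."
            cells = [
                matrix.pattern_at(i, j) or "."
                for j in range(matrix.n_samples)
            ]
            fh.write("\t".join([locus.chrom, str(locus.pos), locus.ref, alt] + cells) + "\n")
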