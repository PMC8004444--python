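"""Gene assignment, marker densities, and summary reporting.

Markers are assigned to genes by position against the full gene span from a
GFF3 annotation ("genic" does not distinguish exon from intron). Densities
are counted in fixed genomic windows (1 Mb by default, matching the per-Mb
densities conventionally quoted for marker panels) and per-chromosome rates
use the supplied genome's chromosome lengths as denominators.

All ratio fields derive from integer counts; presentation values use
half-up decimal rounding (percentages to two decimals) so reports regenerate
bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genotype_io import SnpLocus
from .marker_screen import MarkerCandidate

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "GeneIndex",
    "SummaryReport",
    "GffParseError",
    "load_genes",
    "assign_gene",
    "annotate_candidates",
    "density_track",
    "build_report",
    "round_half_up",
    "percent",
    "write_report_json",
    "write_per_chrom_tsv",
    "write_density_bed",
    "plot_density_heatmap",
]

INTERGENIC = "intergenic"


class GffParseError(Exception):
    """Malformed GFF3 input; the message names the offending line."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the report's documented rounding mode)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Half-up rounded percentage of two integer counts."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


# ---------------------------------------------------------------------------
# Gene index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GffParseError(f"gene {self.gene_id}: start > end")


class GeneIndex:
    """Interval lookup over gene spans, per chromosome."""

    def __init__(self, genes: Iterable[GeneRecord]) -> None:
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            # intervaltree is half-open; genes are 1-based inclusive.
            tree.addi(g.start, g.end + 1, g)

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, chrom: str, pos: int) -> list[GeneRecord]:
        """Every gene whose inclusive span contains ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.at(pos)),
            key=lambda g: (g.start, g.gene_id),
        )


def load_genes(gff_path: str | Path, rename: Mapping[str, str] | None = None) -> GeneIndex:
    """Index ``gene``-type features from a GFF3 file (children are ignored).

    Uses gffutils with an in-memory database; malformed lines raise
    :class:`GffParseError` naming the line number.
    """
    import gffutils

    # Pre-scan for structural errors so we can name the line; gffutils's own
    # errors do not always carry one.
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise GffParseError(
                    f"{gff_path}: line {lineno}: expected 9 tab-separated columns, got {len(parts)}"
                )
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise GffParseError(
                    f"{gff_path}: line {lineno}: non-numeric coordinates"
                ) from None
            if start > end:
                raise GffParseError(f"{gff_path}: line {lineno}: start > end")

    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises heterogeneous exception types
        raise GffParseError(f"{gff_path}: {exc}") from exc

    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        chrom = rename.get(feat.seqid, feat.seqid) if rename else feat.seqid
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                chrom=chrom,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
            )
        )
    logger.info("loaded %d genes from %s", len(genes), gff_path)
    return GeneIndex(genes)


def assign_gene(locus: SnpLocus, index: GeneIndex) -> str:
    """Gene id containing the locus, or ``"intergenic"``.

    Ties between overlapping genes go to the smallest start, then the
    lexicographically smallest id (deterministic).
    """
    hits = index.overlapping(locus.chrom, locus.pos)
    return hits[0].gene_id if hits else INTERGENIC


def annotate_candidates(candidates: Sequence[MarkerCandidate], index: GeneIndex) -> None:
    """Fill ``gene_id`` on each candidate in place (None for intergenic)."""
    for c in candidates:
        gid = assign_gene(c.locus, index)
        c.gene_id = None if gid == INTERGENIC else gid


# ---------------------------------------------------------------------------
# Density track
# ---------------------------------------------------------------------------

def density_track(
    loci: Sequence[SnpLocus],
    chrom_lengths: Mapping[str, int],
    window: int,
) -> dict[str, np.ndarray]:
    """Per-window locus counts; window k covers [k*window+1, (k+1)*window]
    1-based, last window truncated at the chromosome end. Counts sum to the
    number of loci and are invariant to input order.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    tracks = {
        chrom: np.zeros(max(1, -(-length // window)), dtype=np.int64)
        for chrom, length in chrom_lengths.items()
    }
    for locus in loci:
        if locus.chrom not in tracks:
            raise KeyError(f"locus chromosome {locus.chrom!r} absent from chrom_lengths")
        tracks[locus.chrom][(locus.pos - 1) // window] += 1
    return tracks


# ---------------------------------------------------------------------------
# Summary report
# ---------------------------------------------------------------------------

@dataclass
class SummaryReport:
    """Panel/candidate totals, genic fractions, and density summaries.

    Raw ratios are stored as exact fractions of integer counts; ``*_pct``
    and ``*_per_gene`` presentation fields are half-up rounded.
    """

    n_loci: int
    n_candidates: int
    n_core: int
    marker_yield_pct: float  # candidates / loci
    per_chrom: dict[str, dict[str, float]]
    loci_genic: int
    loci_intergenic: int
    loci_genic_pct: float
    loci_genes_hit: int
    loci_per_gene: float  # loci_genic / loci_genes_hit, 2 decimals
    cand_genic: int
    cand_intergenic: int
    cand_genic_pct: float
    cand_genes_hit: int
    cand_per_gene: float  # cand_genic / cand_genes_hit, 1 decimal
    window: int
    density: dict[str, list[int]]

    def as_dict(self) -> dict:
        return asdict(self)


def build_report(
    matrix_loci: Sequence[SnpLocus],
    candidates: Sequence[MarkerCandidate],
    index: GeneIndex,
    chrom_lengths: Mapping[str, int],
    window: int = 1_000_000,
) -> SummaryReport:
    """Compute every summary statistic from integer counts.

    ``matrix_loci`` is the full discovered-SNP universe; ``candidates`` the
    screened marker set. An empty candidate list yields a zeroed report.
    """
    n_loci = len(matrix_loci)
    n_cand = len(candidates)
    n_core = sum(1 for c in candidates if c.tier == "core")

    loci_genes: dict[str, int] = {}
    loci_genic = 0
    for locus in matrix_loci:
        gid = assign_gene(locus, index)
        if gid != INTERGENIC:
            loci_genic += 1
            loci_genes[gid] = loci_genes.get(gid, 0) + 1

    cand_genes: dict[str, int] = {}
    cand_genic = 0
    for c in candidates:
        gid = assign_gene(c.locus, index)
        if gid != INTERGENIC:
            cand_genic += 1
            cand_genes[gid] = cand_genes.get(gid, 0) + 1

    per_chrom: dict[str, dict[str, float]] = {}
    for chrom, length in chrom_lengths.items():
        n_chrom_loci = sum(1 for l in matrix_loci if l.chrom == chrom)
        n_chrom_cand = sum(1 for c in candidates if c.locus.chrom == chrom)
        n_chrom_core = sum(
            1 for c in candidates if c.locus.chrom == chrom and c.tier == "core"
        )
        mb = length / 1e6
        per_chrom[chrom] = {
            "length": length,
            "loci": n_chrom_loci,
            "candidates": n_chrom_cand,
            "core": n_chrom_core,
            "candidate_density_per_mb": round_half_up(n_chrom_cand / mb, 2) if mb else 0.0,
        }

    cand_loci = [c.locus for c in candidates]
    track = density_track(cand_loci, chrom_lengths, window)

    return SummaryReport(
        n_loci=n_loci,
        n_candidates=n_cand,
        n_core=n_core,
        marker_yield_pct=percent(n_cand, n_loci),
        per_chrom=per_chrom,
        loci_genic=loci_genic,
        loci_intergenic=n_loci - loci_genic,
        loci_genic_pct=percent(loci_genic, n_loci),
        loci_genes_hit=len(loci_genes),
        loci_per_gene=(
            round_half_up(loci_genic / len(loci_genes), 2) if loci_genes else 0.0
        ),
        cand_genic=cand_genic,
        cand_intergenic=n_cand - cand_genic,
        cand_genic_pct=percent(cand_genic, n_cand),
        cand_genes_hit=len(cand_genes),
        cand_per_gene=(
            round_half_up(cand_genic / len(cand_genes), 1) if cand_genes else 0.0
        ),
        window=window,
        density={chrom: counts.tolist() for chrom, counts in track.items()},
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_report_json(report: SummaryReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_per_chrom_tsv(report: SummaryReport, path: str | Path) -> None:
    rows = [
        {"chrom": chrom, **vals} for chrom, vals in report.per_chrom.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_density_bed(report: SummaryReport, path: str | Path) -> None:
    """BED (0-based half-open) with the window count as the score column."""
    with open(path, "w") as fh:
        for chrom, counts in report.density.items():
            length = int(report.per_chrom[chrom]["length"])
            for k, count in enumerate(counts):
                start = k * report.window
                end = min((k + 1) * report.window, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{count}\n")


def plot_density_heatmap(report: SummaryReport, path: str | Path) -> None:
    """Convenience per-chromosome marker-density heat map (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(report.density)
    width = max(len(v) for v in report.density.values())
    grid = np.full((len(chroms), width), np.nan)
    for i, chrom in enumerate(chroms):
        counts = report.density[chrom]
        grid[i, : len(counts)] = counts

    fig, ax = plt.subplots(figsize=(10, 0.6 * len(chroms) + 1.5))
    im = ax.imshow(grid, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_yticks(range(len(chroms)), labels=chroms)
    ax.set_xlabel(f"window ({report.window:,} bp)")
    fig.colorbar(im, ax=ax, label="markers per window")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
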