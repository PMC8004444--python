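"""Multi-step KASP marker screen.

A locus becomes a *standard*-tier candidate when it is bi-allelic with two
single-base patterns, sufficiently polymorphic (PIC >= 0.4 by default),
sufficiently genotyped, both 20-bp flanks extract cleanly from the reference,
its upstream flank maps to exactly one genomic location allowing up to one
mismatch, and the upstream primer region carries no other panel SNP with PIC
at or above the conservation threshold (0.2 by default). Candidates that
additionally stay unique at a two-mismatch budget and conserved below the
stricter 0.1 PIC threshold form the nested *core* tier.

Uniqueness search is mismatch-tolerant and gap-free: the query is split into
``max_mismatch + 1`` contiguous seeds (pigeonhole: any window within the
mismatch budget matches at least one seed exactly), exact seed hits are found
by string scanning, and each implied window is verified by Hamming distance.
Both strands are searched; the query's own origin counts as one hit, so
"unique" means exactly one match genome-wide.
"""

from __future__ import annotations

import bisect
import json
import logging
import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    Genome,
    GenotypeMatrix,
    SnpLocus,
    VALID_BASES,
    revcomp,
)
from .snp_stats import LocusStats, compute_all_stats

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "FlankSequence",
    "MarkerCandidate",
    "ScreenResult",
    "PanelVariantIndex",
    "FlankError",
    "FlankEdgeError",
    "AmbiguousFlankError",
    "prefilter_loci",
    "extract_flank",
    "count_genomic_matches",
    "is_unique",
    "primer_region_conserved",
    "screen",
    "write_candidates_tsv",
    "write_candidates_bed",
    "write_tally_json",
    "read_candidates_tsv",
    "REJECTION_ORDER",
]

# Fixed first-failure attribution order for the rejection tally.
REJECTION_ORDER = (
    "pattern_count",
    "pic",
    "genotyped",
    "flank",
    "uniqueness",
    "conservation",
)


class FlankError(Exception):
    """Flank could not be extracted for screening."""


class FlankEdgeError(FlankError):
    """Fewer than the requested number of bases exist on that side."""


class AmbiguousFlankError(FlankError):
    """The flank contains an ambiguity base (N)."""


class InvalidQueryError(ValueError):
    """Uniqueness query violates its preconditions."""


class ScreenConfigError(Exception):
    """Screen invoked with inconsistent or missing configuration."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the marker screen.

    Defaults reproduce the published screen: markers need PIC >= 0.4, at
    least 100 genotyped samples, bi-allelism, a 20-bp upstream flank unique
    at <=1 mismatch (<=2 for the core tier) and primer-region SNPs below PIC
    0.2 (0.1 core). ``max_missing_samples`` drives the separate locus
    pre-filter (drop loci with more missing calls than this).
    """

    min_pic: float = 0.4
    min_genotyped: int = 100
    require_biallelic: bool = True
    flank_len: int = 20
    max_mismatch_standard: int = 1
    max_mismatch_core: int = 2
    conservation_pic_standard: float = 0.2
    conservation_pic_core: float = 0.1
    max_missing_samples: int = 20
    check_downstream_uniqueness: bool = False

    def __post_init__(self) -> None:
        numeric = (
            self.min_pic,
            self.min_genotyped,
            self.flank_len,
            self.max_mismatch_standard,
            self.max_mismatch_core,
            self.conservation_pic_standard,
            self.conservation_pic_core,
            self.max_missing_samples,
        )
        if any(v < 0 for v in numeric):
            raise ScreenConfigError("all screen thresholds must be >= 0")
        if self.max_mismatch_core < self.max_mismatch_standard:
            raise ScreenConfigError("max_mismatch_core must be >= max_mismatch_standard")
        if self.conservation_pic_core > self.conservation_pic_standard:
            raise ScreenConfigError(
                "conservation_pic_core must be <= conservation_pic_standard"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ScreenConfigError(f"unknown screen config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "ScreenConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data.get("screen", data))


# ---------------------------------------------------------------------------
# Flank extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlankSequence:
    """A plus-strand flank immediately adjacent to (not including) a SNP base.

    ``start``/``end`` are 1-based inclusive; for an upstream flank
    ``end == snp_pos - 1``, for a downstream flank ``start == snp_pos + 1``.
    """

    seq: str
    chrom: str
    start: int
    end: int
    side: str  # "upstream" | "downstream"
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.seq):
            raise ValueError("flank interval length does not match sequence length")

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def extract_flank(genome: Genome, locus: SnpLocus, side: str, length: int) -> FlankSequence:
    """Extract the plus-strand flank of ``length`` bases on one ``side`` of a SNP.

    Raises :class:`FlankEdgeError` when the flank would run off the
    chromosome end and :class:`AmbiguousFlankError` when it contains N.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError(f"side must be 'upstream' or 'downstream', got {side!r}")
    if length < 1:
        raise ValueError("flank length must be >= 1")
    chrom_len = genome.length(locus.chrom)
    if not 1 <= locus.pos <= chrom_len:
        raise ValueError(f"{locus.chrom}:{locus.pos} outside chromosome (len {chrom_len})")

    if side == "upstream":
        start, end = locus.pos - length, locus.pos - 1
    else:
        start, end = locus.pos + 1, locus.pos + length
    if start < 1 or end > chrom_len:
        raise FlankEdgeError(
            f"{locus.chrom}:{locus.pos}: {side} flank of {length} bp runs off the chromosome"
        )
    seq = genome.fetch(locus.chrom, start, end)
    if any(b not in VALID_BASES for b in seq):
        raise AmbiguousFlankError(f"{locus.chrom}:{locus.pos}: ambiguous flank (N in {side} flank)")
    return FlankSequence(seq=seq, chrom=locus.chrom, start=start, end=end, side=side)


# ---------------------------------------------------------------------------
# Mismatch-tolerant uniqueness search (pigeonhole seeds + Hamming verify)
# ---------------------------------------------------------------------------

def _hamming_within(a: str, b: str, limit: int) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return False
    return True


def _seed_spans(qlen: int, n_seeds: int) -> list[tuple[int, int]]:
    """Split [0, qlen) into n_seeds contiguous, near-equal spans."""
    base, extra = divmod(qlen, n_seeds)
    spans = []
    off = 0
    for i in range(n_seeds):
        ln = base + (1 if i < extra else 0)
        spans.append((off, off + ln))
        off += ln
    return spans


def _match_starts_in_seq(seq: str, query: str, max_mismatch: int) -> set[int]:
    """0-based window starts in ``seq`` within Hamming ``max_mismatch`` of ``query``."""
    qlen = len(query)
    if len(seq) < qlen:
        return set()
    hits: set[int] = set()
    if max_mismatch == 0:
        start = seq.find(query)
        while start != -1:
            hits.add(start)
            start = seq.find(query, start + 1)
        return hits

    checked: set[int] = set()
    for off, stop in _seed_spans(qlen, max_mismatch + 1):
        seed = query[off:stop]
        pos = seq.find(seed)
        while pos != -1:
            wstart = pos - off
            if 0 <= wstart <= len(seq) - qlen and wstart not in checked:
                checked.add(wstart)
                if _hamming_within(seq[wstart : wstart + qlen], query, max_mismatch):
                    hits.add(wstart)
            pos = seq.find(seed, pos + 1)
    return hits


def count_genomic_matches(genome: Genome, query: str, max_mismatch: int) -> int:
    """Count genome windows on both strands within Hamming distance
    ``max_mismatch`` of ``query`` (gap-free; includes the query's origin).

    A minus-strand match at a location is the plus-strand match of the
    reverse-complemented query there, so the two strand scans are independent
    tallies; by construction a query and its reverse complement always give
    identical counts.
    """
    q = query.upper()
    if len(q) < 10:
        raise InvalidQueryError(f"query too short ({len(q)} < 10)")
    if max_mismatch not in (0, 1, 2):
        raise InvalidQueryError(f"max_mismatch must be 0, 1 or 2 (got {max_mismatch})")
    if any(b not in VALID_BASES for b in q):
        raise InvalidQueryError("query contains a non-ACGT base")

    total = 0
    rc = revcomp(q)
    for name in genome.names:
        seq = genome.seq(name)
        total += len(_match_starts_in_seq(seq, q, max_mismatch))
        total += len(_match_starts_in_seq(seq, rc, max_mismatch))
    return total


def is_unique(genome: Genome, flank: FlankSequence | str, max_mismatch: int) -> bool:
    """True iff the flank has exactly one genomic match (its own origin)."""
    seq = flank.seq if isinstance(flank, FlankSequence) else flank
    return count_genomic_matches(genome, seq, max_mismatch) == 1


# ---------------------------------------------------------------------------
# Primer-region conservation
# ---------------------------------------------------------------------------

class PanelVariantIndex:
    """Position-sorted index of panel SNPs and their PIC, per chromosome.

    The conservation screen uses the panel's own discovered SNP list as the
    variant universe.
    """

    def __init__(self, stats: Iterable[LocusStats]) -> None:
        by_chrom: dict[str, list[tuple[int, float | None]]] = {}
        for s in stats:
            by_chrom.setdefault(s.chrom, []).append((s.pos, s.pic))
        self._pos: dict[str, list[int]] = {}
        self._pic: dict[str, list[float | None]] = {}
        for chrom, entries in by_chrom.items():
            entries.sort(key=lambda t: t[0])
            self._pos[chrom] = [p for p, _ in entries]
            self._pic[chrom] = [v for _, v in entries]

    def snps_in(self, chrom: str, start: int, end: int) -> list[tuple[int, float | None]]:
        """(pos, pic) of panel SNPs in the 1-based inclusive interval."""
        positions = self._pos.get(chrom, [])
        lo = bisect.bisect_left(positions, start)
        hi = bisect.bisect_right(positions, end)
        pics = self._pic.get(chrom, [])
        return [(positions[i], pics[i]) for i in range(lo, hi)]

    def conserved(self, chrom: str, start: int, end: int, pic_threshold: float,
                  exclude_pos: int | None = None) -> bool:
        for pos, v in self.snps_in(chrom, start, end):
            if pos == exclude_pos:
                continue
            if v is not None and v >= pic_threshold:
                return False
        return True


def primer_region_conserved(
    flank_interval: tuple[str, int, int],
    panel_index: PanelVariantIndex,
    pic_threshold: float,
) -> bool:
    """True iff no panel SNP inside the interval has PIC >= ``pic_threshold``.

    Low-PIC secondary SNPs are tolerated: they are too rare across lines to
    destabilise primer annealing.
    """
    chrom, start, end = flank_interval
    return panel_index.conserved(chrom, start, end, pic_threshold)


# ---------------------------------------------------------------------------
# Pre-filter and screen
# ---------------------------------------------------------------------------

def prefilter_loci(matrix: GenotypeMatrix, config: ScreenConfig) -> GenotypeMatrix:
    """Drop loci with more missing calls than ``config.max_missing_samples``.

    Locus order is preserved; an empty result is returned (with a warning),
    not raised.
    """
    missing = matrix.n_missing_per_locus()
    keep = np.flatnonzero(missing <= config.max_missing_samples)
    if keep.size == 0:
        logger.warning(
            "prefilter removed every locus (max_missing_samples=%d)",
            config.max_missing_samples,
        )
    return matrix.subset_loci(keep)


@dataclass
class MarkerCandidate:
    """A locus that passed the screen, with its evidence and tier."""

    locus: SnpLocus
    stats: LocusStats
    upstream_flank: FlankSequence
    downstream_flank: FlankSequence
    uniqueness_hits: dict[int, int]  # mismatch budget -> genome-wide hit count
    conserved_at: dict[float, bool]  # PIC threshold -> conserved flag
    tier: str  # "standard" | "core"
    gene_id: str | None = None

    @property
    def alleles(self) -> tuple[str, str]:
        """The two single-base patterns (lexicographic order)."""
        return (self.locus.patterns[0], self.locus.patterns[1])


@dataclass
class ScreenResult:
    candidates: list[MarkerCandidate]
    tally: dict[str, int]  # first-failed criterion -> locus count
    rejections: dict[tuple[str, int], str]  # (chrom, pos) -> first-failed criterion
    stats: list[LocusStats]

    @property
    def n_standard(self) -> int:
        return len(self.candidates)

    @property
    def n_core(self) -> int:
        return sum(1 for c in self.candidates if c.tier == "core")

    def conservation_check(self, n_input: int) -> bool:
        """#input loci == #candidates + sum of rejection tallies."""
        return n_input == len(self.candidates) + sum(self.tally.values())


def _first_failure(
    locus: SnpLocus,
    stats: LocusStats,
    genome: Genome,
    config: ScreenConfig,
    index: PanelVariantIndex,
) -> tuple[str | None, MarkerCandidate | None]:
    """Evaluate the screen criteria in fixed order; return the first failed
    criterion, or the built candidate on full success."""
    if config.require_biallelic and not locus.is_biallelic_snv:
        return "pattern_count", None
    if stats.pic is None or stats.pic < config.min_pic:
        return "pic", None
    if stats.n_genotyped < config.min_genotyped:
        return "genotyped", None

    try:
        upstream = extract_flank(genome, locus, "upstream", config.flank_len)
        downstream = extract_flank(genome, locus, "downstream", config.flank_len)
    except FlankError:
        return "flank", None

    hits: dict[int, int] = {}
    hits[config.max_mismatch_standard] = count_genomic_matches(
        genome, upstream.seq, config.max_mismatch_standard
    )
    unique_std = hits[config.max_mismatch_standard] == 1
    if unique_std and config.check_downstream_uniqueness:
        unique_std = is_unique(genome, downstream, config.max_mismatch_standard)
    if not unique_std:
        return "uniqueness", None

    conserved: dict[float, bool] = {}
    conserved[config.conservation_pic_standard] = primer_region_conserved(
        upstream.interval, index, config.conservation_pic_standard
    )
    if not conserved[config.conservation_pic_standard]:
        return "conservation", None

    # Core-tier checks: stricter uniqueness budget and conservation threshold.
    hits[config.max_mismatch_core] = count_genomic_matches(
        genome, upstream.seq, config.max_mismatch_core
    )
    core_unique = hits[config.max_mismatch_core] == 1
    if core_unique and config.check_downstream_uniqueness:
        core_unique = is_unique(genome, downstream, config.max_mismatch_core)
    conserved[config.conservation_pic_core] = primer_region_conserved(
        upstream.interval, index, config.conservation_pic_core
    )
    tier = "core" if (core_unique and conserved[config.conservation_pic_core]) else "standard"

    return None, MarkerCandidate(
        locus=locus,
        stats=stats,
        upstream_flank=upstream,
        downstream_flank=downstream,
        uniqueness_hits=hits,
        conserved_at=conserved,
        tier=tier,
    )


def screen(
    matrix: GenotypeMatrix,
    genome: Genome,
    config: ScreenConfig | None = None,
    stats: Sequence[LocusStats] | None = None,
) -> ScreenResult:
    """Run the full marker screen over a (pre-filtered) panel.

    Every rejected locus is attributed to the FIRST failed criterion in the
    fixed order pattern-count -> PIC -> genotyped-count -> flank-edge ->
    uniqueness -> conservation; candidates are sorted by (chromosome in FASTA
    order, position). Core-tier membership is a refinement of standard, so
    core is always a subset of standard.
    """
    if genome is None:
        raise ScreenConfigError("screening requires an attached reference genome")
    config = config or ScreenConfig()
    if stats is None:
        stats = compute_all_stats(matrix)
    index = PanelVariantIndex(stats)

    tally = {k: 0 for k in REJECTION_ORDER}
    rejections: dict[tuple[str, int], str] = {}
    candidates: list[MarkerCandidate] = []

    for locus, st in zip(matrix.loci, stats):
        genome.seq(locus.chrom)  # exact-name check; raises ChromosomeMismatchError
        criterion, cand = _first_failure(locus, st, genome, config, index)
        if cand is not None:
            candidates.append(cand)
        else:
            tally[criterion] += 1
            rejections[locus.key] = criterion

    candidates.sort(key=lambda c: (genome.order(c.locus.chrom), c.locus.pos))
    tally = {k: v for k, v in tally.items() if v}
    logger.info(
        "screen: %d candidates (%d core) from %d loci; rejections: %s",
        len(candidates),
        sum(1 for c in candidates if c.tier == "core"),
        matrix.n_loci,
        tally,
    )
    return ScreenResult(candidates=candidates, tally=tally, rejections=rejections, stats=list(stats))


# ---------------------------------------------------------------------------
# Candidate table I/O
# ---------------------------------------------------------------------------

_CANDIDATE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "pic", "n_genotyped", "tier", "gene_id",
    "upstream_flank", "downstream_flank",
]


def write_candidates_tsv(candidates: Sequence[MarkerCandidate], path: str | Path) -> None:
    """Deterministic candidate table (byte-identical for identical inputs)."""
    rows = [
        {
            "chrom": c.locus.chrom,
            "pos": c.locus.pos,
            "ref": c.locus.ref,
            "alt": ",".join(c.locus.alts),
            "pic": f"{c.stats.pic:.6f}",
            "n_genotyped": c.stats.n_genotyped,
            "tier": c.tier,
            "gene_id": c.gene_id or "intergenic",
            "upstream_flank": c.upstream_flank.seq,
            "downstream_flank": c.downstream_flank.seq,
        }
        for c in candidates
    ]
    pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | Path) -> list[MarkerCandidate]:
    """Rebuild minimal candidates (locus, flanks, tier, gene) from the TSV.

    Uniqueness/conservation evidence is not serialised; re-screen to
    regenerate it.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: list[MarkerCandidate] = []
    for _, r in df.iterrows():
        pos = int(r["pos"])
        alts = tuple(r["alt"].split(","))
        up = r["upstream_flank"]
        down = r["downstream_flank"]
        locus = SnpLocus(r["chrom"], pos, r["ref"], alts, tuple(sorted({r["ref"], *alts})))
        stats = LocusStats(
            chrom=r["chrom"], pos=pos, ref=r["ref"],
            pattern_counts={}, pattern_freqs={},
            n_genotyped=int(r["n_genotyped"]), n_missing=0,
            pic=float(r["pic"]), substitution=_biallelic_class(r["ref"], alts),
            label=None,
        )
        out.append(
            MarkerCandidate(
                locus=locus,
                stats=stats,
                upstream_flank=FlankSequence(up, r["chrom"], pos - len(up), pos - 1, "upstream"),
                downstream_flank=FlankSequence(down, r["chrom"], pos + 1, pos + len(down), "downstream"),
                uniqueness_hits={},
                conserved_at={},
                tier=r["tier"],
                gene_id=None if r["gene_id"] == "intergenic" else r["gene_id"],
            )
        )
    return out


def _biallelic_class(ref: str, alts: tuple[str, ...]):
    from .snp_stats import SubstitutionClass, classify_substitution

    if len(alts) == 1:
        return classify_substitution(ref, alts[0])[0]
    return SubstitutionClass.NOT_BIALLELIC


def write_candidates_bed(candidates: Sequence[MarkerCandidate], path: str | Path) -> None:
    """BED (0-based half-open) of candidate positions, named by tier."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                f"{c.locus.chrom}\t{c.locus.pos - 1}\t{c.locus.pos}\t"
                f"{c.locus.chrom}:{c.locus.pos}|{c.tier}\n"
            )


def write_tally_json(result: ScreenResult, path: str | Path) -> None:
    payload = {
        "n_candidates": result.n_standard,
        "n_core": result.n_core,
        "rejection_tally": result.tally,
        "rejection_order": list(REJECTION_ORDER),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
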