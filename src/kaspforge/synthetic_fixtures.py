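"""Reproducible synthetic genomes, annotations and genotype panels.

The generator emulates the statistical structure of a large inbred-line
RNA-Seq SNP panel at desk scale: fully homozygous calls across hundreds of
samples, a polymorphism spectrum heavily skewed toward low PIC, a transition/
transversion ratio just under one with a fixed directional substitution
spectrum, i.i.d. per-call missingness, repeat families that defeat flank
uniqueness, and genes covering most discovered SNPs.

Ground truth is exact by design: pattern counts are assigned by
largest-remainder composition of the target frequencies (then permuted across
samples with the seeded generator), so the recorded "true" frequencies and
PIC are exactly those of the generated calls before the missing mask is
applied. Planted marker loci are constructed to pass or fail one specific
screening criterion under the default :class:`~kaspforge.marker_screen.ScreenConfig`,
and the generator verifies each uniqueness prescription against the finished
genome (re-drawing the local sequence on the rare accidental collision), so
the planted truth table is consistent for every seed.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
children; no global random state is touched.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotype_io import (
    MISSING,
    Genome,
    GenotypeMatrix,
    SnpLocus,
    write_fasta,
)
from .marker_screen import count_genomic_matches
from .snp_stats import classify_substitution, pic

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatFamily",
    "PlantedMarker",
    "FixtureSpec",
    "GenomeFixture",
    "PanelFixture",
    "FixtureError",
    "PLANTED_KINDS",
    "default_planted_truth",
    "simulate_genome",
    "simulate_panel",
    "generate_fixture",
]

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_BASE_STR = "ACGTN"
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

# Directional substitution spectrum used as the default generator target:
# within-class weights of the twelve ordered ref>alt categories.
TS_WITHIN = {"T>C": 28.79, "A>G": 28.36, "C>T": 21.43, "G>A": 21.41}
TV_WITHIN = {
    "T>G": 22.16, "A>C": 22.05, "G>C": 14.71, "C>G": 14.68,
    "G>T": 8.31, "C>A": 8.24, "T>A": 5.01, "A>T": 4.84,
}

# Planted marker kinds and the screen outcome each prescribes (under the
# default ScreenConfig): a tier for passers, a first-failed criterion for
# rejects. "neighbor" loci are the low/mid-PIC flank SNPs that conservation
# kinds plant; they are ordinary panel loci expected to fail on PIC.
PLANTED_KINDS = {
    "pass_core": "core",
    "std_only_cons": "standard",   # core conservation fails (flank SNP PIC in [0.1, 0.2))
    "std_only_uniq": "standard",   # core uniqueness fails (2-mismatch repeat copy)
    "fail_pattern_mono": "pattern_count",
    "fail_pattern_tri": "pattern_count",
    "fail_pic": "pic",
    "fail_genotyped": "genotyped",
    "fail_edge_upstream": "flank",
    "fail_edge_downstream": "flank",
    "fail_ambiguous": "flank",
    "fail_uniqueness": "uniqueness",
    "fail_conservation": "conservation",
    "fail_prefilter": "core",      # passes the screen but the missing-count prefilter drops it
    "neighbor": "pic",
}

_FLANK_LEN = 20          # flank length the prescriptions are built for
_PLANT_START = 2_000     # first planted position on each chromosome
_PLANT_STRIDE = 600      # spacing keeps flanks + reverse windows disjoint
_EXCLUSION_RADIUS = 220  # background keep-out around planted loci
_REPEAT_GAP = 300


class FixtureError(Exception):
    """The requested fixture cannot be built consistently."""


@dataclass(frozen=True)
class RepeatFamily:
    copies: int = 2
    unit_len: int = 300
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.copies < 2 or self.unit_len < 40 or not 0 <= self.divergence < 0.5:
            raise FixtureError(f"invalid repeat family {self}")


@dataclass(frozen=True)
class PlantedMarker:
    """One prescribed locus; ``kind`` must be a :data:`PLANTED_KINDS` key."""

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in PLANTED_KINDS or self.kind == "neighbor":
            raise FixtureError(f"unknown planted kind {self.kind!r}")


def default_planted_truth() -> tuple[PlantedMarker, ...]:
    """53 planted markers covering every screen criterion (plus the 10
    neighbor loci the conservation kinds add, 63 panel loci in all)."""
    plan = (
        ("pass_core", 10),
        ("std_only_cons", 5),
        ("std_only_uniq", 5),
        ("fail_pattern_mono", 4),
        ("fail_pattern_tri", 3),
        ("fail_pic", 5),
        ("fail_genotyped", 4),
        ("fail_edge_upstream", 1),
        ("fail_edge_downstream", 1),
        ("fail_ambiguous", 2),
        ("fail_uniqueness", 5),
        ("fail_conservation", 5),
        ("fail_prefilter", 3),
    )
    return tuple(PlantedMarker(kind) for kind, n in plan for _ in range(n))


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic fixture.

    Defaults emulate the published panel at desk scale: 368 fully homozygous
    samples; SNP density 1.4/kb; allele-count spectrum 92.42/6.47/1.12%
    (2/3/4 patterns); transition:transversion target 0.91; minor-pattern
    frequency law q = 0.5*u**4.79 (u uniform), whose exponent is the analytic
    solution of P(PIC<=0.1)=62.61% and P(PIC>=0.4)=11.51% and implies a mean
    PIC of about 0.13; per-call missing rate 2%, comfortably inside the <=20
    missing of 368 the locus pre-filter tolerates. ``het_fraction`` injects
    heterozygous patterns into bi-allelic background loci for het-policy
    testing (inbred default: 0).
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 100_000
    n_genes: int = 40
    gene_len_range: tuple[int, int] = (800, 3_000)
    genic_fraction: float = 0.86
    repeat_families: tuple[RepeatFamily, ...] = ()
    n_loci: int = 280
    n_samples: int = 368
    missing_rate: float = 0.02
    tstv_target: float = 0.91
    allele_count_probs: tuple[float, float, float] = (0.9242, 0.0647, 0.0112)
    minor_freq_exponent: float = 4.79
    het_fraction: float = 0.0
    planted: tuple[PlantedMarker, ...] = ()

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise FixtureError("need at least 8 samples for the planted prescriptions")
        if self.chrom_len < 10_000 or self.n_chrom < 1:
            raise FixtureError("chromosomes must be >= 10 kb")
        if not 0 <= self.missing_rate < 0.5:
            raise FixtureError("missing_rate out of range")


@dataclass(frozen=True)
class PlacedMarker:
    kind: str
    chrom: str
    pos: int
    neighbor_pos: int | None = None

    @property
    def expected_screen(self) -> str:
        return PLANTED_KINDS[self.kind]

    @property
    def removed_by_prefilter(self) -> bool:
        return self.kind == "fail_prefilter"


@dataclass
class GenomeFixture:
    genome: Genome
    genes: list[tuple[str, str, int, int, str]]  # (gene_id, chrom, start, end, strand)
    repeats: list[tuple[str, int, int, int, int]]  # (chrom, start, end, family, copy)
    placements: list[PlacedMarker]
    spec: FixtureSpec

    def write_fasta(self, path: str | Path) -> None:
        write_fasta({n: self.genome.seq(n) for n in self.genome.names}, path)

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name in self.genome.names:
                fh.write(f"##sequence-region {name} 1 {self.genome.length(name)}\n")
            for gid, chrom, start, end, strand in self.genes:
                fh.write(
                    f"{chrom}\tkaspforge\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n"
                )


@dataclass
class LocusTruth:
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    patterns: tuple[str, ...]
    target_counts: tuple[int, ...]
    target_freqs: tuple[float, ...]
    true_pic: float
    substitution: str | None  # directional label for bi-allelic loci
    gene_id: str | None
    planted_kind: str | None
    expected_screen: str | None
    removed_by_prefilter: bool
    n_missing_planned: int

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class PanelFixture:
    matrix: GenotypeMatrix
    truth: list[LocusTruth]
    spec: FixtureSpec

    @property
    def truth_by_key(self) -> dict[tuple[str, int], LocusTruth]:
        return {t.key: t for t in self.truth}

    def write_vcf(self, path: str | Path) -> None:
        _write_vcf(self.matrix, path)

    def write_truth_json(self, path: str | Path) -> None:
        payload = {
            "spec": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.spec).items()
            },
            "loci": [
                {**asdict(t), "alts": list(t.alts), "patterns": list(t.patterns),
                 "target_counts": list(t.target_counts),
                 "target_freqs": list(t.target_freqs)}
                for t in self.truth
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def _chrom_names(spec: FixtureSpec) -> list[str]:
    return [f"chr{i + 1}" for i in range(spec.n_chrom)]


class _Allocators:
    """Deterministic position allocators: planted markers fill the lower half
    of each chromosome left to right; repeat constructs fill the top of the
    last chromosome right to left."""

    def __init__(self, spec: FixtureSpec) -> None:
        self.spec = spec
        self.plant_chrom = 0
        self.plant_pos = _PLANT_START
        self.repeat_end = spec.chrom_len - 1_100
        self.repeat_chrom = spec.n_chrom - 1

    def next_planted(self) -> tuple[int, int]:
        limit = self.spec.chrom_len // 2
        if self.plant_pos > limit:
            self.plant_chrom += 1
            self.plant_pos = _PLANT_START
            if self.plant_chrom >= self.spec.n_chrom:
                raise FixtureError("too many planted markers for the genome size")
        out = (self.plant_chrom, self.plant_pos)
        self.plant_pos += _PLANT_STRIDE
        return out

    def next_repeat_slot(self, length: int) -> tuple[int, int]:
        start = self.repeat_end - length + 1
        if start <= self.spec.chrom_len // 2:
            raise FixtureError("repeat region exhausted; enlarge chrom_len")
        self.repeat_end = start - _REPEAT_GAP
        return (self.repeat_chrom, start)


def _apply_divergence(unit: np.ndarray, n_subs: int, rng: np.random.Generator,
                      positions: Sequence[int] | None = None) -> np.ndarray:
    out = unit.copy()
    if n_subs == 0:
        return out
    if positions is None:
        positions = rng.choice(len(unit), size=n_subs, replace=False)
    for p in positions:
        out[p] = (out[p] + rng.integers(1, 4)) % 4
    return out


def simulate_genome(spec: FixtureSpec) -> GenomeFixture:
    """Background i.i.d. sequence with embedded repeat families, non-overlapping
    gene intervals, and the genomic constructs each planted marker needs."""
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])
    names = _chrom_names(spec)

    chrom_arrays = [
        rng.integers(0, 4, size=spec.chrom_len, dtype=np.uint8) for _ in names
    ]
    alloc = _Allocators(spec)
    repeats: list[tuple[str, int, int, int, int]] = []
    placements: list[PlacedMarker] = []
    family_counter = 0

    def paste(chrom_idx: int, start: int, unit: np.ndarray) -> None:
        chrom_arrays[chrom_idx][start - 1 : start - 1 + len(unit)] = unit

    # -- generic repeat families -------------------------------------------
    for fam in spec.repeat_families:
        unit = rng.integers(0, 4, size=fam.unit_len, dtype=np.uint8)
        n_subs = int(round(fam.divergence * fam.unit_len))
        for copy_idx in range(fam.copies):
            ci, start = alloc.next_repeat_slot(fam.unit_len)
            copy = unit if copy_idx == 0 else _apply_divergence(unit, n_subs, rng)
            paste(ci, start, copy)
            repeats.append((names[ci], start, start + fam.unit_len - 1, family_counter, copy_idx))
        family_counter += 1

    # -- planted marker placement ------------------------------------------
    shared_uniq: list[tuple[int, int]] = []  # (chrom_idx, copy1_start) of identical families
    shared_uniq_used = 0
    edge_up_used = 0
    edge_down_used = 0
    retry_units: list[dict] = []  # std_only_uniq constructs, for verification retries

    for pm in spec.planted:
        kind = pm.kind
        if kind == "fail_edge_upstream":
            pos = 10 + 2 * edge_up_used  # any pos < flank_len + 1 fails upstream
            edge_up_used += 1
            if pos > _FLANK_LEN:
                raise FixtureError("too many upstream edge markers")
            placements.append(PlacedMarker(kind, names[0], pos))
        elif kind == "fail_edge_downstream":
            pos = spec.chrom_len - 5 - 3 * edge_down_used  # within flank_len of the end
            edge_down_used += 1
            if pos <= spec.chrom_len - _FLANK_LEN:
                raise FixtureError("too many downstream edge markers")
            placements.append(PlacedMarker(kind, names[0], pos))
        elif kind == "fail_uniqueness":
            offset = 40 + 70 * (shared_uniq_used % 5)
            if shared_uniq_used % 5 == 0:
                unit = rng.integers(0, 4, size=400, dtype=np.uint8)
                ci1, s1 = alloc.next_repeat_slot(400)
                ci2, s2 = alloc.next_repeat_slot(400)
                paste(ci1, s1, unit)
                paste(ci2, s2, unit)
                repeats.append((names[ci1], s1, s1 + 399, family_counter, 0))
                repeats.append((names[ci2], s2, s2 + 399, family_counter, 1))
                family_counter += 1
                shared_uniq.append((ci1, s1))
            ci1, s1 = shared_uniq[-1]
            shared_uniq_used += 1
            placements.append(PlacedMarker(kind, names[ci1], s1 + offset))
        elif kind == "std_only_uniq":
            # two copies whose only differences are 2 bases inside the
            # marker's upstream flank: unique at <=1 mismatch, twice at <=2.
            ci1, s1 = alloc.next_repeat_slot(60)
            ci2, s2 = alloc.next_repeat_slot(60)
            unit = rng.integers(0, 4, size=60, dtype=np.uint8)
            copy2 = _apply_divergence(unit, 2, rng, positions=(25, 35))
            paste(ci1, s1, unit)
            paste(ci2, s2, copy2)
            repeats.append((names[ci1], s1, s1 + 59, family_counter, 0))
            repeats.append((names[ci2], s2, s2 + 59, family_counter, 1))
            family_counter += 1
            pos = s1 + 40
            placements.append(PlacedMarker(kind, names[ci1], pos))
            retry_units.append(
                {"pos_chrom": ci1, "pos": pos, "c1": (ci1, s1), "c2": (ci2, s2)}
            )
        else:
            ci, pos = alloc.next_planted()
            neighbor = pos - 10 if kind in ("std_only_cons", "fail_conservation") else None
            if kind == "fail_ambiguous":
                chrom_arrays[ci][pos - 1 - 5] = 4  # N inside the upstream flank
            placements.append(PlacedMarker(kind, names[ci], pos, neighbor_pos=neighbor))

    # -- genes ---------------------------------------------------------------
    genes: list[tuple[str, str, int, int, str]] = []
    per_chrom = [spec.n_genes // spec.n_chrom] * spec.n_chrom
    for i in range(spec.n_genes % spec.n_chrom):
        per_chrom[i] += 1
    gid = 0
    for ci, n_g in enumerate(per_chrom):
        if n_g == 0:
            continue
        stride = spec.chrom_len // n_g
        for k in range(n_g):
            max_len = min(spec.gene_len_range[1], stride - 10)
            length = int(rng.integers(min(spec.gene_len_range[0], max_len), max_len + 1))
            start = k * stride + int(rng.integers(1, max(2, stride - length - 1)))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            gid += 1
            genes.append((f"gene{gid:04d}", names[ci], start, start + length - 1, strand))

    # -- build genome and verify uniqueness prescriptions -------------------
    def to_genome() -> Genome:
        table = np.frombuffer(_BASE_STR.encode(), dtype=np.uint8)
        return Genome(
            {
                name: table[arr].tobytes().decode()
                for name, arr in zip(names, chrom_arrays)
            }
        )

    genome = to_genome()
    needs_unique_mm2 = {"pass_core", "std_only_cons", "fail_prefilter"}
    for attempt in range(20):
        dirty = False
        for place in placements:
            flank = None
            if place.kind in needs_unique_mm2 or place.kind == "fail_conservation":
                seq = genome.seq(place.chrom)
                flank = seq[place.pos - 1 - _FLANK_LEN : place.pos - 1]
                budget = 2 if place.kind in needs_unique_mm2 else 1
                if count_genomic_matches(genome, flank, budget) != 1:
                    # accidental near-duplicate: re-draw the local background
                    ci = names.index(place.chrom)
                    lo = place.pos - 1 - _FLANK_LEN - 5
                    hi = place.pos + _FLANK_LEN + 5
                    chrom_arrays[ci][lo:hi] = rng.integers(0, 4, size=hi - lo, dtype=np.uint8)
                    dirty = True
        for rec in retry_units:
            seq = genome.seq(names[rec["pos_chrom"]])
            flank = seq[rec["pos"] - 1 - _FLANK_LEN : rec["pos"] - 1]
            if (
                count_genomic_matches(genome, flank, 1) != 1
                or count_genomic_matches(genome, flank, 2) != 2
            ):
                unit = rng.integers(0, 4, size=60, dtype=np.uint8)
                copy2 = _apply_divergence(unit, 2, rng, positions=(25, 35))
                paste(rec["c1"][0], rec["c1"][1], unit)
                paste(rec["c2"][0], rec["c2"][1], copy2)
                dirty = True
        if not dirty:
            break
        genome = to_genome()
    else:
        raise FixtureError("could not realise planted uniqueness prescriptions")

    return GenomeFixture(
        genome=genome, genes=genes, repeats=repeats, placements=placements, spec=spec
    )


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

def _composition(freqs: Sequence[float], total: int) -> list[int]:
    """Largest-remainder integer composition of ``total`` over ``freqs``,
    with every part at least 1."""
    raw = [f * total for f in freqs]
    counts = [int(math.floor(x)) for x in raw]
    short = total - sum(counts)
    order = sorted(range(len(freqs)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in range(short):
        counts[order[i % len(order)]] += 1
    # guarantee at least one carrier per pattern
    for i, c in enumerate(counts):
        if c == 0:
            donor = max(range(len(counts)), key=lambda j: counts[j])
            counts[donor] -= 1
            counts[i] = 1
    return counts


def _directional_table(tstv_target: float) -> tuple[list[str], np.ndarray]:
    ts_share = tstv_target / (1.0 + tstv_target)
    labels, weights = [], []
    ts_total = sum(TS_WITHIN.values())
    tv_total = sum(TV_WITHIN.values())
    for lab, w in TS_WITHIN.items():
        labels.append(lab)
        weights.append(ts_share * w / ts_total)
    for lab, w in TV_WITHIN.items():
        labels.append(lab)
        weights.append((1 - ts_share) * w / tv_total)
    return labels, np.asarray(weights) / sum(weights)


def _planted_prescription(kind: str, ref: str, n: int) -> tuple[tuple[str, ...], list[int], int]:
    """(patterns, target counts, planned missing) for a planted locus.

    Count fractions are fixed so the resulting PIC lands where the screen
    criterion needs it: 0.5/0.5 for passers (PIC 0.5), 0.75/0.25 for the PIC
    reject (0.375), 0.85/0.15 for the conservation-killing neighbor
    (PIC ~0.254, in [0.2, 0.4)), 0.9185/0.0815 for the core-only neighbor
    (PIC ~0.150, in [0.1, 0.2)).
    """
    alt = _TRANSITION_PARTNER[ref]
    if kind == "fail_pattern_mono":
        return (ref,), [n], 0
    if kind == "fail_pattern_tri":
        others = sorted(b for b in "ACGT" if b != ref)[:2]
        pats = tuple(sorted([ref, *others]))
        by_pat = {ref: n - 2 * round(0.25 * n)}
        for o in others:
            by_pat[o] = round(0.25 * n)
        return pats, [by_pat[p] for p in pats], 0
    if kind == "fail_pic":
        c2 = round(0.25 * n)
    elif kind == "neighbor_cons":
        c2 = round(0.15 * n)
    elif kind == "neighbor_core":
        c2 = round(0.0815 * n)
    else:
        c2 = n // 2
    missing = 0
    if kind == "fail_genotyped":
        genotyped = min(n - 2, 80)
        missing = n - genotyped
        c2 = genotyped // 2
        pats = tuple(sorted([ref, alt]))
        counts = {ref: genotyped - c2, alt: c2}
        return pats, [counts[p] for p in pats], missing
    if kind == "fail_prefilter":
        missing = 25
    pats = tuple(sorted([ref, alt]))
    called = n - missing
    counts = {ref: called - c2, alt: c2}
    return pats, [counts[p] for p in pats], missing


def simulate_panel(gfix: GenomeFixture, spec: FixtureSpec) -> PanelFixture:
    """Place SNP loci on the fixture genome and generate homozygous calls.

    Planted loci get exact prescribed pattern counts and missing counts;
    background loci get exact-composition counts at frequencies drawn from the
    spec's distributions, then an i.i.d. per-call missing mask. True
    frequencies and PIC recorded in the truth refer to the calls before
    masking.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])
    genome = gfix.genome
    names = genome.names
    n = spec.n_samples

    entries: list[dict] = []  # locus assembly records

    # -- planted loci --------------------------------------------------------
    for place in gfix.placements:
        ref = genome.fetch(place.chrom, place.pos, place.pos)
        if ref == "N":
            raise FixtureError(f"planted marker on an N base at {place.chrom}:{place.pos}")
        pats, counts, missing = _planted_prescription(place.kind, ref, n)
        entries.append(
            dict(chrom=place.chrom, pos=place.pos, ref=ref, patterns=pats,
                 counts=counts, missing=missing, kind=place.kind)
        )
        if place.neighbor_pos is not None:
            nref = genome.fetch(place.chrom, place.neighbor_pos, place.neighbor_pos)
            nkind = "neighbor_cons" if place.kind == "fail_conservation" else "neighbor_core"
            npats, ncounts, nmissing = _planted_prescription(nkind, nref, n)
            entries.append(
                dict(chrom=place.chrom, pos=place.neighbor_pos, ref=nref,
                     patterns=npats, counts=ncounts, missing=nmissing, kind="neighbor")
            )

    # -- background locus positions -----------------------------------------
    if spec.n_loci:
        entries.extend(_background_entries(gfix, spec, rng))

    # -- assemble matrix ------------------------------------------------------
    entries.sort(key=lambda e: (names.index(e["chrom"]), e["pos"]))
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    loci: list[SnpLocus] = []
    rows = np.full((len(entries), n), MISSING, dtype=np.int16)
    truth: list[LocusTruth] = []
    placements_by_key = {(p.chrom, p.pos): p for p in gfix.placements}

    for i, e in enumerate(entries):
        pats: tuple[str, ...] = tuple(e["patterns"])
        counts: list[int] = list(e["counts"])
        target_freqs = tuple(c / sum(counts) for c in counts)

        # full call vector before masking: exact composition, permuted
        vec = np.concatenate(
            [np.full(c, k, dtype=np.int16) for k, c in enumerate(counts)]
            + [np.full(e["missing"], MISSING, dtype=np.int16)]
        )
        vec = rng.permutation(vec)

        # i.i.d. missing mask (background loci only; planted use exact counts)
        if e["kind"] is None and spec.missing_rate > 0:
            vec = vec.copy()
            vec[rng.random(n) < spec.missing_rate] = MISSING

        # observed pattern set may shrink if masking removed a pattern
        observed = sorted({pats[c] for c in vec[vec >= 0]})
        remap = {pats.index(p): k for k, p in enumerate(observed)}
        row = np.fromiter(
            (remap[c] if c >= 0 else MISSING for c in vec), dtype=np.int16, count=n
        )
        rows[i] = row

        ref = e["ref"]
        base_pats = {b for p in observed for b in p.split("/")}
        alts = tuple(sorted(b for b in base_pats if b != ref))
        if not alts:  # monomorphic-for-ref locus still needs a declared alt
            alts = (_TRANSITION_PARTNER[ref],)
        loci.append(SnpLocus(e["chrom"], e["pos"], ref, alts, tuple(observed)))

        label = None
        if len(pats) == 2 and all(len(p) == 1 for p in pats):
            other = pats[0] if pats[1] == ref else pats[1]
            if other != ref:
                label = classify_substitution(ref, other)[1]
        place = placements_by_key.get((e["chrom"], e["pos"])) if e["kind"] else None
        expected = PLANTED_KINDS[e["kind"]] if e["kind"] else None
        truth.append(
            LocusTruth(
                chrom=e["chrom"], pos=e["pos"], ref=ref, alts=alts,
                patterns=pats, target_counts=tuple(counts),
                target_freqs=target_freqs, true_pic=pic(target_freqs),
                substitution=label,
                gene_id=_gene_at(gfix.genes, e["chrom"], e["pos"]),
                planted_kind=e["kind"],
                expected_screen=expected,
                removed_by_prefilter=bool(place and place.removed_by_prefilter)
                if e["kind"] else False,
                n_missing_planned=e["missing"],
            )
        )

    matrix = GenotypeMatrix(sample_ids, loci, rows)
    return PanelFixture(matrix=matrix, truth=truth, spec=spec)


def _gene_at(genes: Sequence[tuple[str, str, int, int, str]], chrom: str, pos: int) -> str | None:
    # generator genes are non-overlapping; a linear scan is plenty at fixture scale
    for gid, g_chrom, start, end, _ in genes:
        if g_chrom == chrom and start <= pos <= end:
            return gid
    return None


def _background_entries(
    gfix: GenomeFixture, spec: FixtureSpec, rng: np.random.Generator
) -> list[dict]:
    genome = gfix.genome
    names = genome.names
    margin = _FLANK_LEN + 5

    # allowed-position machinery: global arrays over all chromosomes
    chrom_idx_parts, pos_parts, base_parts, genic_parts = [], [], [], []
    for ci, name in enumerate(names):
        seq = genome.seq(name)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        length = len(seq)
        allowed = np.ones(length, dtype=bool)
        allowed[: margin] = False
        allowed[length - margin :] = False
        allowed[arr == ord("N")] = False
        for place in gfix.placements:
            if place.chrom == name:
                lo = max(0, place.pos - 1 - _EXCLUSION_RADIUS)
                hi = min(length, place.pos + _EXCLUSION_RADIUS)
                allowed[lo:hi] = False
        for r_chrom, r_start, r_end, _, _ in gfix.repeats:
            if r_chrom == name:
                lo = max(0, r_start - 1 - margin)
                hi = min(length, r_end + margin)
                allowed[lo:hi] = False
        genic = np.zeros(length, dtype=bool)
        for _, g_chrom, g_start, g_end, _ in gfix.genes:
            if g_chrom == name:
                genic[g_start - 1 : g_end] = True
        idx = np.flatnonzero(allowed)
        chrom_idx_parts.append(np.full(idx.size, ci, dtype=np.int32))
        pos_parts.append(idx + 1)
        base_parts.append(arr[idx])
        genic_parts.append(genic[idx])

    chrom_idx = np.concatenate(chrom_idx_parts)
    pos = np.concatenate(pos_parts)
    base = np.concatenate(base_parts)
    genic = np.concatenate(genic_parts)

    m = spec.n_loci
    probs = np.asarray(spec.allele_count_probs, dtype=float)
    probs = probs / probs.sum()
    k_alleles = rng.choice([2, 3, 4], size=m, p=probs)
    n_genic = round(spec.genic_fraction * m)
    genic_flag = rng.permutation(
        np.concatenate([np.ones(n_genic, bool), np.zeros(m - n_genic, bool)])
    )
    labels, weights = _directional_table(spec.tstv_target)

    taken = np.zeros(pos.size, dtype=bool)
    entries: list[dict] = []

    def draw_from(mask: np.ndarray, count: int) -> np.ndarray:
        pool = np.flatnonzero(mask & ~taken)
        if pool.size < count:
            raise FixtureError(
                f"not enough free positions for {count} background loci; "
                "reduce n_loci or enlarge the genome"
            )
        chosen = rng.choice(pool, size=count, replace=False)
        taken[chosen] = True
        return chosen

    # bi-allelic loci, grouped by (genic flag, required ref base)
    bi = np.flatnonzero(k_alleles == 2)
    bi_labels = rng.choice(len(labels), size=bi.size, p=weights)
    for g_flag in (True, False):
        for li, lab in enumerate(labels):
            sel = bi[(genic_flag[bi] == g_flag) & (bi_labels == li)]
            if sel.size == 0:
                continue
            ref_b, alt_b = lab.split(">")
            mask = (base == ord(ref_b)) & (genic == g_flag)
            chosen = draw_from(mask, sel.size)
            us = rng.random(sel.size)
            for j, pool_i in enumerate(chosen):
                q = 0.5 * us[j] ** spec.minor_freq_exponent
                c2 = min(spec.n_samples - 1, max(1, round(q * spec.n_samples)))
                pats = tuple(sorted([ref_b, alt_b]))
                counts = {ref_b: spec.n_samples - c2, alt_b: c2}
                count_list = [counts[p] for p in pats]
                if spec.het_fraction > 0:
                    pats, count_list = _inject_het(
                        ref_b, alt_b, count_list, spec, rng
                    )
                entries.append(
                    dict(chrom=names[chrom_idx[pool_i]], pos=int(pos[pool_i]),
                         ref=ref_b, patterns=pats, counts=count_list,
                         missing=0, kind=None)
                )

    # multi-allelic loci: any base, Dirichlet-skewed pattern frequencies
    for k in (3, 4):
        sel = np.flatnonzero(k_alleles == k)
        for g_flag in (True, False):
            sub = sel[genic_flag[sel] == g_flag]
            if sub.size == 0:
                continue
            mask = (genic == g_flag) & (base != ord("N"))
            chosen = draw_from(mask, sub.size)
            for pool_i in chosen:
                ref_b = chr(base[pool_i])
                others = [b for b in "ACGT" if b != ref_b]
                alts = sorted(rng.choice(others, size=k - 1, replace=False))
                pats = tuple(sorted([ref_b, *alts]))
                w = rng.dirichlet([8.0] + [1.0] * (k - 1))
                by_allele = dict(zip([ref_b, *alts], w))
                counts = _composition([by_allele[p] for p in pats], spec.n_samples)
                entries.append(
                    dict(chrom=names[chrom_idx[pool_i]], pos=int(pos[pool_i]),
                         ref=ref_b, patterns=pats, counts=counts,
                         missing=0, kind=None)
                )
    return entries


def _inject_het(
    ref_b: str, alt_b: str, counts: list[int], spec: FixtureSpec, rng: np.random.Generator
) -> tuple[tuple[str, ...], list[int]]:
    """Move a fraction of homozygous calls into the heterozygous pattern."""
    n_het = round(spec.het_fraction * spec.n_samples)
    pats = sorted([ref_b, alt_b])
    if n_het == 0 or min(counts) <= n_het:
        return tuple(pats), counts
    het = "/".join(pats)
    new_pats = sorted([*pats, het])
    take0 = n_het // 2
    take1 = n_het - take0
    by = {pats[0]: counts[0] - take0, pats[1]: counts[1] - take1, het: n_het}
    return tuple(new_pats), [by[p] for p in new_pats]


# ---------------------------------------------------------------------------
# VCF writer
# ---------------------------------------------------------------------------

def _write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Plain-text VCF 4.2 with GT-only FORMAT and homozygous diploid calls."""
    chrom_order: dict[str, int] = {}
    for locus in matrix.loci:
        chrom_order.setdefault(locus.chrom, len(chrom_order))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=kaspforge synthetic fixture\n")
        for chrom in chrom_order:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids) + "\n"
        )
        for i, locus in enumerate(matrix.loci):
            alleles = [locus.ref, *locus.alts]
            index_of = {a: k for k, a in enumerate(alleles)}
            gts = []
            for j in range(matrix.n_samples):
                pat = matrix.pattern_at(i, j)
                if pat is None:
                    gts.append("./.")
                elif "/" in pat:
                    a, b = sorted(pat.split("/"), key=lambda x: index_of[x])
                    gts.append(f"{index_of[a]}/{index_of[b]}")
                else:
                    k = index_of[pat]
                    gts.append(f"{k}/{k}")
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t.\t{locus.ref}\t"
                f"{','.join(locus.alts)}\t60\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def generate_fixture(
    spec: FixtureSpec, outdir: str | Path | None = None
) -> tuple[GenomeFixture, PanelFixture]:
    """Simulate genome + panel; optionally write genome.fa, genes.gff3,
    panel.vcf and truth.json under ``outdir``."""
    gfix = simulate_genome(spec)
    pfix = simulate_panel(gfix, spec)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gfix.write_fasta(outdir / "genome.fa")
        gfix.write_gff3(outdir / "genes.gff3")
        pfix.write_vcf(outdir / "panel.vcf")
        pfix.write_truth_json(outdir / "truth.json")
    return gfix, pfix
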