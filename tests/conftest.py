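"""Shared fixtures: tiny hand-built panels, seeded synthetic bundles, and the
brute-force uniqueness oracle the mismatch search is checked against."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kaspforge.genotype_io import MISSING, Genome, GenotypeMatrix, SnpLocus, revcomp
from kaspforge.marker_screen import ScreenConfig, screen
from kaspforge.synthetic_fixtures import (
    FixtureSpec,
    PlantedMarker,
    default_planted_truth,
    simulate_genome,
    simulate_panel,
)

settings.register_profile(
    "kaspforge",
    settings(derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]),
)
settings.load_profile("kaspforge")


# ---------------------------------------------------------------------------
# Hand-built matrices
# ---------------------------------------------------------------------------

def _make_matrix(loci_spec, sample_ids=None):
    """Build a GenotypeMatrix from [(chrom, pos, ref, [pattern or None, ...]), ...]."""
    n = len(loci_spec[0][3])
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    loci, rows = [], []
    for chrom, pos, ref, calls in loci_spec:
        patterns = tuple(sorted({c for c in calls if c is not None}))
        code = {p: k for k, p in enumerate(patterns)}
        bases = {b for p in patterns for b in p.split("/")}
        alts = tuple(sorted(bases - {ref})) or ({"A": ("G",), "G": ("A",), "C": ("T",), "T": ("C",)}[ref])
        loci.append(SnpLocus(chrom, pos, ref, alts, patterns))
        rows.append([code[c] if c is not None else MISSING for c in calls])
    return GenotypeMatrix(sample_ids, loci, np.array(rows, dtype=np.int16))


@pytest.fixture
def make_matrix():
    return _make_matrix


# ---------------------------------------------------------------------------
# Brute-force uniqueness oracle (independent of the pigeonhole search)
# ---------------------------------------------------------------------------

def _brute_force_mismatch_counts(genome: Genome, query: str, budgets=(0, 1, 2)) -> dict[int, int]:
    """Position-by-position Hamming scan of every window on both strands."""
    totals = {b: 0 for b in budgets}
    for name in genome.names:
        seq = np.frombuffer(genome.seq(name).encode(), dtype=np.uint8)
        for q in (query, revcomp(query)):
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            n_win = len(seq) - len(qa) + 1
            if n_win <= 0:
                continue
            mism = np.zeros(n_win, dtype=np.int16)
            for j in range(len(qa)):
                mism += seq[j : j + n_win] != qa[j]
            for b in budgets:
                totals[b] += int((mism <= b).sum())
    return totals


@pytest.fixture(scope="session")
def brute_force_counts():
    return _brute_force_mismatch_counts


# ---------------------------------------------------------------------------
# Seeded synthetic bundles (session-scoped; generation is deterministic)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def planted_bundle():
    """Planted-truth fixture: 53 prescribed markers (+10 neighbor loci),
    no background, screened with the default configuration."""
    spec = FixtureSpec(seed=1, n_loci=0, planted=default_planted_truth())
    gfix = simulate_genome(spec)
    pfix = simulate_panel(gfix, spec)
    result = screen(pfix.matrix, gfix.genome, ScreenConfig())
    return spec, gfix, pfix, result


@pytest.fixture(scope="session")
def design_bundle():
    """Fifty clean validation-style markers plus their screen result."""
    spec = FixtureSpec(
        seed=3, n_loci=0, planted=tuple(PlantedMarker("pass_core") for _ in range(50))
    )
    gfix = simulate_genome(spec)
    pfix = simulate_panel(gfix, spec)
    result = screen(pfix.matrix, gfix.genome, ScreenConfig())
    return gfix, pfix, result


@pytest.fixture(scope="session")
def random_genome_100kb():
    rng = np.random.default_rng(20_240_901)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
    return Genome({"chr1": seq})
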