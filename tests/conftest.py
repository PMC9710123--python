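"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every quantity with naive per-base /
per-read loops over plain Python structures, independent of the package's
vectorised implementations.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest
from hypothesis import settings

import teenrich as te

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_coverage(library: te.MappingLibrary) -> dict[str, np.ndarray]:
    """Per-base ambiguity-weighted coverage by an explicit double loop."""
    cov = {c: np.zeros(s) for c, s in library.chrom_sizes.items()}
    for rg in library.reads:
        w = 1.0 / rg.n_mappings
        for m in rg.mappings:
            size = library.chrom_sizes[m.chrom]
            for n in range(max(0, m.start), min(m.end, size)):
                cov[m.chrom][n] += w
    return cov


def brute_family_counts(library, copies: list[te.TECopy]) -> dict[str, float]:
    """C_K by the explicit triple loop over copies, reads and mappings."""
    if hasattr(library, "reads"):
        reads = library.reads
    else:  # simulated library
        reads = library.to_library().reads
    counts: dict[str, float] = defaultdict(float)
    for c in copies:
        counts[c.family_id] += 0.0
    for rg in reads:
        for m in rg.mappings:
            for c in copies:
                if c.chrom != m.chrom:
                    continue
                l = min(m.end, c.end) - max(m.start, c.start)
                if l > 0:
                    counts[c.family_id] += l / (rg.n_mappings * rg.length)
    return dict(counts)


def brute_reads_at(library: te.MappingLibrary, chrom: str, pos: int):
    """(read_id, p_r) pairs at a position from the brute-force coverage."""
    cov_n = brute_coverage(library)[chrom][pos]
    out = []
    for rg in library.reads:
        for m in rg.mappings:
            if m.chrom == chrom and m.start <= pos < m.end:
                out.append((rg.read_id, 1.0 / (cov_n * rg.n_mappings)))
    return out


# ---------------------------------------------------------------------------
# Shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def two_read_library() -> te.MappingLibrary:
    """Worked micro-example: unimapper A on [10,20), 2-mapper B on [15,25)
    and [100,110); chr1 of length 200."""
    reads = [
        te.ReadGroup("A", 10, [te.Mapping("chr1", 10, 20)]),
        te.ReadGroup("B", 10, [te.Mapping("chr1", 15, 25),
                               te.Mapping("chr1", 100, 110)]),
    ]
    return te.MappingLibrary(reads, {"chr1": 200})


@pytest.fixture(scope="session")
def small_study():
    """A complete synthetic study: genome, annotation, input and sample."""
    spec = te.FixtureSpec(
        chrom_sizes={"chr1": 30_000, "chr2": 20_000},
        families=[
            te.FamilySpec("AluZ", 5, 300, 0.0),
            te.FamilySpec("L1X", 4, 500, 0.02),
            te.FamilySpec("MERQ", 6, 200, 0.0),
        ],
        read_length=50,
        n_input_reads=1_500,
        n_sample_reads=800,
        region_weights={"MERQ": 3.0},
        enrichment={"AluZ": 3.0},
        seed=11,
    )
    genome, records, layout = te.generate_genome_and_annotation(spec)
    annotation = te.merge_family_copies(te.filter_te_records(records))
    input_lib, input_truth = te.generate_mapping_library(spec, layout, "input")
    sample_lib, sample_truth = te.generate_mapping_library(spec, layout, "sample")
    return {
        "spec": spec, "genome": genome, "records": records, "layout": layout,
        "annotation": annotation, "input": input_lib, "sample": sample_lib,
        "input_truth": input_truth, "sample_truth": sample_truth,
    }
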