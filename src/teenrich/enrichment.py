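"""Enrichment of TE families against the simulated input background.

For each ChIP-seq sample the background model is built from its input
control, N simulated input libraries of matched size are drawn, and every
library — real and simulated — is counted with the ambiguity-weighted C_K.
Per family the empirical P-value is the fraction of simulated libraries
whose count reaches the sample's (ties count as reaching), and the
Fold-Change is the sample count over the mean simulated count.  Families
with P < alpha (default 0.01) are flagged enriched.  No library-size or
composition normalisation is applied anywhere: matched library sizes and the
input-conditioned background make the counts directly comparable.

A uniform-shuffle baseline (every mapping relocated uniformly at random,
counted binarily per family) is provided to expose the bias this background
exists to avoid: families whose copies sit in high-input-coverage regions are
systematically under-expected by a uniform null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import TEAnnotation
from .background import (
    RegionMask,
    build_probability_model,
    compute_weighted_coverage,
    filter_library_by_mask,
)
from .library_io import MappingLibrary
from .quantify import _as_arrays, count_family_mappings_arrays
from .simulate import simulate_library

__all__ = [
    "EnrichmentResult",
    "UniformBaseline",
    "run_enrichment",
    "empirical_pvalue",
    "fold_change",
    "uniform_background_counts",
    "write_results",
]


@dataclass
class EnrichmentResult:
    """Per-family enrichment of a sample over the simulated background."""

    family_id: str
    sample_count: float
    background_counts: np.ndarray
    n_copies: int
    alpha: float = 0.01

    background_mean: float = field(init=False)
    fold_change: float = field(init=False)
    pvalue: float = field(init=False)
    unstable: bool = field(init=False)

    def __post_init__(self) -> None:
        self.background_mean = float(np.mean(self.background_counts))
        self.pvalue = empirical_pvalue(self.sample_count, self.background_counts)
        self.fold_change, self.unstable = fold_change(
            self.sample_count, self.background_counts, with_flag=True
        )

    @property
    def enriched(self) -> bool:
        return self.pvalue < self.alpha

    @property
    def pvalue_label(self) -> str:
        """Empirical p floor: a p of 0 only means 'below 1/N'."""
        if self.pvalue == 0.0:
            return f"<{1 / len(self.background_counts):.6g}"
        return f"{self.pvalue:.6g}"


def empirical_pvalue(sample_count: float, background_counts: np.ndarray) -> float:
    """Fraction of simulated libraries with count >= the sample's.

    Ties count toward the numerator; the smallest reportable non-zero value
    is 1/N, and 0 means the sample exceeded every simulation.
    """
    bg = np.asarray(background_counts, dtype=np.float64)
    if len(bg) == 0:
        raise ValueError("background_counts must be non-empty")
    return float((bg >= sample_count).sum()) / len(bg)


def fold_change(sample_count: float, background_counts: np.ndarray,
                with_flag: bool = False):
    """sample_count / mean(background_counts).

    Conventions for a zero background mean: FC = 1 when the sample count is
    also 0; +inf flagged "unstable" otherwise (a family supported by too few
    background hits to quantify).
    """
    bg = np.asarray(background_counts, dtype=np.float64)
    if len(bg) == 0:
        raise ValueError("background_counts must be non-empty")
    mean = float(bg.mean())
    if mean > 0:
        fc, unstable = sample_count / mean, False
    elif sample_count == 0:
        fc, unstable = 1.0, False
    else:
        fc, unstable = math.inf, True
    return (fc, unstable) if with_flag else fc


def run_enrichment(sample: MappingLibrary, input_library: MappingLibrary,
                   annotation: TEAnnotation, N: int = 100, alpha: float = 0.01,
                   seed: int = 0, mask: RegionMask | None = None,
                   min_copies: int = 1) -> list[EnrichmentResult]:
    """Full enrichment analysis of one sample against its input control.

    If a mask is given it is applied to BOTH libraries (masked mapping
    portions removed, ambiguities recomputed) before anything else, so the
    background model, the simulated library size and the sample counts all
    live on the same masked universe.  Iteration i's RNG substream depends
    only on (seed, i), so execution order is irrelevant.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if input_library.n_reads == 0:
        raise ValueError("cannot build background from empty input library")
    if mask is not None and not mask.is_empty():
        sample = filter_library_by_mask(sample, mask)
        input_library = filter_library_by_mask(input_library, mask)
    model = build_probability_model(compute_weighted_coverage(input_library))
    families = [f for f in annotation.family_ids
                if annotation.families[f] >= min_copies]
    sample_counts = count_family_mappings_arrays(_as_arrays(sample), annotation, families)
    bg = np.empty((N, len(families)), dtype=np.float64)
    for i in range(N):
        sim = simulate_library(model, input_library, sample.n_reads, seed, i)
        bg[i] = count_family_mappings_arrays(sim.arrays, annotation, families)
    return [
        EnrichmentResult(
            family_id=fam,
            sample_count=float(sample_counts[f_i]),
            background_counts=bg[:, f_i].copy(),
            n_copies=annotation.families[fam],
            alpha=alpha,
        )
        for f_i, fam in enumerate(families)
    ]


@dataclass
class UniformBaseline:
    """Mapping-level family counts under a genome-uniform relocation null."""

    observed: dict[str, float]  # mappings overlapping each family, unshuffled
    shuffled_mean: dict[str, float]  # mean over N shuffles
    log2_fold_change: dict[str, float]  # observed vs shuffled mean
    n_shuffles: int


def _binary_family_counts(annotation: TEAnnotation, families: list[str],
                          chrom_codes: np.ndarray, starts: np.ndarray,
                          ends: np.ndarray, chrom_names: list[str]) -> np.ndarray:
    out = np.empty(len(families))
    for f_i, fam in enumerate(families):
        ov = annotation.family_overlap_bp(fam, chrom_codes, starts, ends, chrom_names)
        out[f_i] = float((ov > 0).sum())
    return out


def uniform_background_counts(library: MappingLibrary, chrom_sizes: dict[str, int],
                              annotation: TEAnnotation, N: int = 100,
                              seed: int = 0) -> UniformBaseline:
    """Shuffle every mapping uniformly across the genome, N times.

    Each mapping keeps its span and is relocated independently: a chromosome
    is chosen with probability proportional to its number of usable start
    positions (size − span + 1) and the start uniformly among them, so the
    mapping stays fully inside the chromosome.  Counting is mapping-level and
    unweighted: a shuffled mapping counts once toward every family it
    overlaps by >= 1 bp.  This is the naive null that ignores both ambiguity
    and input biases.
    """
    arr = library.arrays()
    chrom_names = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chrom_names], dtype=np.int64)
    spans = arr.ends - arr.starts
    if spans.max(initial=0) > sizes.max(initial=0):
        raise ValueError("a mapping is longer than every chromosome")
    families = annotation.family_ids
    observed = _binary_family_counts(annotation, families, arr.chrom_codes,
                                     arr.starts, arr.ends, arr.chrom_names)
    rng = np.random.default_rng(seed)
    acc = np.zeros(len(families))
    n_map = arr.n_mappings
    for _ in range(N):
        # usable placements per chromosome depend on the mapping's span
        placements = np.maximum(sizes[None, :] - spans[:, None] + 1, 0)  # (n_map, n_chrom)
        totals = placements.sum(axis=1)
        u = rng.random(n_map) * totals
        chrom_idx = (np.cumsum(placements, axis=1) <= u[:, None]).sum(axis=1)
        new_starts = rng.integers(0, placements[np.arange(n_map), chrom_idx])
        acc += _binary_family_counts(annotation, families,
                                     chrom_idx.astype(np.int32), new_starts,
                                     new_starts + spans, chrom_names)
    mean = acc / N
    with np.errstate(divide="ignore", invalid="ignore"):
        l2fc = np.log2(observed / mean)
    return UniformBaseline(
        observed=dict(zip(families, observed.tolist())),
        shuffled_mean=dict(zip(families, mean.tolist())),
        log2_fold_change=dict(zip(families, l2fc.tolist())),
        n_shuffles=N,
    )


def write_results(results: list[EnrichmentResult], path: str | Path) -> pd.DataFrame:
    """Write the enrichment report TSV.

    Rows sorted by fold-change descending, ties broken alphabetically by
    family id; floats at 6 significant digits; the ``pvalue_label`` column
    renders an empirical p of 0 as "<1/N".
    """
    rows = [
        (r.family_id, r.n_copies, r.sample_count, r.background_mean,
         r.fold_change, r.pvalue, "yes" if r.enriched else "no",
         r.pvalue_label)
        for r in results
    ]
    df = pd.DataFrame(rows, columns=[
        "family_id", "n_copies", "sample_count", "background_mean",
        "fold_change", "pvalue", "enriched", "pvalue_label",
    ])
    df = df.sort_values(["fold_change", "family_id"],
                        ascending=[False, True], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
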