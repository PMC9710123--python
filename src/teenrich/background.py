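"""Input-control background model.

The input control library defines where reads can come from in the absence
of immunoprecipitation: per-base coverage is accumulated with each mapping
weighted by 1/N_r (ambiguity weighting), normalised per chromosome into a
sampling distribution p_n = cov_n / cov_c, and chromosomes are weighted by
their total coverage w_c ∝ cov_c, so a genome-wide draw lands on base n with
probability proportional to cov_n.  Bases with zero input coverage have
probability exactly zero (the "effective genome").

Optionally, artifact regions — windows with extreme mapping counts, typically
satellite/centromeric signal — are detected with a sliding-window percentile
rule and masked out of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .library_io import Mapping, MappingArrays, MappingLibrary, ReadGroup

__all__ = [
    "CoverageModel",
    "ProbabilityModel",
    "RegionMask",
    "compute_weighted_coverage",
    "build_probability_model",
    "detect_artifact_windows",
    "apply_region_mask",
    "filter_library_by_mask",
    "write_coverage_summary",
]


@dataclass
class RegionMask:
    """Excluded genomic intervals, 0-based half-open, disjoint and sorted."""

    intervals: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, ivs: list[tuple[str, int, int]]) -> "RegionMask":
        """Build from (chrom, start, end) triples, unioning overlaps."""
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in ivs:
            per_chrom.setdefault(chrom, []).append((s, e))
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in per_chrom.items():
            pairs.sort()
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = (
                np.array([m[0] for m in merged], dtype=np.int64),
                np.array([m[1] for m in merged], dtype=np.int64),
            )
        return cls(out)

    @property
    def n_intervals(self) -> int:
        return sum(len(s) for s, _ in self.intervals.values())

    @property
    def total_bp(self) -> int:
        return int(sum((e - s).sum() for s, e in self.intervals.values()))

    def is_empty(self) -> bool:
        return self.n_intervals == 0

    def gaps(self, chrom: str, length: int) -> list[tuple[int, int]]:
        """Complement of the mask on [0, length) — the unmasked intervals."""
        if chrom not in self.intervals:
            return [(0, length)]
        starts, ends = self.intervals[chrom]
        out, prev = [], 0
        for s, e in zip(starts, ends):
            s, e = max(int(s), 0), min(int(e), length)
            if s > prev:
                out.append((prev, s))
            prev = max(prev, e)
        if prev < length:
            out.append((prev, length))
        return out

    def subtract(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        """Unmasked sub-intervals of [start, end)."""
        if chrom not in self.intervals:
            return [(start, end)]
        starts, ends = self.intervals[chrom]
        out, cur = [], start
        lo = max(0, int(np.searchsorted(ends, start, side="right")))
        for i in range(lo, len(starts)):
            s, e = int(starts[i]), int(ends[i])
            if s >= end:
                break
            if s > cur:
                out.append((cur, s))
            cur = max(cur, e)
        if cur < end:
            out.append((cur, end))
        return out

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for s, e in zip(*self.intervals[chrom]):
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    @classmethod
    def read_bed(cls, path: str | Path) -> "RegionMask":
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                ivs.append((f[0], int(f[1]), int(f[2])))
        return cls.from_intervals(ivs)


@dataclass
class CoverageModel:
    """Ambiguity-weighted per-base coverage of a library.

    ``cov[chrom][n]`` is the sum of 1/N_r over all mappings overlapping base
    n (truncated at chromosome bounds).  Dense per-chromosome vectors: memory
    scales with genome length, which is the intended regime for this package
    (fixture-to-tens-of-Mb genomes).
    """

    cov: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    source: MappingArrays  # the library the coverage was computed from

    @property
    def cov_c(self) -> dict[str, float]:
        return {c: float(v.sum()) for c, v in self.cov.items()}

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.cov.values()))

    def effective_positions(self, chrom: str) -> np.ndarray:
        return np.nonzero(self.cov[chrom])[0]


def compute_weighted_coverage(input_library: MappingLibrary) -> CoverageModel:
    """Accumulate 1/N_r per base for every mapping of every read.

    Mappings extending past a chromosome end contribute only for in-bounds
    bases.  With no truncation and full-length alignments the total coverage
    equals the summed read lengths of the library.
    """
    if input_library.n_reads == 0:
        raise ValueError("cannot build background from empty input library")
    arr = input_library.arrays()
    sizes = input_library.chrom_sizes
    weights = 1.0 / arr.map_nr
    cov: dict[str, np.ndarray] = {}
    for code, chrom in enumerate(arr.chrom_names):
        size = sizes[chrom]
        diff = np.zeros(size + 1, dtype=np.float64)
        ndiff = np.zeros(size + 1, dtype=np.int64)
        sel = arr.chrom_codes == code
        if sel.any():
            s = np.clip(arr.starts[sel], 0, size)
            e = np.clip(arr.ends[sel], 0, size)
            np.add.at(diff, s, weights[sel])
            np.add.at(diff, e, -weights[sel])
            np.add.at(ndiff, s, 1)
            np.add.at(ndiff, e, -1)
        v = np.cumsum(diff[:-1])
        # the float running sum leaves ~1e-15 residue where the true value is
        # zero; an integer overlap count restores exact zeros
        v[np.cumsum(ndiff[:-1]) == 0] = 0.0
        cov[chrom] = v
    return CoverageModel(cov=cov, chrom_sizes=dict(sizes), source=arr)


def apply_region_mask(coverage: CoverageModel, mask: RegionMask) -> CoverageModel:
    """Zero the coverage inside masked intervals; cov_c is recomputed lazily."""
    new_cov = {c: v.copy() for c, v in coverage.cov.items()}
    for chrom, (starts, ends) in mask.intervals.items():
        if chrom not in new_cov:
            continue
        v = new_cov[chrom]
        for s, e in zip(starts, ends):
            v[max(0, int(s)):min(len(v), int(e))] = 0.0
    return CoverageModel(cov=new_cov, chrom_sizes=coverage.chrom_sizes,
                         source=coverage.source)


@dataclass
class ProbabilityModel:
    """Sampling distribution over the effective genome.

    Position draws use the per-chromosome normalised probabilities
    p_n = cov_n/cov_c with chromosome weights w_c = cov_c/Σcov_c; read draws
    at a position use p_r = 1/(cov_n·N_r).  Internally the joint draw is
    also available as a flat list of mapping *segments* (mappings clipped to
    chromosome bounds and to the unmasked genome) with weight span/N_r —
    drawing a segment proportionally to its weight and an offset uniformly
    within it is exactly the position→read chain.
    """

    chrom_names: list[str]
    chrom_sizes: dict[str, int]
    w_c: np.ndarray  # per chromosome, sums to 1
    eff_pos: dict[str, np.ndarray]  # effective positions per chromosome
    p: dict[str, np.ndarray]  # p_n over effective positions, sums to 1
    cum: dict[str, np.ndarray]  # cumulative P_n over effective positions
    coverage: CoverageModel  # post-mask coverage
    source: MappingArrays
    # joint-draw segment table
    seg_chrom: np.ndarray  # int32 chromosome code
    seg_start: np.ndarray  # int64
    seg_end: np.ndarray  # int64
    seg_map: np.ndarray  # int64 -> row in source arrays
    seg_cumw: np.ndarray  # float64 cumulative weight (span/N_r)

    @property
    def total_weight(self) -> float:
        return float(self.seg_cumw[-1]) if len(self.seg_cumw) else 0.0

    def reads_at(self, chrom: str, position: int) -> tuple[np.ndarray, np.ndarray]:
        """(read rows, draw probabilities) for reads mapping across a position.

        Probabilities are p_r = 1/(cov_n·N_r) and sum to 1 at any effective
        position.
        """
        arr = self.source
        code = self.chrom_names.index(chrom)
        sel = np.nonzero(
            (self.seg_chrom == code)
            & (self.seg_start <= position)
            & (self.seg_end > position)
        )[0]
        map_rows = self.seg_map[sel]
        reads = arr.read_index[map_rows]
        cov_n = self.coverage.cov[chrom][position]
        probs = 1.0 / (cov_n * arr.read_nmap[reads])
        return reads, probs


def build_probability_model(coverage: CoverageModel,
                            mask: RegionMask | None = None) -> ProbabilityModel:
    """Normalise coverage into the background sampling distribution.

    Masked positions are removed from the effective set before
    normalisation; the remaining per-chromosome probabilities are
    renormalised to 1 and chromosomes reweighted by their residual coverage.
    """
    if mask is not None and not mask.is_empty():
        coverage = apply_region_mask(coverage, mask)
    cov_c = coverage.cov_c
    total = sum(cov_c.values())
    if total <= 0:
        raise ValueError("no effective positions: all coverage is zero or masked")
    chrom_names = coverage.source.chrom_names
    w_c = np.array([cov_c.get(c, 0.0) / total for c in chrom_names])
    eff_pos, p, cum = {}, {}, {}
    for chrom in chrom_names:
        pos = coverage.effective_positions(chrom)
        eff_pos[chrom] = pos
        if len(pos) and cov_c[chrom] > 0:
            pc = coverage.cov[chrom][pos] / cov_c[chrom]
            p[chrom] = pc
            cum[chrom] = np.cumsum(pc)
        else:
            p[chrom] = np.zeros(0)
            cum[chrom] = np.zeros(0)

    # segment table: mappings clipped to chromosome bounds and mask gaps
    arr = coverage.source
    seg_chrom, seg_start, seg_end, seg_map = [], [], [], []
    for code, chrom in enumerate(chrom_names):
        size = coverage.chrom_sizes[chrom]
        sel = np.nonzero(arr.chrom_codes == code)[0]
        if len(sel) == 0:
            continue
        s = np.clip(arr.starts[sel], 0, size)
        e = np.clip(arr.ends[sel], 0, size)
        gaps = mask.gaps(chrom, size) if mask is not None else [(0, size)]
        for g_s, g_e in gaps:
            cs = np.maximum(s, g_s)
            ce = np.minimum(e, g_e)
            keep = cs < ce
            if keep.any():
                seg_chrom.append(np.full(keep.sum(), code, dtype=np.int32))
                seg_start.append(cs[keep])
                seg_end.append(ce[keep])
                seg_map.append(sel[keep])
    if seg_chrom:
        seg_chrom = np.concatenate(seg_chrom)
        seg_start = np.concatenate(seg_start)
        seg_end = np.concatenate(seg_end)
        seg_map = np.concatenate(seg_map)
    else:
        seg_chrom = np.zeros(0, dtype=np.int32)
        seg_start = seg_end = seg_map = np.zeros(0, dtype=np.int64)
    weights = (seg_end - seg_start) / arr.read_nmap[arr.read_index[seg_map]]
    return ProbabilityModel(
        chrom_names=chrom_names,
        chrom_sizes=dict(coverage.chrom_sizes),
        w_c=w_c,
        eff_pos=eff_pos,
        p=p,
        cum=cum,
        coverage=coverage,
        source=arr,
        seg_chrom=seg_chrom,
        seg_start=seg_start,
        seg_end=seg_end,
        seg_map=seg_map,
        seg_cumw=np.cumsum(weights),
    )


def _window_counts(arr: MappingArrays, size: int, window: int, step: int,
                   sel: np.ndarray) -> np.ndarray:
    """Mapping counts per sliding window (a mapping counts in every window
    it overlaps by >=1 bp)."""
    n_win = max(1, -(-size // step))  # windows start at 0, step, 2*step, ...
    diff = np.zeros(n_win + 1, dtype=np.int64)
    if sel.any():
        s = np.clip(arr.starts[sel], 0, size)
        e = np.clip(arr.ends[sel], 0, size)
        # window w overlaps [s, e) iff w*step < e and w*step + window > s
        first = np.maximum(0, -(-(s - window + 1) // step))
        last = np.minimum(n_win, -(-e // step))  # exclusive
        ok = first < last
        np.add.at(diff, first[ok], 1)
        np.add.at(diff, last[ok], -1)
    return np.cumsum(diff[:-1])


def detect_artifact_windows(library: MappingLibrary, window: int = 100,
                            step: int = 50, percentile: float = 99.997,
                            mode: str = "both") -> RegionMask:
    """Flag sliding windows with extreme mapping counts.

    Counts per window are compared against percentile thresholds computed
    over NON-ZERO windows, once per chromosome and once genome-wide
    (linear-interpolation percentile).  ``mode="both"`` (default) flags a
    window only if it strictly exceeds both thresholds — the conservative
    reading; ``mode="either"`` flags on either.  Flagged windows are unioned
    into a single mask.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if library.n_reads == 0:
        raise ValueError("cannot detect artifact windows in an empty library")
    arr = library.arrays()
    counts: dict[str, np.ndarray] = {}
    for code, chrom in enumerate(arr.chrom_names):
        counts[chrom] = _window_counts(
            arr, library.chrom_sizes[chrom], window, step,
            arr.chrom_codes == code,
        )
    all_nonzero = np.concatenate([c[c > 0] for c in counts.values()])
    if len(all_nonzero) == 0:
        return RegionMask()
    genome_thr = float(np.percentile(all_nonzero, percentile))
    flagged: list[tuple[str, int, int]] = []
    for chrom, c in counts.items():
        nz = c[c > 0]
        if len(nz) == 0:
            continue
        chrom_thr = float(np.percentile(nz, percentile))
        if mode == "both":
            hot = (c > chrom_thr) & (c > genome_thr)
        elif mode == "either":
            hot = (c > chrom_thr) | (c > genome_thr)
        else:
            raise ValueError(f"mode must be 'both' or 'either', got {mode!r}")
        size = library.chrom_sizes[chrom]
        for w in np.nonzero(hot)[0]:
            flagged.append((chrom, int(w) * step, min(int(w) * step + window, size)))
    return RegionMask.from_intervals(flagged)


def filter_library_by_mask(library: MappingLibrary, mask: RegionMask) -> MappingLibrary:
    """Remove mappings overlapping masked regions from a library.

    Any mapping with >= 1 bp inside the mask is dropped whole — exclusion
    operates at mapping granularity, so the read mass removed from a library
    and the coverage mass removed from the background stay proportional.
    Reads left with no mapping are dropped and N_r recomputed, so downstream
    weighting operates on the retained universe.
    """
    if mask.is_empty():
        return library
    reads: list[ReadGroup] = []
    for rg in library.reads:
        kept: list[Mapping] = []
        for m in rg.mappings:
            pieces = mask.subtract(m.chrom, m.start, m.end)
            if len(pieces) == 1 and pieces[0] == (m.start, m.end):
                kept.append(m)
        if not kept:
            continue
        reads.append(rg if len(kept) == rg.n_mappings
                     else ReadGroup(rg.read_id, rg.length, kept))
    return MappingLibrary(reads, library.chrom_sizes, library.label)


def write_coverage_summary(coverage: CoverageModel, path: str | Path) -> None:
    """Per-chromosome coverage totals and effective-position counts (TSV)."""
    with open(path, "w") as fh:
        fh.write("chrom\tcov_total\teffective_positions\tlength\n")
        for chrom, v in coverage.cov.items():
            fh.write(
                f"{chrom}\t{v.sum():.6g}\t{int((v > 0).sum())}"
                f"\t{coverage.chrom_sizes[chrom]}\n"
            )
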