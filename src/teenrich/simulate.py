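"""Simulated input libraries.

Each simulated read is produced by a three-step chain: draw a genomic
position from the background distribution (p_n over the effective genome),
draw one of the reads of the input control mapping across that position with
probability p_r = 1/(cov_n·N_r), then translate *all* of that read's
mappings so the selected mapping is centred on the drawn position.  Repeating
this as many times as the ChIP-seq sample has reads yields a simulated input
library of matched size whose per-family expected counts track the input
control.

The per-read chain is equivalent to drawing a (mapping-segment, offset) cell
with weight 1/N_r; :func:`simulate_library` uses that joint draw, fully
vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .background import ProbabilityModel
from .library_io import Mapping, MappingArrays, MappingLibrary, ReadGroup

__all__ = [
    "SimulatedLibrary",
    "sample_position",
    "sample_positions",
    "sample_read_at_position",
    "center_shift_mappings",
    "simulate_library",
]


@dataclass
class SimulatedLibrary:
    """One simulated input library in columnar form.

    ``arrays`` has the same shape contract as a real library's columnar view;
    ``source_read`` records, per simulated read, the row of the input read
    that seeded it (provenance, together with seed and iteration).
    """

    arrays: MappingArrays
    chrom_sizes: dict[str, int]
    seed: int
    iteration: int
    source_read: np.ndarray  # int64 per simulated read
    # draw provenance: the genomic position drawn for each simulated read and
    # the source-mapping row that was selected (and re-centred) there
    source_chrom: np.ndarray = None  # int32 per simulated read
    source_position: np.ndarray = None  # int64 per simulated read
    selected_mapping: np.ndarray = None  # int64 per simulated read

    @property
    def n_reads(self) -> int:
        return self.arrays.n_reads

    @property
    def n_mappings(self) -> int:
        return self.arrays.n_mappings

    def to_library(self, label: str = "") -> MappingLibrary:
        """Materialise ReadGroup objects (tests / debug output)."""
        arr = self.arrays
        reads = []
        for r in range(arr.n_reads):
            lo, hi = arr.read_indptr[r], arr.read_indptr[r + 1]
            mappings = [
                Mapping(arr.chrom_names[arr.chrom_codes[j]],
                        int(arr.starts[j]), int(arr.ends[j]))
                for j in range(lo, hi)
            ]
            reads.append(ReadGroup(str(arr.read_ids[r]), int(arr.read_length[r]), mappings))
        return MappingLibrary(reads, self.chrom_sizes,
                              label or f"sim_{self.seed}_{self.iteration}")

    def write_bed(self, path) -> None:
        arr = self.arrays
        with open(path, "w") as fh:
            for j in range(arr.n_mappings):
                r = arr.read_index[j]
                fh.write(
                    f"{arr.chrom_names[arr.chrom_codes[j]]}\t{arr.starts[j]}"
                    f"\t{arr.ends[j]}\t{arr.read_ids[r]}\t{arr.read_nmap[r]}\n"
                )


def sample_positions(model: ProbabilityModel, n: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw n genomic positions: chromosome ∝ w_c, then inverse transform on
    the cumulative P_n of that chromosome.  Returns (chrom codes, positions).
    """
    chrom_idx = rng.choice(len(model.chrom_names), size=n, p=model.w_c)
    positions = np.empty(n, dtype=np.int64)
    for code in np.unique(chrom_idx):
        chrom = model.chrom_names[code]
        sel = chrom_idx == code
        q = rng.random(sel.sum())
        k = np.searchsorted(model.cum[chrom], q, side="right")
        k = np.minimum(k, len(model.eff_pos[chrom]) - 1)
        positions[sel] = model.eff_pos[chrom][k]
    return chrom_idx.astype(np.int32), positions


def sample_position(model: ProbabilityModel,
                    rng: np.random.Generator) -> tuple[str, int]:
    """Draw one genomic position from the effective genome."""
    codes, pos = sample_positions(model, 1, rng)
    return model.chrom_names[codes[0]], int(pos[0])


def sample_read_at_position(model: ProbabilityModel, chrom: str, position: int,
                            rng: np.random.Generator) -> int:
    """Draw one input read among those mapping across ``position``.

    Draw probability p_r = 1/(cov_n·N_r); at any effective position these
    sum to 1.  Returns the read's row in the model's source arrays.
    """
    reads, probs = model.reads_at(chrom, position)
    if len(reads) == 0:
        raise RuntimeError(
            f"internal consistency error: no reads at effective position "
            f"{chrom}:{position}"
        )
    return int(rng.choice(reads, p=probs))


def center_shift_mappings(read: ReadGroup, selected_mapping_index: int,
                          target_position: int,
                          chrom_sizes: dict[str, int]) -> ReadGroup:
    """Translate all mappings of a read so the selected one is centred on
    ``target_position``.

    The centre of a mapping [s, e) is s + (span-1)//2 (left-of-centre for
    even spans).  Every mapping is shifted by the same δ; mappings pushed
    partially out of chromosome bounds are truncated to their in-bounds
    portion, mappings pushed fully out are dropped (N_r recomputed).
    """
    m = read.mappings[selected_mapping_index]
    delta = target_position - (m.start + (m.span - 1) // 2)
    mappings = []
    for mm in read.mappings:
        size = chrom_sizes[mm.chrom]
        s = min(max(mm.start + delta, 0), size)
        e = min(max(mm.end + delta, 0), size)
        if e > s:
            mappings.append(Mapping(mm.chrom, s, e))
    return ReadGroup(read.read_id, read.length, mappings)


def simulate_library(model: ProbabilityModel, input_library: MappingLibrary,
                     sample_size: int, seed: int, iteration: int = 0) -> SimulatedLibrary:
    """Draw one simulated input library of ``sample_size`` reads.

    Draws are with replacement; the RNG stream is fully determined by
    (seed, iteration) — substream seed = seed + iteration — so iterations
    can run in any order (or in parallel) with identical results.

    The position→read draw is performed jointly: a mapping segment is drawn
    with probability ∝ span/N_r and the position uniformly within it, which
    is exactly the chain p_n then p_r = 1/(cov_n·N_r).
    """
    if sample_size <= 0:
        raise ValueError("sample_size must be positive")
    if model.total_weight <= 0:
        raise ValueError("probability model has no effective positions")
    arr = model.source
    rng = np.random.default_rng(seed + iteration)

    # joint (position, read) draw via weighted segments
    q = rng.random(sample_size) * model.total_weight
    seg = np.searchsorted(model.seg_cumw, q, side="right")
    seg = np.minimum(seg, len(model.seg_cumw) - 1)
    span = model.seg_end[seg] - model.seg_start[seg]
    positions = model.seg_start[seg] + rng.integers(0, span)
    sel_map = model.seg_map[seg]  # selected mapping row per simulated read
    sel_read = arr.read_index[sel_map]

    # centre shift: δ = position − centre(selected mapping)
    centers = arr.starts[sel_map] + (arr.ends[sel_map] - arr.starts[sel_map] - 1) // 2
    delta = positions - centers

    # translate every mapping of each selected read by its δ
    lo = arr.read_indptr[sel_read]
    hi = arr.read_indptr[sel_read + 1]
    counts = hi - lo
    total = int(counts.sum())
    sim_read_of_map = np.repeat(np.arange(sample_size), counts)
    # flat source-mapping rows: lo[i] + (0..counts[i]-1) for each simulated read
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    rows = np.repeat(lo, counts) + offsets
    chrom_codes = arr.chrom_codes[rows]
    sizes = np.array([model.chrom_sizes[c] for c in arr.chrom_names], dtype=np.int64)
    bound = sizes[chrom_codes]
    d = np.repeat(delta, counts)
    new_s = np.clip(arr.starts[rows] + d, 0, bound)
    new_e = np.clip(arr.ends[rows] + d, 0, bound)
    keep = new_e > new_s
    sim_read_of_map = sim_read_of_map[keep]

    nmap = np.bincount(sim_read_of_map, minlength=sample_size).astype(np.int64)
    sim_ids = np.array([f"sim{iteration}_{i}" for i in range(sample_size)], dtype=object)
    sim_arrays = MappingArrays(
        chrom_names=arr.chrom_names,
        chrom_codes=chrom_codes[keep],
        starts=new_s[keep],
        ends=new_e[keep],
        read_index=sim_read_of_map,
        read_ids=sim_ids,
        read_length=arr.read_length[sel_read],
        read_nmap=nmap,
    )
    return SimulatedLibrary(
        arrays=sim_arrays,
        chrom_sizes=dict(model.chrom_sizes),
        seed=seed,
        iteration=iteration,
        source_read=sel_read,
        source_chrom=model.seg_chrom[seg].copy(),
        source_position=positions,
        selected_mapping=sel_map,
    )
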