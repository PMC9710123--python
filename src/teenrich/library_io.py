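"""Ingestion of all-mappings alignment libraries.

A sequencing library is modelled as a set of reads, each carrying *all* of
its reported genomic mappings (primary + secondary).  The per-read ambiguity
``N_r`` (number of mappings) and read length ``L_r`` drive every downstream
weighting: a mapping contributes 1/N_r to coverage and overlap_bp/(N_r·L_r)
to family counts.

The aligner must have been run in report-all mode (e.g. ``bwa mem -a``);
without secondary alignments every read looks like a unimapper and the
ambiguity weighting degenerates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping as TMapping

import numpy as np
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "Mapping",
    "ReadGroup",
    "MappingArrays",
    "MappingLibrary",
    "load_mappings",
    "read_chrom_sizes",
    "apply_standard_filters",
    "downsample_reads",
    "write_mappings_bed",
]

MITOCHONDRIAL = frozenset({"chrM", "chrMT", "MT", "M"})


@dataclass(frozen=True)
class Mapping:
    """One alignment of one read: reference extent, 0-based half-open.

    ``end - start`` is the aligned span on the reference (CIGAR walk), which
    for soft-clipped reads is shorter than the read length.
    """

    chrom: str
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ReadGroup:
    """All mappings of one read; ambiguity N_r = number of mappings."""

    read_id: str
    length: int  # L_r, full read length in nucleotides
    mappings: list[Mapping]

    @property
    def n_mappings(self) -> int:
        return len(self.mappings)

    @property
    def is_multimapper(self) -> bool:
        return len(self.mappings) > 1


@dataclass
class MappingArrays:
    """Columnar view of a library: one row per mapping, read-grouped.

    Rows are sorted by read so that ``read_indptr[r]:read_indptr[r+1]``
    slices read r's mappings.  ``map_nr``/``map_length`` broadcast the
    per-read N_r and L_r onto mappings for vectorised weighting.
    """

    chrom_names: list[str]
    chrom_codes: np.ndarray  # int32 per mapping
    starts: np.ndarray  # int64 per mapping
    ends: np.ndarray  # int64 per mapping
    read_index: np.ndarray  # int64 per mapping -> read row
    read_ids: np.ndarray  # object, per read
    read_length: np.ndarray  # int64 per read (L_r)
    read_nmap: np.ndarray  # int64 per read (N_r)
    read_indptr: np.ndarray = field(default=None)  # int64, len n_reads+1

    def __post_init__(self) -> None:
        if self.read_indptr is None:
            counts = np.bincount(self.read_index, minlength=len(self.read_ids))
            self.read_indptr = np.concatenate(([0], np.cumsum(counts)))

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def n_mappings(self) -> int:
        return len(self.starts)

    @property
    def map_nr(self) -> np.ndarray:
        return self.read_nmap[self.read_index]

    @property
    def map_length(self) -> np.ndarray:
        return self.read_length[self.read_index]


class MappingLibrary:
    """All mappings of all reads of one sequencing library."""

    def __init__(self, reads: list[ReadGroup], chrom_sizes: TMapping[str, int],
                 label: str = ""):
        self.reads = reads
        self.chrom_sizes = dict(chrom_sizes)
        self.label = label
        self._arrays: MappingArrays | None = None

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def n_mappings(self) -> int:
        return sum(r.n_mappings for r in self.reads)

    def arrays(self) -> MappingArrays:
        """Columnar view (cached); chromosome order follows chrom_sizes."""
        if self._arrays is None:
            chrom_names = list(self.chrom_sizes)
            code = {c: i for i, c in enumerate(chrom_names)}
            n_map = self.n_mappings
            chrom_codes = np.empty(n_map, dtype=np.int32)
            starts = np.empty(n_map, dtype=np.int64)
            ends = np.empty(n_map, dtype=np.int64)
            read_index = np.empty(n_map, dtype=np.int64)
            read_ids = np.empty(self.n_reads, dtype=object)
            read_length = np.empty(self.n_reads, dtype=np.int64)
            read_nmap = np.empty(self.n_reads, dtype=np.int64)
            j = 0
            for r_i, rg in enumerate(self.reads):
                read_ids[r_i] = rg.read_id
                read_length[r_i] = rg.length
                read_nmap[r_i] = rg.n_mappings
                for m in rg.mappings:
                    chrom_codes[j] = code[m.chrom]
                    starts[j] = m.start
                    ends[j] = m.end
                    read_index[j] = r_i
                    j += 1
            self._arrays = MappingArrays(
                chrom_names, chrom_codes, starts, ends, read_index,
                read_ids, read_length, read_nmap,
            )
        return self._arrays

    def sorted_copy(self) -> "MappingLibrary":
        """Reads sorted by read_id — canonical order for comparisons."""
        reads = sorted(self.reads, key=lambda r: r.read_id)
        return MappingLibrary(reads, self.chrom_sizes, self.label)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column chrom.sizes TSV -> {chrom: length}."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def load_mappings(alignment_path: str | Path, chrom_sizes: TMapping[str, int],
                  label: str = "") -> MappingLibrary:
    """Load a SAM/BAM file produced in report-all-mappings mode.

    All primary and secondary alignments of one read name are collapsed into
    one :class:`ReadGroup`.  Unmapped, supplementary and duplicate-flagged
    records are skipped (duplicates are expected to have been removed
    upstream).  L_r is the read sequence length taken from the primary
    record; secondary records routinely omit the sequence.
    """
    path = str(alignment_path)
    groups: dict[str, list[Mapping]] = {}
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_supplementary or rec.is_duplicate:
                continue
            qname = rec.query_name
            groups.setdefault(qname, []).append(
                Mapping(rec.reference_name, rec.reference_start, rec.reference_end)
            )
            if rec.query_sequence is not None:
                lengths.setdefault(qname, len(rec.query_sequence))
            elif rec.infer_read_length() is not None:
                lengths.setdefault(qname, rec.infer_read_length())
    reads = []
    for qname in sorted(groups):
        if qname not in lengths:
            raise ValueError(f"cannot resolve read length for read {qname!r}")
        reads.append(ReadGroup(qname, lengths[qname], groups[qname]))
    return MappingLibrary(reads, chrom_sizes, label or Path(path).stem)


def apply_standard_filters(library: MappingLibrary) -> MappingLibrary:
    """Remove mitochondrial and non-canonical-contig mappings.

    Mappings on chrM/MT or on contigs absent from the chromosome-sizes table
    are dropped; reads left with no mapping are removed and N_r is recomputed
    on the filtered universe (the background and counting formulas operate on
    what remains).
    """
    keep_chroms = {c for c in library.chrom_sizes if c not in MITOCHONDRIAL}
    reads: list[ReadGroup] = []
    n_dropped_reads = 0
    n_dropped_mappings = 0
    for rg in library.reads:
        kept = [m for m in rg.mappings if m.chrom in keep_chroms]
        n_dropped_mappings += rg.n_mappings - len(kept)
        if not kept:
            n_dropped_reads += 1
            continue
        reads.append(rg if len(kept) == rg.n_mappings
                     else ReadGroup(rg.read_id, rg.length, kept))
    if n_dropped_mappings:
        logger.info(
            "standard filters: dropped %d mappings and %d reads (%s)",
            n_dropped_mappings, n_dropped_reads, library.label,
        )
    sizes = {c: s for c, s in library.chrom_sizes.items() if c in keep_chroms}
    return MappingLibrary(reads, sizes, library.label)


def downsample_reads(library: MappingLibrary, n: int = 20_000_000,
                     seed: int = 0) -> MappingLibrary:
    """Keep exactly ``n`` reads chosen uniformly without replacement.

    Retained reads keep all their mappings; identity if n >= n_reads.
    Original read order is preserved for determinism.
    """
    if n >= library.n_reads:
        return library
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(library.n_reads, size=n, replace=False))
    reads = [library.reads[i] for i in keep]
    return MappingLibrary(reads, library.chrom_sizes, library.label)


def write_mappings_bed(library: MappingLibrary, path: str | Path) -> None:
    """Debug dump: one BED row per mapping with read id and ambiguity."""
    with open(path, "w") as fh:
        for rg in library.reads:
            for m in rg.mappings:
                fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{rg.read_id}\t{rg.n_mappings}\n")
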