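"""Synthetic genomes, TE annotations and mapping libraries.

Everything downstream of an aligner is generated directly: planted TE copies
with controlled sequence divergence define the multimapping structure (a
read drawn from the interior of one of m identical copies carries the m
homologous mappings, N_r = m), a piecewise-constant position density defines
the input-control bias, and per-family enrichment folds define the ChIP-seq
sample.  Ground-truth per-read origins are recorded so tests can compare
recovered counts and fold-changes against what was planted.

Every artefact is fully determined by (spec, seed): regeneration is
byte-identical.  No base-quality or sequencing-error model is included —
reads are exact substrings of the genome — and all libraries are
single-ended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import RepeatRecord
from .library_io import Mapping, MappingLibrary, ReadGroup

__all__ = [
    "FamilySpec",
    "ArtifactSpec",
    "FixtureSpec",
    "generate_genome_and_annotation",
    "generate_mapping_library",
    "plant_artifact_region",
    "write_fasta",
    "write_chrom_sizes",
    "write_annotation_bed_records",
    "write_sam",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FamilySpec:
    """One planted TE family: n_copies copies of copy_length bp.

    ``divergence`` is the per-base substitution rate applied independently to
    each copy relative to the family consensus; 0 means all copies are exact
    duplicates (maximal ambiguity).
    """

    family_id: str
    n_copies: int
    copy_length: int
    divergence: float = 0.0
    rep_class: str = "SINE"
    rep_family: str = ""


@dataclass(frozen=True)
class ArtifactSpec:
    """A hot locus: ``intensity`` stacked unimapper reads near ``position``."""

    chrom: str
    position: int
    intensity: int
    jitter: int = 200


@dataclass
class FixtureSpec:
    """Blueprint of a synthetic study.

    ``region_weights`` sets the input-control position density multiplier
    inside each family's copies (background = 1), emulating accessibility /
    fragmentation bias; ``enrichment`` multiplies the sample density inside
    the given families on top of that, emulating true ChIP signal.
    """

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 100_000})
    families: list[FamilySpec] = field(default_factory=list)
    read_length: int = 50
    n_input_reads: int = 2_000
    n_sample_reads: int = 1_000
    region_weights: dict[str, float] = field(default_factory=dict)
    enrichment: dict[str, float] = field(default_factory=dict)
    artifact: ArtifactSpec | None = None
    copy_gap: int = 0  # minimum gap between planted copies; 0 = auto
    seed: int = 0

    def __post_init__(self) -> None:
        for fam, fold in self.enrichment.items():
            if fold < 1:
                raise ValueError(f"enrichment fold must be >= 1 ({fam}: {fold})")

    @property
    def gap(self) -> int:
        return self.copy_gap or (self.read_length + 10)


@dataclass
class GroundTruth:
    """Per-read provenance of a generated library."""

    origin_family: np.ndarray  # object, family_id or None per read
    origin_copy: np.ndarray  # int64, copy index within family (-1 = background)

    def family_read_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for fam in self.origin_family:
            if fam is not None:
                out[fam] = out.get(fam, 0) + 1
        return out


@dataclass
class CopyLayout:
    """Where each copy of each family landed, plus divergent-site offsets."""

    # family_id -> list of (chrom, start) per copy, all copy_length long
    placements: dict[str, list[tuple[str, int]]]
    # family_id -> list of per-copy sorted offset arrays of substituted sites
    divergent_sites: dict[str, list[np.ndarray]]
    spec: FixtureSpec


def generate_genome_and_annotation(
    spec: FixtureSpec,
) -> tuple[dict[str, str], list[RepeatRecord], CopyLayout]:
    """Random background sequence with planted TE copies.

    Copies are laid out in a seeded-shuffled order with at least ``spec.gap``
    background bases between consecutive copies, so distinct copies never
    merge and reads can start in pure background.  Copies of a family with
    zero divergence are exact duplicates of the family consensus; otherwise
    each copy receives independent point substitutions whose offsets are
    recorded (they shrink read ambiguity in the mapping generator).
    """
    rng = np.random.default_rng(spec.seed)
    genome = {
        chrom: rng.choice(_BASES, size=size)
        for chrom, size in spec.chrom_sizes.items()
    }
    consensus = {
        f.family_id: rng.choice(_BASES, size=f.copy_length)
        for f in spec.families
    }
    # one slot per copy, shuffled so family and position are not confounded
    slots = [f for f in spec.families for _ in range(f.n_copies)]
    order = rng.permutation(len(slots))
    chroms = list(spec.chrom_sizes)
    placements: dict[str, list[tuple[str, int]]] = {f.family_id: [] for f in spec.families}
    sites: dict[str, list[np.ndarray]] = {f.family_id: [] for f in spec.families}
    records: list[RepeatRecord] = []
    chrom_i, cursor = 0, spec.gap
    for idx in order:
        fam = slots[idx]
        while chrom_i < len(chroms) and (
            cursor + fam.copy_length + spec.gap > spec.chrom_sizes[chroms[chrom_i]]
        ):
            chrom_i += 1
            cursor = spec.gap
        if chrom_i >= len(chroms):
            raise ValueError("planted copies do not fit within the genome")
        chrom = chroms[chrom_i]
        seq = consensus[fam.family_id].copy()
        if fam.divergence > 0:
            hit = np.nonzero(rng.random(fam.copy_length) < fam.divergence)[0]
            for o in hit:
                others = _BASES[_BASES != seq[o]]
                seq[o] = others[rng.integers(0, len(others))]
            sites[fam.family_id].append(hit)
        else:
            sites[fam.family_id].append(np.empty(0, dtype=np.int64))
        genome[chrom][cursor:cursor + fam.copy_length] = seq
        placements[fam.family_id].append((chrom, cursor))
        records.append(RepeatRecord(
            chrom=chrom, start=cursor, end=cursor + fam.copy_length,
            name=fam.family_id,
            rep_class=fam.rep_class,
            rep_family=fam.rep_family or fam.family_id,
            strand="+",
        ))
        cursor += fam.copy_length + spec.gap
    genome_str = {c: "".join(v) for c, v in genome.items()}
    layout = CopyLayout(placements=placements, divergent_sites=sites, spec=spec)
    records.sort(key=lambda r: (r.chrom, r.start))
    return genome_str, records, layout


def _start_density(spec: FixtureSpec, layout: CopyLayout, role: str):
    """Piecewise-constant density over read start positions.

    A start position takes a family's weight iff the read lies fully inside
    one of that family's copies; all other starts have background weight 1.
    Returns per-chromosome breakpoint/weight arrays and interval totals.
    """
    L = spec.read_length
    pieces: dict[str, list[tuple[int, int, float, str, int]]] = {
        c: [] for c in spec.chrom_sizes
    }
    for f in spec.families:
        w = spec.region_weights.get(f.family_id, 1.0)
        if role == "sample":
            w *= spec.enrichment.get(f.family_id, 1.0)
        for copy_i, (chrom, start) in enumerate(layout.placements[f.family_id]):
            if f.copy_length >= L:
                pieces[chrom].append(
                    (start, start + f.copy_length - L + 1, w, f.family_id, copy_i)
                )
    intervals = []  # (chrom, lo, hi, weight, family_id|None, copy_i)
    for chrom, size in spec.chrom_sizes.items():
        limit = size - L + 1
        prev = 0
        for lo, hi, w, fam, copy_i in sorted(pieces[chrom]):
            if lo > prev:
                intervals.append((chrom, prev, lo, 1.0, None, -1))
            intervals.append((chrom, lo, hi, w, fam, copy_i))
            prev = hi
        if prev < limit:
            intervals.append((chrom, prev, limit, 1.0, None, -1))
    return intervals


def generate_mapping_library(
    spec: FixtureSpec, layout: CopyLayout, role: str,
    n_reads: int | None = None, seed_offset: int = 0,
) -> tuple[MappingLibrary, GroundTruth]:
    """Draw a read-mapping library with known multimapping structure.

    Read starts follow the role's piecewise density.  A read fully inside a
    copy of family F maps to every copy of F whose sequence is identical over
    the read's window — for zero divergence that is all copies (N_r =
    n_copies), and a divergent site inside the window on either the origin
    or a candidate copy removes that candidate.  Reads starting outside
    copies (or straddling a boundary) are unimappers.
    """
    if role not in ("input", "sample"):
        raise ValueError(f"role must be 'input' or 'sample', got {role!r}")
    if n_reads is None:
        n_reads = spec.n_input_reads if role == "input" else spec.n_sample_reads
    L = spec.read_length
    rng = np.random.default_rng(spec.seed + (1 if role == "input" else 2) + seed_offset)
    intervals = _start_density(spec, layout, role)
    lens = np.array([hi - lo for _, lo, hi, _, _, _ in intervals], dtype=np.float64)
    weights = lens * np.array([w for _, _, _, w, _, _ in intervals])
    probs = weights / weights.sum()
    iv_idx = rng.choice(len(intervals), size=n_reads, p=probs)
    offsets = rng.integers(0, lens[iv_idx].astype(np.int64))

    reads: list[ReadGroup] = []
    origin_family = np.empty(n_reads, dtype=object)
    origin_copy = np.full(n_reads, -1, dtype=np.int64)
    prefix = "in" if role == "input" else "smp"
    for i in range(n_reads):
        chrom, lo, hi, w, fam, copy_i = intervals[iv_idx[i]]
        start = lo + int(offsets[i])
        origin_family[i] = fam
        origin_copy[i] = copy_i
        if fam is None:
            mappings = [Mapping(chrom, start, start + L)]
        else:
            placements = layout.placements[fam]
            sites = layout.divergent_sites[fam]
            o = start - placements[copy_i][1]  # homologous offset within copy
            origin_clean = not _window_hits(sites[copy_i], o, o + L)
            mappings = []
            for j, (c_chrom, c_start) in enumerate(placements):
                if j == copy_i:
                    mappings.append(Mapping(c_chrom, c_start + o, c_start + o + L))
                elif origin_clean and not _window_hits(sites[j], o, o + L):
                    mappings.append(Mapping(c_chrom, c_start + o, c_start + o + L))
            mappings.sort(key=lambda m: (m.chrom, m.start))
        reads.append(ReadGroup(f"{prefix}_{i:06d}", L, mappings))
    library = MappingLibrary(reads, spec.chrom_sizes, label=role)
    if spec.artifact is not None:
        library = plant_artifact_region(
            library, spec.artifact.chrom, spec.artifact.position,
            spec.artifact.intensity, read_length=L,
            jitter=spec.artifact.jitter,
            seed=spec.seed + 7 + (0 if role == "input" else 1) + seed_offset,
        )
    return library, GroundTruth(origin_family=origin_family, origin_copy=origin_copy)


def _window_hits(sites: np.ndarray, lo: int, hi: int) -> bool:
    """True if any divergent-site offset falls in [lo, hi)."""
    if len(sites) == 0:
        return False
    k = np.searchsorted(sites, lo, side="left")
    return k < len(sites) and sites[k] < hi


def plant_artifact_region(library: MappingLibrary, chrom: str, position: int,
                          intensity: int, read_length: int = 50,
                          jitter: int = 200, seed: int = 0) -> MappingLibrary:
    """Append ``intensity`` stacked unimapper reads at one locus.

    Starts are jittered uniformly within ``jitter`` bases of ``position``,
    emulating a satellite-like hot region a few hundred bases wide.  A locus
    wider than one window keeps nearby window counts distinct, which matters
    for a strictly-greater percentile threshold (a locus fully contained in
    two overlapping windows ties them at the top).  Identity for intensity 0.
    """
    if intensity == 0:
        return library
    size = library.chrom_sizes[chrom]
    if not (0 <= position < size):
        raise ValueError(f"artifact position {position} outside {chrom}")
    rng = np.random.default_rng(seed)
    starts = position + rng.integers(0, max(jitter, 1), size=intensity)
    reads = list(library.reads)
    for i, s in enumerate(starts):
        e = min(int(s) + read_length, size)
        reads.append(ReadGroup(f"art_{i:06d}", read_length,
                               [Mapping(chrom, int(s), e)]))
    return MappingLibrary(reads, library.chrom_sizes, library.label)


# ---------------------------------------------------------------------------
# File output (FASTA / BED / chrom.sizes / SAM) for round-trip tests and CLI
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_annotation_bed_records(records: list[RepeatRecord], path: str | Path) -> None:
    """BED with the name:family:class encoding understood by the parser."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}"
                f"\t{r.name}:{r.rep_family}:{r.rep_class}\t0\t{r.strand}\n"
            )


def write_sam(library: MappingLibrary, genome: dict[str, str],
              path: str | Path) -> None:
    """Emit the library as SAM with explicit secondary records.

    The first mapping of each read is the primary record carrying the read
    sequence (taken from the genome at the mapped locus); the remaining
    mappings are secondary records with '*' sequence, as report-all aligners
    emit them.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": s} for c, s in library.chrom_sizes.items()],
    }
    tid = {c: i for i, c in enumerate(library.chrom_sizes)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rg in library.reads:
            for j, m in enumerate(rg.mappings):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = rg.read_id
                rec.reference_id = tid[m.chrom]
                rec.reference_start = m.start
                rec.mapping_quality = 0 if rg.is_multimapper else 60
                rec.cigarstring = f"{m.span}M"
                rec.flag = 0 if j == 0 else 256
                if j == 0:
                    rec.query_sequence = genome[m.chrom][m.start:m.end]
                out.write(rec)
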