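"""Repeat annotation handling.

Parses RepeatMasker-style annotations (UCSC rmsk table, RepeatMasker ``.out``
or a BED encoding), discards repeat classes that are not transposable
elements, merges overlapping/adjacent copies of the same family or subfamily,
and exposes fast interval overlap queries.

Coordinates are 0-based half-open throughout; rmsk tables and BED are already
0-based half-open, RepeatMasker ``.out`` begin positions (1-based inclusive)
are converted on read.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "RepeatRecord",
    "TECopy",
    "TEAnnotation",
    "ParseError",
    "parse_repeatmasker",
    "filter_te_records",
    "merge_family_copies",
    "eligible_families",
    "write_annotation_bed",
    "write_family_census",
]


class ParseError(ValueError):
    """Raised when an annotation row cannot be parsed."""


# Repeat classes/families that are repeats but not transposable elements.
# Matched after stripping a trailing "?" (rmsk marks uncertain classes so);
# "Satellite" matches as a prefix (Satellite/centr, Satellite/telo, ...).
NON_TE_CLASSES = frozenset(
    {
        "Simple_repeat",
        "Low_complexity",
        "RNA",
        "tRNA",
        "rRNA",
        "snRNA",
        "scRNA",
        "srpRNA",
        "Other",
        "ARTEFACT",
    }
)

_MITO_NAMES = frozenset({"chrM", "chrMT", "MT", "M"})


def is_canonical_chrom(name: str) -> bool:
    """True for ordinary nuclear chromosomes (no scaffolds, no mitochondrion).

    Scaffolds/patches follow UCSC naming with an underscore (chrUn_*,
    chr1_*_random, chr*_alt); those and chrM/MT are excluded to mirror the
    read-level filters.
    """
    return name not in _MITO_NAMES and "_" not in name


@dataclass(frozen=True)
class RepeatRecord:
    """One annotated repeat copy, as parsed (class filtering happens later)."""

    chrom: str
    start: int
    end: int
    name: str
    rep_class: str
    rep_family: str
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class TECopy:
    """A merged TE copy carrying the family/subfamily label used for counting."""

    chrom: str
    start: int
    end: int
    family_id: str

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class TEAnnotation:
    """Merged TE copies grouped by family, with interval indexes.

    ``copies`` are sorted by (chrom, start); within one family and chromosome
    they are pairwise disjoint and non-adjacent.  ``families`` maps family_id
    to its merged copy count.  Per-(family, chrom) sorted coordinate arrays
    with cumulative covered length support O(log n) union-overlap queries used
    by the counting engine.
    """

    copies: list[TECopy]
    level: str = "name"
    families: Counter = field(default_factory=Counter)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    # (family_id, chrom) -> (starts, ends, cumcov) arrays
    _fam_index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )
    # chrom -> union of all family copies (starts, ends, cumcov)
    _any_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self.copies.sort(key=lambda c: (c.chrom, c.start, c.family_id))
        self.families = Counter(c.family_id for c in self.copies)
        self._trees = {}
        for chrom, group in itertools.groupby(self.copies, key=lambda c: c.chrom):
            tree = IntervalTree()
            for c in group:
                tree.addi(c.start, c.end, c)
            self._trees[chrom] = tree
        self._fam_index = {}
        key = lambda c: (c.family_id, c.chrom)
        for (fam, chrom), group in itertools.groupby(sorted(self.copies, key=key), key=key):
            g = list(group)
            starts = np.array([c.start for c in g], dtype=np.int64)
            ends = np.array([c.end for c in g], dtype=np.int64)
            self._fam_index[(fam, chrom)] = (starts, ends, _cumcov(starts, ends))
        self._any_index = {}
        for chrom, tree in self._trees.items():
            merged = tree.copy()
            merged.merge_overlaps(strict=False)
            ivs = sorted(merged)
            starts = np.array([iv.begin for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            self._any_index[chrom] = (starts, ends, _cumcov(starts, ends))

    @property
    def family_ids(self) -> list[str]:
        return sorted(self.families)

    def overlapping(self, chrom: str, start: int, end: int) -> list[TECopy]:
        """All merged copies overlapping [start, end) on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda c: (c.start, c.family_id))

    def family_overlap_bp(
        self, family_id: str, chrom_codes: np.ndarray, starts: np.ndarray,
        ends: np.ndarray, chrom_names: list[str],
    ) -> np.ndarray:
        """Vectorised overlap (bp) of each interval with one family's copies."""
        out = np.zeros(len(starts), dtype=np.float64)
        for code, chrom in enumerate(chrom_names):
            idx = self._fam_index.get((family_id, chrom))
            if idx is None:
                continue
            sel = chrom_codes == code
            if not sel.any():
                continue
            out[sel] = _union_overlap(starts[sel], ends[sel], *idx)
        return out

    def any_te_overlap_bp(
        self, chrom_codes: np.ndarray, starts: np.ndarray, ends: np.ndarray,
        chrom_names: list[str],
    ) -> np.ndarray:
        """Overlap (bp) of each interval with the union of all TE copies."""
        out = np.zeros(len(starts), dtype=np.float64)
        for code, chrom in enumerate(chrom_names):
            idx = self._any_index.get(chrom)
            if idx is None:
                continue
            sel = chrom_codes == code
            if not sel.any():
                continue
            out[sel] = _union_overlap(starts[sel], ends[sel], *idx)
        return out

    def total_bp(self, family_id: str) -> int:
        return sum(c.span for c in self.copies if c.family_id == family_id)


def _cumcov(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """cumcov[j] = total covered bases of copies 0..j-1 (sorted, disjoint)."""
    cum = np.zeros(len(starts) + 1, dtype=np.int64)
    np.cumsum(ends - starts, out=cum[1:])
    return cum


def _coverage_upto(x: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                   cumcov: np.ndarray) -> np.ndarray:
    """Covered bases of the interval union lying strictly left of each x."""
    j = np.searchsorted(starts, x, side="right") - 1
    j_safe = np.maximum(j, 0)
    inside = np.clip(x - starts[j_safe], 0, ends[j_safe] - starts[j_safe])
    return np.where(j < 0, 0, cumcov[j_safe] + inside)


def _union_overlap(a: np.ndarray, b: np.ndarray, starts: np.ndarray,
                   ends: np.ndarray, cumcov: np.ndarray) -> np.ndarray:
    """Overlap in bp of each query [a, b) with a sorted disjoint interval union."""
    if len(starts) == 0:
        return np.zeros(len(a), dtype=np.float64)
    return (_coverage_upto(b, starts, ends, cumcov)
            - _coverage_upto(a, starts, ends, cumcov)).astype(np.float64)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_repeatmasker(path: str | Path, dialect: str = "rmsk_table") -> list[RepeatRecord]:
    """Parse a repeat annotation file into :class:`RepeatRecord` objects.

    Parameters
    ----------
    path:
        Annotation file.
    dialect:
        ``rmsk_table`` — UCSC RepeatMasker track dump (tab-separated, with or
        without the leading ``bin`` column);
        ``rm_out`` — RepeatMasker ``.out`` (whitespace columns, 3 header lines);
        ``bed`` — BED with the name field encoded ``repName:repFamily:repClass``.
    """
    path = Path(path)
    if dialect == "rmsk_table":
        return list(_parse_rmsk_table(path))
    if dialect == "rm_out":
        return list(_parse_rm_out(path))
    if dialect == "bed":
        return list(_parse_bed(path))
    raise ValueError(f"unknown annotation dialect: {dialect!r}")


def _parse_rmsk_table(path: Path) -> Iterator[RepeatRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            # 17 columns with the UCSC bin column, 16 without
            if len(fields) >= 17:
                fields = fields[1:]
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: expected >=16 rmsk columns")
            try:
                yield RepeatRecord(
                    chrom=fields[4],
                    start=int(fields[5]),
                    end=int(fields[6]),
                    strand=fields[8],
                    name=fields[9],
                    rep_class=fields[10],
                    rep_family=fields[11],
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc


def _parse_rm_out(path: Path) -> Iterator[RepeatRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or not fields[0].lstrip("-").isdigit():
                continue  # header/blank lines
            if len(fields) < 11:
                raise ParseError(f"{path}:{lineno}: expected >=11 .out columns")
            try:
                cls_fam = fields[10]
                rep_class, _, rep_family = cls_fam.partition("/")
                yield RepeatRecord(
                    chrom=fields[4],
                    start=int(fields[5]) - 1,  # .out is 1-based inclusive
                    end=int(fields[6]),
                    strand="-" if fields[8] == "C" else fields[8],
                    name=fields[9],
                    rep_class=rep_class,
                    rep_family=rep_family or rep_class,
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc


def _parse_bed(path: Path) -> Iterator[RepeatRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 BED columns")
            try:
                name, _, rest = fields[3].partition(":")
                rep_family, _, rep_class = rest.partition(":")
                yield RepeatRecord(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=name,
                    rep_family=rep_family or name,
                    rep_class=rep_class or rep_family or name,
                    strand=fields[5] if len(fields) > 5 else ".",
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc


# ---------------------------------------------------------------------------
# Filtering and merging
# ---------------------------------------------------------------------------

def _is_te(record: RepeatRecord) -> bool:
    for label in (record.rep_class, record.rep_family):
        label = label.rstrip("?")
        if label in NON_TE_CLASSES or label.startswith("Satellite"):
            return False
    return True


def filter_te_records(records: Iterable[RepeatRecord]) -> list[RepeatRecord]:
    """Drop repeats that are not transposable elements.

    Simple repeats (micro-satellites), satellite DNA, low-complexity
    sequences and RNA repeat classes are removed; everything else, including
    class ``Unknown``, is retained.  Copies on the mitochondrial chromosome
    and on non-chromosomal scaffolds are also dropped, mirroring the
    read-level filters.
    """
    return [
        r for r in records if _is_te(r) and is_canonical_chrom(r.chrom)
    ]


def merge_family_copies(records: Iterable[RepeatRecord], level: str = "name") -> TEAnnotation:
    """Merge overlapping and immediately adjacent copies of the same family.

    ``level`` selects the counting unit: ``"name"`` uses the repName column
    (subfamily, e.g. AluYb8), ``"family"`` the repFamily column (e.g. Alu).
    Adjacency means zero gap in half-open coordinates (end_i == start_j);
    copies of different families are never merged, so a base may belong to
    copies of two different families.
    """
    if level not in ("name", "family"):
        raise ValueError(f"level must be 'name' or 'family', got {level!r}")
    label = (lambda r: r.name) if level == "name" else (lambda r: r.rep_family)
    key = lambda r: (label(r), r.chrom)
    copies: list[TECopy] = []
    for (fam, chrom), group in itertools.groupby(sorted(records, key=lambda r: (label(r), r.chrom, r.start)), key=key):
        cur_start = cur_end = None
        for r in group:
            if cur_start is None:
                cur_start, cur_end = r.start, r.end
            elif r.start <= cur_end:  # overlap or zero gap
                cur_end = max(cur_end, r.end)
            else:
                copies.append(TECopy(chrom, cur_start, cur_end, fam))
                cur_start, cur_end = r.start, r.end
        if cur_start is not None:
            copies.append(TECopy(chrom, cur_start, cur_end, fam))
    return TEAnnotation(copies=copies, level=level)


def eligible_families(annotation: TEAnnotation, min_copies: int = 50) -> set[str]:
    """Families whose merged copy count is at least ``min_copies``."""
    return {fam for fam, n in annotation.families.items() if n >= min_copies}


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_annotation_bed(annotation: TEAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in annotation.copies:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.family_id}\n")


def write_family_census(annotation: TEAnnotation, path: str | Path) -> pd.DataFrame:
    """Per-family census: copy number, total bp and mean merged copy length."""
    rows = []
    for fam in annotation.family_ids:
        n = annotation.families[fam]
        bp = annotation.total_bp(fam)
        rows.append((fam, n, bp, bp / n))
    df = pd.DataFrame(rows, columns=["family_id", "n_copies", "total_bp", "mean_copy_length"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
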