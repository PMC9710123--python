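"""Ambiguity-weighted TE family counting and mapping-ambiguity diagnostics.

The count of a TE family/subfamily K over a library is

    C_K = Σ_{k∈K} Σ_{r∈S} Σ_i  l_{k,r_i} / (N_r · L_r)

where l is the number of bases of the i-th mapping of read r overlapping the
merged copy k, N_r the read's total number of genomic mappings and L_r the
read length.  A read fully contained in one copy with a single mapping thus
contributes exactly 1; a read whose mappings touch several families
contributes to each, fractionally — there is no exclusive assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import TEAnnotation
from .library_io import MappingArrays, MappingLibrary

__all__ = [
    "FamilyCountTable",
    "AmbiguityReport",
    "count_family_mappings",
    "count_family_mappings_arrays",
    "mapping_summary",
    "classify_families_by_ambiguity",
    "write_counts_tsv",
]


@dataclass
class FamilyCountTable:
    """Fractional read-mapping counts per family for one library."""

    counts: dict[str, float]
    label: str = ""
    total_reads: int = 0

    def __getitem__(self, family_id: str) -> float:
        return self.counts.get(family_id, 0.0)

    @property
    def total(self) -> float:
        return sum(self.counts.values())


def _as_arrays(library) -> MappingArrays:
    if isinstance(library, MappingArrays):
        return library
    if hasattr(library, "arrays"):
        arr = library.arrays
        return arr() if callable(arr) else arr
    raise TypeError(f"cannot interpret {type(library).__name__} as a mapping library")


def count_family_mappings_arrays(arr: MappingArrays, annotation: TEAnnotation,
                                 families: list[str] | None = None) -> np.ndarray:
    """C_K for each family as a vector (order = ``families`` or sorted ids)."""
    if families is None:
        families = annotation.family_ids
    inv_w = 1.0 / (arr.map_nr * arr.map_length)
    out = np.empty(len(families), dtype=np.float64)
    for f_i, fam in enumerate(families):
        ov = annotation.family_overlap_bp(fam, arr.chrom_codes, arr.starts,
                                          arr.ends, arr.chrom_names)
        out[f_i] = float(np.dot(ov, inv_w))
    return out


def count_family_mappings(library, annotation: TEAnnotation) -> FamilyCountTable:
    """Ambiguity-weighted nucleotide-fraction counts C_K per family.

    Accepts a :class:`MappingLibrary` or a simulated library.  Copies are
    merged per family, so no base is double-counted within a family; bases
    shared between copies of *different* families count toward each.
    """
    arr = _as_arrays(library)
    families = annotation.family_ids
    vec = count_family_mappings_arrays(arr, annotation, families)
    return FamilyCountTable(
        counts=dict(zip(families, vec.tolist())),
        label=getattr(library, "label", ""),
        total_reads=arr.n_reads,
    )


@dataclass
class AmbiguityReport:
    """Read-ambiguity diagnostics for one or more libraries.

    ``library_fractions`` partitions each library's reads into
    {uni, multi} × {TE, non-TE} (fractions summing to 1); ``per_family``
    holds, per family, the number of reads with at least one mapping
    overlapping its copies and the multimapper fraction among them;
    ``classification`` labels each family multimapper/unimapper-dominated,
    "neither", or "no-data".
    """

    library_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    per_family: dict[str, pd.DataFrame] = field(default_factory=dict)
    classification: dict[str, str] = field(default_factory=dict)


def _family_touch_stats(arr: MappingArrays, annotation: TEAnnotation) -> pd.DataFrame:
    """Per family: reads touching (>=1 bp overlap) and multimapper fraction."""
    rows = []
    multi = arr.read_nmap > 1
    for fam in annotation.family_ids:
        ov = annotation.family_overlap_bp(fam, arr.chrom_codes, arr.starts,
                                          arr.ends, arr.chrom_names)
        touching = np.unique(arr.read_index[ov > 0])
        n = len(touching)
        frac_mm = float(multi[touching].mean()) if n else np.nan
        rows.append((fam, n, frac_mm))
    return pd.DataFrame(rows, columns=["family_id", "n_reads_touching",
                                       "fraction_multimapper"]).set_index("family_id")


def mapping_summary(library, annotation: TEAnnotation) -> AmbiguityReport:
    """Assign each read to one of {uni, multi} × {TE, non-TE}.

    TE membership is binary: at least one of the read's mappings overlaps an
    annotated TE copy by >= 1 bp.  The four fractions sum to 1 over the
    library.
    """
    arr = _as_arrays(library)
    ov = annotation.any_te_overlap_bp(arr.chrom_codes, arr.starts, arr.ends,
                                      arr.chrom_names)
    te_read = np.zeros(arr.n_reads, dtype=bool)
    np.logical_or.at(te_read, arr.read_index, ov > 0)
    multi = arr.read_nmap > 1
    n = arr.n_reads
    fractions = {
        "uni_te": float((~multi & te_read).sum()) / n,
        "multi_te": float((multi & te_read).sum()) / n,
        "uni_nonte": float((~multi & ~te_read).sum()) / n,
        "multi_nonte": float((multi & ~te_read).sum()) / n,
    }
    label = getattr(library, "label", "") or "library"
    return AmbiguityReport(
        library_fractions={label: fractions},
        per_family={label: _family_touch_stats(arr, annotation)},
    )


def classify_families_by_ambiguity(libraries: list, annotation: TEAnnotation,
                                   threshold: float = 0.9,
                                   strict: bool = True) -> AmbiguityReport:
    """Label families dominated by multimappers or unimappers.

    A family is multimapper-dominated iff in EVERY library the multimapper
    fraction among reads touching its copies exceeds ``threshold`` (strictly
    by default; ``strict=False`` uses >=); symmetric for unimapper-dominated.
    Families touched by no read in any library are "no-data"; a family
    untouched in one library but touched in another cannot satisfy the
    all-libraries condition and is "neither".
    """
    if not libraries:
        raise ValueError("at least one library required")
    stats = []
    fractions = {}
    for i, lib in enumerate(libraries):
        rep = mapping_summary(lib, annotation)
        stats.append(next(iter(rep.per_family.values())))
        label = getattr(lib, "label", "") or "library"
        if label in fractions:
            label = f"{label}_{i}"
        fractions[label] = next(iter(rep.library_fractions.values()))
    exceeds = (lambda f, t: f > t) if strict else (lambda f, t: f >= t)
    classification = {}
    for fam in annotation.family_ids:
        touched = [df.loc[fam] for df in stats]
        if all(row.n_reads_touching == 0 for row in touched):
            classification[fam] = "no-data"
            continue
        ok = [row for row in touched if row.n_reads_touching > 0]
        complete = len(ok) == len(touched)
        if complete and all(exceeds(row.fraction_multimapper, threshold) for row in ok):
            classification[fam] = "multimapper"
        elif complete and all(exceeds(1.0 - row.fraction_multimapper, threshold) for row in ok):
            classification[fam] = "unimapper"
        else:
            classification[fam] = "neither"
    return AmbiguityReport(
        library_fractions=fractions,
        per_family={lbl: df for lbl, df in zip(fractions, stats)},
        classification=classification,
    )


def write_counts_tsv(table: FamilyCountTable, annotation: TEAnnotation,
                     path) -> pd.DataFrame:
    df = pd.DataFrame(
        [(fam, table[fam], annotation.families.get(fam, 0))
         for fam in sorted(table.counts)],
        columns=["family_id", "count", "n_copies"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
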