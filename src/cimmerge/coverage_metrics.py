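"""Sequence coverage, redundancy and curation accounting for peptide maps.

Coverage is the percentage of protein residues touched by at least one
peptide; redundancy is the mean number of unique peptides covering each
covered residue.  Higher coverage broadens the structural information from
a hydrogen/deuterium-exchange experiment, higher redundancy sharpens its
spatial resolution through overlapping peptides.

The curation helpers express the bookkeeping done after manual spectral
validation: what fraction of a filtered list survives curation, and what
fraction of monitored peptides track through a labelling timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .peptide_io import ProteinRecord

__all__ = [
    "CoverageReport",
    "coverage_report",
    "compare_reports",
    "removal_percent",
    "monitored_percent",
    "fraction_percent",
]


@dataclass(frozen=True)
class CoverageReport:
    """Coverage metrics for one protein.

    ``coverage_percent`` = 100 x covered residues / protein length;
    ``redundancy`` = mean peptide depth over *covered* residues (0 when
    nothing is covered); ``per_residue_depth[i]`` is the number of unique
    peptides spanning residue ``i + 1``.  Values are stored unrounded.
    """

    protein_id: str
    n_peptides: int
    coverage_percent: float
    redundancy: float
    per_residue_depth: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        """Per-residue depth as a two-column (residue, depth) table."""
        return pd.DataFrame(
            {
                "residue": np.arange(1, len(self.per_residue_depth) + 1),
                "depth": list(self.per_residue_depth),
            }
        )

    def summary(self) -> str:
        return (
            f"{self.protein_id}: {self.n_peptides} peptides, "
            f"{self.coverage_percent:.1f}% coverage, "
            f"redundancy {self.redundancy:.2f}"
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def coverage_report(
    peptides: Iterable,
    protein: ProteinRecord,
    redundancy_denominator: str = "covered",
) -> CoverageReport:
    """Compute coverage and redundancy of a peptide list over a protein.

    Every peptide's [start, end] span (1-based inclusive) increments the
    depth of each residue it contains.  ``redundancy_denominator`` selects
    whether redundancy divides the summed depth by the number of covered
    residues (default) or by the full protein length (``"total"``).

    Peptides outside [1, length] raise, naming the offender.
    """
    if redundancy_denominator not in ("covered", "total"):
        raise ValueError(
            f"redundancy_denominator must be 'covered' or 'total', "
            f"got {redundancy_denominator!r}"
        )
    length = protein.length
    depth = np.zeros(length, dtype=int)
    n = 0
    for p in peptides:
        if p.start < 1 or p.end > length:
            raise ValueError(
                f"peptide {p.sequence!r} [{p.start}, {p.end}] falls outside "
                f"protein {protein.protein_id!r} of length {length}"
            )
        depth[p.start - 1 : p.end] += 1
        n += 1
    covered = int(np.count_nonzero(depth))
    coverage = 100.0 * covered / length
    total_depth = int(depth.sum())
    if redundancy_denominator == "covered":
        redundancy = total_depth / covered if covered else 0.0
    else:
        redundancy = total_depth / length
    return CoverageReport(
        protein_id=protein.protein_id,
        n_peptides=n,
        coverage_percent=coverage,
        redundancy=redundancy,
        per_residue_depth=tuple(int(d) for d in depth),
    )


def compare_reports(a: CoverageReport, b: CoverageReport) -> pd.DataFrame:
    """Tabulate metric deltas between two reports of the same protein.

    Returns a table with each metric's value under ``a`` and ``b``, the
    absolute difference ``a - b`` and the percent change
    ``100 * (a - b) / b`` (NaN where ``b`` is 0).
    """
    if a.protein_id != b.protein_id:
        raise ValueError(
            f"cannot compare reports for different proteins: "
            f"{a.protein_id!r} vs {b.protein_id!r}"
        )
    rows = []
    for metric in ("n_peptides", "coverage_percent", "redundancy"):
        va, vb = float(getattr(a, metric)), float(getattr(b, metric))
        rows.append(
            {
                "metric": metric,
                "a": va,
                "b": vb,
                "abs_diff": va - vb,
                "percent_change": 100.0 * (va - vb) / vb if vb else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def removal_percent(n_before: int, n_after: int) -> float:
    """Percent of peptides removed going from one list to a curated subset."""
    if n_before <= 0:
        raise ValueError("n_before must be > 0")
    if not 0 <= n_after <= n_before:
        raise ValueError(f"n_after must be in [0, {n_before}], got {n_after}")
    return 100.0 * (n_before - n_after) / n_before


def monitored_percent(n_monitored: int, n_assessed: int) -> float:
    """Percent of assessed peptides successfully monitored in an HDX timepoint."""
    return fraction_percent(n_monitored, n_assessed)


def fraction_percent(part: int, whole: int) -> float:
    """100 * part / whole, guarding the degenerate denominators."""
    if whole <= 0:
        raise ValueError("whole must be > 0")
    if not 0 <= part <= whole:
        raise ValueError(f"part must be in [0, {whole}], got {part}")
    return 100.0 * part / whole
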