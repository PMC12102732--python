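"""Reading and writing peptide-identification tables and target sequences.

Per-replicate peptide ID lists are plain CSV exports, one file per replicate,
sorted into per-trendline subfolders named by the underscore convention
(``11_13`` for the 11-13 trendline; single-pass always ``1_1``)::

    output/
      11_13/rep1.csv  rep2.csv  rep3.csv
      21_23/rep1.csv  ...
      1_1/rep1.csv    ...

Vendor exports vary in their column headings, so the reader goes through an
explicit column map (:data:`DEFAULT_COLUMN_MAP`) that callers can override to
adapt a particular export dialect without touching the parser.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, asdict, fields as _dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "PeptideID",
    "ProteinRecord",
    "PeptideTableError",
    "DEFAULT_COLUMN_MAP",
    "read_peptide_table",
    "read_peptide_folder",
    "read_fasta",
    "write_peptide_table",
    "write_final_list",
    "FINAL_LIST_COLUMNS",
]


class PeptideTableError(ValueError):
    """Malformed peptide table: missing columns, bad rows, broken invariants."""


@dataclass(frozen=True)
class PeptideID:
    """One identified peptide as exported per replicate.

    Coordinates are 1-based inclusive residue indices on the target protein
    (``end - start + 1 == len(sequence)``).  ``dt_bin`` is the drift-time
    bin within the 200-push acquisition window.  ``plgs_score`` is the
    search engine's confidence score, used downstream only as a ranking key.
    """

    protein_id: str
    sequence: str
    start: int
    end: int
    modification: str
    plgs_score: float
    rt: float
    dt_bin: float
    intensity: float
    products_per_aa: float
    matched_products: int
    consecutive_products: int
    sum_product_intensity: float
    mh_ppm_error: float
    replicate_id: str
    trendline_tag: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise PeptideTableError(
                f"peptide {self.sequence!r}: end {self.end} < start {self.start}"
            )
        if self.end - self.start + 1 != len(self.sequence):
            raise PeptideTableError(
                f"peptide {self.sequence!r}: span [{self.start}, {self.end}] "
                f"has length {self.end - self.start + 1}, sequence has "
                f"{len(self.sequence)}"
            )
        if not (0.0 <= self.dt_bin <= 200.0):
            raise PeptideTableError(
                f"peptide {self.sequence!r}: dt_bin {self.dt_bin} outside [0, 200]"
            )
        if self.rt <= 0 or not math.isfinite(self.rt):
            raise PeptideTableError(
                f"peptide {self.sequence!r}: rt must be > 0, got {self.rt}"
            )
        if self.plgs_score < 0:
            raise PeptideTableError(
                f"peptide {self.sequence!r}: plgs_score must be >= 0"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def key(self) -> tuple[str, str, str]:
        """Identity key used for merging: (protein, sequence, modification)."""
        return (self.protein_id, self.sequence, self.modification)


@dataclass(frozen=True)
class ProteinRecord:
    """A target protein sequence from the supplied FASTA."""

    protein_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


# canonical field name -> CSV column heading (identity by default)
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "protein_id": "protein_id",
    "sequence": "sequence",
    "start": "start",
    "end": "end",
    "modification": "modification",
    "plgs_score": "plgs_score",
    "rt": "rt",
    "dt_bin": "dt_bin",
    "intensity": "intensity",
    "products_per_aa": "products_per_aa",
    "matched_products": "matched_products",
    "consecutive_products": "consecutive_products",
    "sum_product_intensity": "sum_product_intensity",
    "mh_ppm_error": "mh_ppm_error",
}

_NUMERIC = {
    "start": int,
    "end": int,
    "plgs_score": float,
    "rt": float,
    "dt_bin": float,
    "intensity": float,
    "products_per_aa": float,
    "matched_products": int,
    "consecutive_products": int,
    "sum_product_intensity": float,
    "mh_ppm_error": float,
}

#: Columns written by :func:`write_final_list` (averaged metrics plus
#: replicate bookkeeping); shared columns round-trip through
#: :func:`read_peptide_table`.
FINAL_LIST_COLUMNS = [
    "protein_id", "sequence", "start", "end", "modification",
    "plgs_score", "rt", "rt_rsd_percent", "replicate_count",
    "dt_bin", "intensity", "products_per_aa", "matched_products",
    "consecutive_products", "sum_product_intensity", "mh_ppm_error",
    "source_tags",
]


def _infer_tags(path: Path) -> tuple[str, str]:
    """(replicate_id, trendline_tag) from the folder convention."""
    return path.stem, path.parent.name


def read_peptide_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> list[PeptideID]:
    """Read one per-replicate peptide ID table (CSV) into records.

    ``replicate_id`` and ``trendline_tag`` are taken from columns of those
    names when present, otherwise inferred from the path: the file stem
    names the replicate and the parent folder names the trendline tag.

    When ``proteins`` is given (a mapping of protein_id -> ProteinRecord),
    each peptide's sequence is checked against the protein at its stated
    coordinates.

    Raises :class:`PeptideTableError` naming the missing column, or the
    offending row index for row-level parse failures.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [col for field, col in cmap.items() if col not in df.columns]
    if missing:
        raise PeptideTableError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    rep_default, tag_default = _infer_tags(path)
    has_rep = "replicate_id" in df.columns
    has_tag = "trendline_tag" in df.columns

    records: list[PeptideID] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        values: dict[str, object] = {}
        for field, col in cmap.items():
            raw = rowd[col]
            conv = _NUMERIC.get(field)
            if conv is None:
                values[field] = str(raw).strip()
                continue
            try:
                values[field] = conv(float(raw)) if conv is int else conv(raw)
            except (TypeError, ValueError) as exc:
                raise PeptideTableError(
                    f"{path}: row {i}: cannot parse {col}={raw!r} as "
                    f"{conv.__name__}"
                ) from exc
        values["sequence"] = str(values["sequence"]).upper()
        values["replicate_id"] = (
            str(rowd["replicate_id"]).strip() if has_rep else rep_default
        )
        values["trendline_tag"] = (
            str(rowd["trendline_tag"]).strip() if has_tag else tag_default
        )
        try:
            rec = PeptideID(**values)  # type: ignore[arg-type]
        except PeptideTableError as exc:
            raise PeptideTableError(f"{path}: row {i}: {exc}") from exc
        if proteins is not None:
            prot = proteins.get(rec.protein_id)
            if prot is not None:
                segment = prot.sequence[rec.start - 1 : rec.end]
                if segment != rec.sequence:
                    raise PeptideTableError(
                        f"{path}: row {i}: sequence {rec.sequence!r} does not "
                        f"match protein {rec.protein_id!r} at "
                        f"[{rec.start}, {rec.end}] (found {segment!r})"
                    )
        records.append(rec)
    return records


def read_peptide_folder(
    root: str | Path,
    column_map: Mapping[str, str] | None = None,
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> dict[str, list[list[PeptideID]]]:
    """Read a per-trendline folder tree into ``{tag: [replicate tables]}``.

    Each immediate subfolder of ``root`` is one trendline tag; every
    ``*.csv`` inside is one replicate table.  Files are read in sorted
    order for reproducibility.
    """
    root = Path(root)
    out: dict[str, list[list[PeptideID]]] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        files = sorted(sub.glob("*.csv"))
        if files:
            out[sub.name] = [
                read_peptide_table(f, column_map, proteins) for f in files
            ]
    return out


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read target protein sequences; uppercased, whitespace stripped.

    Raises on an empty file or duplicate record IDs.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA ID {rec.id!r}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split()).upper()
        out.append(ProteinRecord(rec.id, seq))
    return out


def write_peptide_table(records: Sequence[PeptideID], path: str | Path) -> Path:
    """Write PeptideID records to CSV with the canonical column names."""
    path = Path(path)
    cols = [f.name for f in _dc_fields(PeptideID)]
    df = pd.DataFrame([asdict(r) for r in records], columns=cols)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_final_list(
    peptides: Iterable,  # Iterable[MergedPeptide]; untyped to avoid a cycle
    out_dir: str | Path,
    stem: str = "final_peptides",
    timestamp: _dt.datetime | None = None,
) -> Path:
    """Save a merged/filtered peptide list as a timestamped CSV.

    The filename embeds an ISO-8601 basic timestamp
    (``<stem>_YYYYMMDDThhmmss.csv``) so successive runs never overwrite
    each other.  Returns the written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ts = (timestamp or _dt.datetime.now()).strftime("%Y%m%dT%H%M%S")
    path = out_dir / f"{stem}_{ts}.csv"
    rows = []
    for p in peptides:
        rows.append(
            {
                "protein_id": p.protein_id,
                "sequence": p.sequence,
                "start": p.start,
                "end": p.end,
                "modification": p.modification,
                "plgs_score": p.plgs_score,
                "rt": p.rt_mean,
                "rt_rsd_percent": p.rt_rsd,
                "replicate_count": p.replicate_count,
                # merged records have no single drift time; placeholder keeps
                # the export re-readable as a peptide table
                "dt_bin": 0.0,
                "intensity": p.intensity,
                "products_per_aa": p.products_per_aa,
                "matched_products": p.matched_products,
                "consecutive_products": p.consecutive_products,
                "sum_product_intensity": p.sum_product_intensity,
                "mh_ppm_error": p.mh_ppm_error,
                "source_tags": ";".join(sorted(p.source_tags)),
            }
        )
    pd.DataFrame(rows, columns=FINAL_LIST_COLUMNS).to_csv(path, index=False)
    return path
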