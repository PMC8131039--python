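"""Readers and writers for the tabular and genomic inputs shared by every stage.

The canonical carriers are plain-text tables (TSV or CSV, auto-detected from
the header line), 3+ column BED for genomic intervals, a minimal VCF subset
for variants, and JSON for fitted-model serialization.  All internal
coordinates are 0-based half-open; 1-based coordinates appear only at the
VCF boundary.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .phenotype import StorageSeries

logger = logging.getLogger(__name__)

#: tokens that denote a missing genotype call in exported tables
MISSING_TOKENS = frozenset({"", "NA", "-", "./."})

#: annotation regions understood by the candidate filter
VARIANT_REGIONS = ("promoter", "CDS_domain", "CDS_other", "other")


class TableFormatError(ValueError):
    """Raised when an input table violates its documented schema."""


# ---------------------------------------------------------------------------
# genotype calls
# ---------------------------------------------------------------------------

def normalize_call(raw: Optional[str]) -> Optional[str]:
    """Normalize one genotype cell to a canonical class label.

    ``"G:A"`` and ``"A:G"`` map to the same label (alleles sorted); a bare
    single allele ``"A"`` is treated as homozygous ``"A:A"``; missing tokens
    map to ``None``.  Normalization is idempotent.
    """
    if raw is None:
        return None
    token = str(raw).strip()
    if token in MISSING_TOKENS:
        return None
    alleles = token.split(":")
    if len(alleles) == 1:
        alleles = [alleles[0], alleles[0]]
    if len(alleles) != 2 or any(not a for a in alleles):
        raise TableFormatError(f"unparseable genotype call {raw!r}")
    return ":".join(sorted(alleles))


def call_alleles(label: str) -> tuple[str, str]:
    """Split a normalized class label into its (sorted) allele pair."""
    a, b = label.split(":")
    return a, b


@dataclass
class GenotypeTable:
    """Hybrids x markers matrix of normalized biallelic genotype-class labels.

    ``calls`` is an object-dtype DataFrame indexed by hybrid id with one
    column per marker; missing calls are ``None``.  ``population`` is an
    optional per-hybrid cross label aligned with the index.
    """

    calls: pd.DataFrame
    population: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dupes = self.calls.index[self.calls.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate hybrid id(s): {dupes}")
        if self.calls.columns.has_duplicates:
            dupes = self.calls.columns[self.calls.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate marker id(s): {dupes}")
        self._validate_alleles()

    def _validate_alleles(self) -> None:
        for marker in self.calls.columns:
            alleles: set[str] = set()
            for label in self.calls[marker]:
                if label is not None:
                    alleles.update(call_alleles(label))
            if len(alleles) > 2:
                raise TableFormatError(
                    f"marker {marker!r} shows {len(alleles)} alleles "
                    f"({sorted(alleles)}); at most 2 allowed"
                )

    @property
    def hybrid_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_missing(self) -> int:
        return int(self.calls.isna().sum().sum())

    def complete_hybrids(self, markers: Optional[Sequence[str]] = None) -> list[str]:
        """Hybrid ids with a non-missing call at every requested marker."""
        sub = self.calls if markers is None else self.calls[list(markers)]
        mask = sub.notna().all(axis=1)
        return list(sub.index[mask])

    def subset(self, hybrid_ids: Iterable[str]) -> "GenotypeTable":
        ids = list(hybrid_ids)
        pop = self.population.loc[ids] if self.population is not None else None
        return GenotypeTable(self.calls.loc[ids].copy(), pop)


def _sniff_delimiter(header_line: str, override: Optional[str] = None) -> str:
    if override:
        return override
    return "\t" if "\t" in header_line else ","


def read_genotype_table(path: str | Path, delimiter: Optional[str] = None) -> GenotypeTable:
    """Read a hybrids x markers genotype table.

    Layout: first column = hybrid id, optional ``population`` column,
    remaining columns = marker ids; cells are ``X:Y``, ``X``, or a missing
    token.  Allele order in unphased calls is not meaningful and is
    normalized away.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise TableFormatError(f"{path}: empty file")
        delim = _sniff_delimiter(first, delimiter)
        fh.seek(0)
        frame = pd.read_csv(fh, sep=delim, dtype=str, keep_default_na=False)
    id_col = frame.columns[0]
    pop_col = next((c for c in frame.columns[1:] if c.lower() == "population"), None)
    marker_cols = [c for c in frame.columns[1:] if c != pop_col]
    calls = frame[marker_cols].map(normalize_call)
    calls.index = pd.Index(frame[id_col].astype(str), name="hybrid_id")
    calls.columns.name = "marker_id"
    # object dtype with None for missing
    calls = calls.astype(object).where(calls.notna(), None)
    population = None
    if pop_col is not None:
        population = pd.Series(frame[pop_col].values, index=calls.index, name="population")
    table = GenotypeTable(calls, population)
    pct_missing = 100.0 * table.n_missing / max(1, calls.size)
    logger.info(
        "read genotype table %s: %d hybrids x %d markers, %.2f%% missing",
        path, len(table.hybrid_ids), len(table.marker_ids), pct_missing,
    )
    return table


def write_genotype_table(table: GenotypeTable, path: str | Path, delimiter: str = "\t") -> None:
    frame = table.calls.copy()
    frame = frame.astype(object).where(frame.notna(), "NA")
    if table.population is not None:
        frame.insert(0, "population", table.population)
    frame.to_csv(path, sep=delimiter, index_label="hybrid_id")


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def read_phenotype_table(path: str | Path, delimiter: Optional[str] = None,
                         max_month: float = 6.0) -> pd.DataFrame:
    """Read per-hybrid observed phenotype values (retainability in months).

    Columns: ``hybrid_id``, ``trait``, ``opv`` and optional ``year``.  One
    record per (hybrid, trait, year).
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        delim = _sniff_delimiter(first, delimiter)
    frame = pd.read_csv(path, sep=delim)
    required = {"hybrid_id", "trait", "opv"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing_cols)}")
    if (frame["opv"] < 0).any():
        raise TableFormatError(f"{path}: negative opv value")
    if (frame["opv"] > max_month).any():
        raise TableFormatError(f"{path}: opv exceeds max_month={max_month}")
    keys = ["hybrid_id", "trait"] + (["year"] if "year" in frame.columns else [])
    if frame.duplicated(keys).any():
        raise TableFormatError(f"{path}: duplicate record for {keys}")
    frame["hybrid_id"] = frame["hybrid_id"].astype(str)
    return frame


def write_phenotype_table(frame: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    frame.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# storage-series tables
# ---------------------------------------------------------------------------

def read_storage_table(path: str | Path, delimiter: Optional[str] = None) -> list[StorageSeries]:
    """Read monthly storage measurements into per-(hybrid, trait) series.

    Columns: ``hybrid_id``, ``trait``, ``month``, ``value``.  Duplicate
    (hybrid, trait, month) rows are technical replicates and are averaged.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        delim = _sniff_delimiter(first, delimiter)
    frame = pd.read_csv(path, sep=delim)
    required = {"hybrid_id", "trait", "month", "value"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing_cols)}")
    if (frame["value"] < 0).any():
        bad = frame.loc[frame["value"] < 0].iloc[0]
        raise TableFormatError(
            f"{path}: negative value {bad['value']} for hybrid {bad['hybrid_id']}"
        )
    months = frame["month"]
    if not (months == months.astype(int)).all():
        raise TableFormatError(f"{path}: non-integer month value")
    if (months < 0).any():
        raise TableFormatError(f"{path}: negative month value")
    frame = frame.copy()
    frame["hybrid_id"] = frame["hybrid_id"].astype(str)
    frame["month"] = months.astype(int)
    grouped = (
        frame.groupby(["hybrid_id", "trait", "month"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    series: list[StorageSeries] = []
    for (hybrid_id, trait), grp in grouped.groupby(["hybrid_id", "trait"], sort=True):
        grp = grp.sort_values("month")
        series.append(
            StorageSeries(
                hybrid_id=hybrid_id,
                trait=trait,
                months=grp["month"].to_numpy(),
                values=grp["value"].to_numpy(float),
            )
        )
    return series


def write_storage_table(series: Iterable[StorageSeries], path: str | Path,
                        delimiter: str = "\t") -> None:
    rows = []
    for s in series:
        for month, value in zip(s.months, s.values):
            rows.append((s.hybrid_id, s.trait, int(month), float(value)))
    frame = pd.DataFrame(rows, columns=["hybrid_id", "trait", "month", "value"])
    frame.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# genomic intervals and variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class VariantRecord:
    """Minimal variant: position (internal 0-based) plus filter annotations."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    region: str = "other"
    disrupts_cis_element: bool = False
    disrupts_domain: bool = False


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file (0-based half-open) into intervals."""
    intervals: list[GenomicInterval] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableFormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            label = fields[3] if len(fields) > 3 else ""
            try:
                intervals.append(GenomicInterval(fields[0], start, end, label))
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def _parse_info(info: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if info in (".", ""):
        return out
    for item in info.split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key] = value if value else "1"
    return out


_TRUE_TOKENS = {"1", "true", "True", "yes"}


def read_minimal_vcf(path: str | Path) -> list[VariantRecord]:
    """Read the minimal VCF subset: CHROM, POS, REF, ALT plus INFO annotations.

    Recognized INFO keys: ``REGION`` (one of promoter / CDS_domain /
    CDS_other / other), ``CIS_DISRUPT`` and ``DOMAIN_DISRUPT`` (flags).
    POS is converted from 1-based to the internal 0-based convention.
    """
    records: list[VariantRecord] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise TableFormatError(f"{path}:{lineno}: expected >=5 VCF columns")
            chrom, pos_str, _id, ref, alt = fields[:5]
            try:
                pos = int(pos_str)
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: non-integer POS") from exc
            if pos < 1:
                raise TableFormatError(f"{path}:{lineno}: POS must be >= 1")
            info = _parse_info(fields[7]) if len(fields) > 7 else {}
            region = info.get("REGION", "other")
            if region not in VARIANT_REGIONS:
                raise TableFormatError(f"{path}:{lineno}: unknown REGION {region!r}")
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos - 1,
                    ref=ref,
                    alt=alt,
                    region=region,
                    disrupts_cis_element=info.get("CIS_DISRUPT", "0") in _TRUE_TOKENS,
                    disrupts_domain=info.get("DOMAIN_DISRUPT", "0") in _TRUE_TOKENS,
                )
            )
    return records


def write_minimal_vcf(records: Iterable[VariantRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            info = f"REGION={rec.region}"
            if rec.disrupts_cis_element:
                info += ";CIS_DISRUPT=1"
            if rec.disrupts_domain:
                info += ";DOMAIN_DISRUPT=1"
            fh.write(
                f"{rec.chrom}\t{rec.pos + 1}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{info}\n"
            )


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------

def write_model_json(model, path: str | Path) -> None:
    """Serialize a fitted model to JSON (round-trips to an identical model)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model_json(path: str | Path):
    from .gap_model import GapModel  # local import: gap_model imports this module

    with Path(path).open(encoding="utf-8") as fh:
        payload = json.load(fh)
    return GapModel.from_dict(payload)
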