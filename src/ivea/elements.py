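"""Construction of promoter and enhancer elements from peak calls and annotation.

Coordinates are 0-based half-open (BED dialect) throughout.  Element and
promoter lengths are carried in kilobases, effective transcript lengths are
converted from nucleotides to kilobases on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "PeakRecord",
    "RegulatoryElement",
    "PromoterElement",
    "ExpressionRecord",
    "select_resize_merge_peaks",
    "build_promoter_elements",
    "enhancer_universe",
    "compute_tpm",
    "filter_genes_by_expression",
    "read_genes",
    "read_peaks",
    "read_expression",
    "read_burst_sizes",
    "read_elements",
    "write_elements",
    "write_promoters",
    "read_promoters",
]

DEFAULT_PROMOTER_FLANK = 1000
DEFAULT_TOP_N = 150_000
DEFAULT_PEAK_WIDTH = 500
DEFAULT_TPM_CUTOFF = 8.0


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.body_start < self.body_end:
            raise ValueError(f"{self.gene_id}: body_start must be < body_end")
        if not self.body_start <= self.tss <= self.body_end:
            raise ValueError(f"{self.gene_id}: tss outside gene body")


@dataclass(frozen=True)
class PeakRecord:
    chrom: str
    start: int
    end: int
    summit_offset: int
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("peak read_count must be non-negative")
        if not 0 <= self.summit_offset < self.end - self.start:
            raise ValueError("summit_offset outside peak interval")

    @property
    def summit(self) -> int:
        return self.start + self.summit_offset


@dataclass(frozen=True)
class RegulatoryElement:
    element_id: str
    chrom: str
    start: int
    end: int
    read_count: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.element_id}: empty interval")

    @property
    def length_kb(self) -> float:
        return (self.end - self.start) / 1000.0

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PromoterElement:
    gene_id: str
    length_kb: float
    read_count: int
    constituent_element_ids: tuple = ()


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    read_count: int
    effective_length_kb: float
    tpm: float = field(default=np.nan)


def _element_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def select_resize_merge_peaks(
    peaks: Sequence[PeakRecord],
    top_n: int | None = DEFAULT_TOP_N,
    width: int | None = DEFAULT_PEAK_WIDTH,
) -> list[RegulatoryElement]:
    """Keep the ``top_n`` peaks by read count, resize each around its summit
    and merge strictly overlapping intervals into regulatory elements.

    Resizing maps a peak to ``[summit - width//2, summit + width - width//2)``
    clipped at the chromosome start; ``width=None`` keeps native intervals.
    Merged elements sum their constituents' read counts.  Bookended intervals
    (end == next start) are left unmerged.  Ties in the top-N cut are broken
    by genomic order.
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    if width is not None and width < 1:
        raise ValueError("width must be >= 1")
    peaks = list(peaks)
    if not peaks:
        warnings.warn("no peaks supplied; returning an empty element set")
        return []

    ranked = sorted(peaks, key=lambda p: (-p.read_count, p.chrom, p.start))
    if top_n is not None:
        ranked = ranked[:top_n]

    resized: list[tuple[str, int, int, int]] = []
    for p in ranked:
        if width is None:
            start, end = p.start, p.end
        else:
            half = width // 2
            start = max(0, p.summit - half)
            end = p.summit + (width - half)
        resized.append((p.chrom, start, end, p.read_count))
    resized.sort(key=lambda r: (r[0], r[1], r[2]))

    merged: list[RegulatoryElement] = []
    cur = None  # [chrom, start, end, count]
    for chrom, start, end, count in resized:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3] += count
        else:
            if cur is not None:
                merged.append(
                    RegulatoryElement(_element_id(*cur[:3]), cur[0], cur[1], cur[2], cur[3])
                )
            cur = [chrom, start, end, count]
    if cur is not None:
        merged.append(RegulatoryElement(_element_id(*cur[:3]), cur[0], cur[1], cur[2], cur[3]))
    return merged


def build_promoter_elements(
    genes: Sequence[GeneRecord],
    elements: Sequence[RegulatoryElement],
    flank: int = DEFAULT_PROMOTER_FLANK,
) -> tuple[list[PromoterElement], list[str]]:
    """Aggregate elements overlapping ``[tss - flank, tss + flank)`` per gene.

    Returns the promoter elements and the ids of genes with no overlapping
    element (those genes are dropped from downstream analysis).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[RegulatoryElement]]] = {}
    for chrom in {e.chrom for e in elements}:
        els = [e for e in elements if e.chrom == chrom]
        by_chrom[chrom] = (
            np.array([e.start for e in els]),
            np.array([e.end for e in els]),
            els,
        )

    promoters: list[PromoterElement] = []
    excluded: list[str] = []
    for g in genes:
        lo, hi = g.tss - flank, g.tss + flank
        hit: list[RegulatoryElement] = []
        if g.chrom in by_chrom:
            starts, ends, els = by_chrom[g.chrom]
            mask = (starts < hi) & (ends > lo)
            hit = [els[i] for i in np.flatnonzero(mask)]
        if not hit:
            excluded.append(g.gene_id)
            continue
        promoters.append(
            PromoterElement(
                gene_id=g.gene_id,
                length_kb=sum(e.length_kb for e in hit),
                read_count=sum(e.read_count for e in hit),
                constituent_element_ids=tuple(e.element_id for e in hit),
            )
        )
    return promoters, excluded


def enhancer_universe(elements: Sequence[RegulatoryElement]) -> list[RegulatoryElement]:
    """All elements act individually as candidate enhancers, including those
    inside promoter regions; this is the identity on the element set."""
    return list(elements)


def compute_tpm(records: Iterable[ExpressionRecord]) -> list[ExpressionRecord]:
    """Fill in TPM: 1e6 * (count/length) / sum_over_genes(count/length)."""
    records = list(records)
    rates = np.array([r.read_count / r.effective_length_kb for r in records], dtype=float)
    total = rates.sum()
    tpms = rates / total * 1e6 if total > 0 else np.zeros_like(rates)
    return [
        ExpressionRecord(r.gene_id, r.read_count, r.effective_length_kb, tpm)
        for r, tpm in zip(records, tpms)
    ]


def filter_genes_by_expression(
    records: Sequence[ExpressionRecord], cutoff_tpm: float = DEFAULT_TPM_CUTOFF
) -> list[ExpressionRecord]:
    """Keep records with TPM strictly greater than ``cutoff_tpm``."""
    if cutoff_tpm < 0:
        raise ValueError("cutoff_tpm must be >= 0")
    recs = list(records)
    if any(np.isnan(r.tpm) for r in recs):
        recs = compute_tpm(recs)
    return [r for r in recs if r.tpm > cutoff_tpm]


# ---------------------------------------------------------------------------
# File interfaces


def read_genes(path: str | Path) -> list[GeneRecord]:
    """TSV with header gene_id, symbol, chrom, strand, tss, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "symbol", "chrom", "strand", "tss", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} is missing columns: {sorted(missing)}")
    return [
        GeneRecord(
            str(r.gene_id), str(r.symbol), str(r.chrom), str(r.strand),
            int(r.tss), int(r.start), int(r.end),
        )
        for r in df.itertuples()
    ]


def read_peaks(path: str | Path) -> list[PeakRecord]:
    """narrowPeak (10 columns, no header: summit offset in column 10, signal in
    column 7) or a headered TSV with chrom, start, end, summit_offset, read_count."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("chrom"):
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        need = {"chrom", "start", "end", "summit_offset", "read_count"}
        if need - set(df.columns):
            raise ValueError(
                f"peak table {path} needs columns {sorted(need)}; "
                f"found {list(df.columns)}"
            )
        rows = zip(df.chrom, df.start, df.end, df.summit_offset, df.read_count)
    else:
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
        if df.shape[1] < 10:
            raise ValueError(
                f"{path}: expected 10-column narrowPeak "
                f"(column 10 = summit offset), got {df.shape[1]} columns"
            )
        rows = zip(df[0], df[1], df[2], df[9], df[6])
    return [
        PeakRecord(str(c), int(s), int(e), int(o), int(round(float(n))))
        for c, s, e, o, n in rows
    ]


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    """TSV with header gene_id, count, effective_length (nt; converted to kb)."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "count", "effective_length"}
    if need - set(df.columns):
        raise ValueError(f"expression table {path} needs columns {sorted(need)}")
    recs = [
        ExpressionRecord(str(r.gene_id), int(r.count), float(r.effective_length) / 1000.0)
        for r in df.itertuples()
    ]
    return compute_tpm(recs)


def read_burst_sizes(path: str | Path, default: float = 1.0) -> dict[str, float]:
    """TSV with header gene_id, burst_size; values must be positive."""
    df = pd.read_csv(path, sep="\t")
    if {"gene_id", "burst_size"} - set(df.columns):
        raise ValueError(f"burst-size table {path} needs columns gene_id, burst_size")
    table = {str(r.gene_id): float(r.burst_size) for r in df.itertuples()}
    if any(v <= 0 for v in table.values()):
        raise ValueError("burst sizes must be strictly positive")
    table["__default__"] = default
    return table


def write_elements(elements: Sequence[RegulatoryElement], bed_path, tsv_path) -> None:
    rows = [
        (e.chrom, e.start, e.end, e.element_id, e.read_count, ".") for e in elements
    ]
    pd.DataFrame(rows).to_csv(bed_path, sep="\t", header=False, index=False)
    pd.DataFrame(
        {
            "element_id": [e.element_id for e in elements],
            "chrom": [e.chrom for e in elements],
            "start": [e.start for e in elements],
            "end": [e.end for e in elements],
            "read_count": [e.read_count for e in elements],
            "length_kb": [e.length_kb for e in elements],
        }
    ).to_csv(tsv_path, sep="\t", index=False)


def read_elements(tsv_path) -> list[RegulatoryElement]:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    need = {"element_id", "chrom", "start", "end", "read_count"}
    if need - set(df.columns):
        raise ValueError(f"element table {tsv_path} needs columns {sorted(need)}")
    return [
        RegulatoryElement(str(r.element_id), str(r.chrom), int(r.start), int(r.end), int(r.read_count))
        for r in df.itertuples()
    ]


def write_promoters(promoters: Sequence[PromoterElement], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in promoters],
            "length_kb": [p.length_kb for p in promoters],
            "read_count": [p.read_count for p in promoters],
            "constituents": [",".join(p.constituent_element_ids) for p in promoters],
        }
    ).to_csv(path, sep="\t", index=False)


def read_promoters(path) -> list[PromoterElement]:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "length_kb", "read_count"}
    if need - set(df.columns):
        raise ValueError(f"promoter table {path} needs columns {sorted(need)}")
    out = []
    for r in df.itertuples():
        cons = ()
        if "constituents" in df.columns and isinstance(r.constituents, str) and r.constituents:
            cons = tuple(r.constituents.split(","))
        out.append(PromoterElement(str(r.gene_id), float(r.length_kb), int(r.read_count), cons))
    return out
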