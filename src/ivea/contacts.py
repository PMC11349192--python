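"""Sparse binned chromatin-contact processing and per-pair contact extraction.

Maps are stored as sparse symmetric dictionaries keyed by (bin_i, bin_j) with
i <= j; bins are indices of fixed-size windows (default 5 kb).  Three
corrections mirror the standard activity-by-contact preprocessing: diagonal
entries are replaced by the maximum of their four matrix neighbours,
low-confidence entries (NaN or balancing factor below threshold) are replaced
by a power-law expectation of distance, and a pseudocount keeps every
gene-element contact strictly positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .elements import GeneRecord, RegulatoryElement

__all__ = [
    "BinnedContactMap",
    "PowerLawModel",
    "PseudocountPolicy",
    "GeneEnhancerContacts",
    "fix_diagonal",
    "replace_low_confidence",
    "extract_pair_contacts",
    "read_contact_map",
    "read_pair_contacts",
    "write_pair_contacts",
]

DEFAULT_RESOLUTION = 5000
DEFAULT_WINDOW = 5_000_000
DEFAULT_GAMMA = 0.7
DEFAULT_NORM_THRESHOLD = 0.25
PSEUDOCOUNT_DISTANCE_CAP = 1_000_000


@dataclass(frozen=True)
class PowerLawModel:
    """Expected contact ~ reference_scale * max(distance, d_min)^(-exponent)."""

    exponent: float = DEFAULT_GAMMA
    reference_scale: float = 1.0
    d_min: float = float(DEFAULT_RESOLUTION)

    def __post_init__(self) -> None:
        if self.exponent <= 0 or self.reference_scale <= 0 or self.d_min <= 0:
            raise ValueError("power-law parameters must be positive")

    def expected_contact(self, distance):
        distance = np.asarray(distance, dtype=float)
        if np.any(distance < 0):
            raise ValueError("distance must be non-negative")
        return self.reference_scale * np.maximum(distance, self.d_min) ** (-self.exponent)


def expected_contact(model: PowerLawModel, distance):
    return model.expected_contact(distance)


@dataclass
class BinnedContactMap:
    chrom: str
    resolution: int = DEFAULT_RESOLUTION
    entries: dict = field(default_factory=dict)  # (i, j) with i <= j -> value
    norm_factors: dict | None = None  # bin -> balancing factor

    @staticmethod
    def _key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i <= j else (j, i)

    def get(self, i: int, j: int, default: float = 0.0) -> float:
        return self.entries.get(self._key(i, j), default)

    def set(self, i: int, j: int, value: float) -> None:
        self.entries[self._key(i, j)] = value

    def bin_of(self, position: int) -> int:
        return position // self.resolution


def fix_diagonal(cmap: BinnedContactMap) -> BinnedContactMap:
    """Replace each stored diagonal entry (i, i) by the maximum of its four
    matrix neighbours (i-1,i), (i+1,i), (i,i-1), (i,i+1); by symmetry this is
    max{value(i-1,i), value(i,i+1)}.  Missing neighbours count as absent (0).
    Off-diagonal entries are untouched.
    """
    out = BinnedContactMap(cmap.chrom, cmap.resolution, dict(cmap.entries), cmap.norm_factors)
    for (i, j) in list(cmap.entries):
        if i == j:
            neighbours = [
                v
                for v in (
                    cmap.entries.get(BinnedContactMap._key(i - 1, i)),
                    cmap.entries.get(BinnedContactMap._key(i, i + 1)),
                )
                if v is not None and not np.isnan(v)
            ]
            out.entries[(i, i)] = max(neighbours) if neighbours else 0.0
    return out


def replace_low_confidence(
    cmap: BinnedContactMap,
    model: PowerLawModel,
    threshold: float = DEFAULT_NORM_THRESHOLD,
) -> BinnedContactMap:
    """Replace stored entries that are NaN, or whose row/column bin has a
    balancing factor below ``threshold``, by the power-law expectation at the
    bin distance.  Without norm factors only the NaN criterion applies.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    nf = cmap.norm_factors or {}
    out = BinnedContactMap(cmap.chrom, cmap.resolution, {}, cmap.norm_factors)
    n_replaced = 0
    for (i, j), v in cmap.entries.items():
        low = (
            np.isnan(v)
            or nf.get(i, np.inf) < threshold
            or nf.get(j, np.inf) < threshold
        )
        if low:
            v = float(model.expected_contact((j - i) * cmap.resolution))
            n_replaced += 1
        out.entries[(i, j)] = v
    if n_replaced:
        warnings.warn(f"{cmap.chrom}: replaced {n_replaced} low-confidence entries")
    return out


@dataclass(frozen=True)
class PseudocountPolicy:
    """Additive adjustment keeping every pair contact strictly positive.

    mode 'powerlaw': add expected_contact(min(distance, distance_cap)) under
    ``model``; mode 'constant': add ``value``; mode 'none': add nothing
    (only safe in pure power-law contact mode, where contacts are positive).
    """

    mode: str = "powerlaw"
    value: float = 0.0
    distance_cap: float = float(PSEUDOCOUNT_DISTANCE_CAP)
    model: PowerLawModel = field(default_factory=PowerLawModel)

    def adjustment(self, distance):
        if self.mode == "powerlaw":
            return self.model.expected_contact(np.minimum(distance, self.distance_cap))
        if self.mode == "constant":
            return np.full_like(np.asarray(distance, dtype=float), self.value)
        if self.mode == "none":
            return np.zeros_like(np.asarray(distance, dtype=float))
        raise ValueError(f"unknown pseudocount mode {self.mode!r}")


@dataclass
class GeneEnhancerContacts:
    """Sparse per-pair contact frequencies within the distance window."""

    window: int
    pairs: pd.DataFrame  # columns gene_id, element_id, distance_bp, contact
    pseudocount: PseudocountPolicy = field(default_factory=PseudocountPolicy)

    def __post_init__(self) -> None:
        if len(self.pairs) and (self.pairs["contact"] <= 0).any():
            raise ValueError("all stored contacts must be strictly positive")

    def as_mapping(self) -> dict:
        return {
            (r.gene_id, r.element_id): r.contact for r in self.pairs.itertuples()
        }


def extract_pair_contacts(
    genes: Sequence[GeneRecord],
    elements: Sequence[RegulatoryElement],
    maps: Mapping[str, BinnedContactMap] | None = None,
    model: PowerLawModel | None = None,
    window: int = DEFAULT_WINDOW,
    pseudocount: PseudocountPolicy | None = None,
) -> GeneEnhancerContacts:
    """Contact frequency for every same-chromosome (gene, element) pair with
    |TSS - element midpoint| <= window.

    With ``maps``, the value at (bin(TSS), bin(midpoint)) plus the pseudocount
    is used; genes on chromosomes without a map fall back to the power-law
    model with a warning.  With ``maps=None`` (pure power-law mode) the value
    is ``model.expected_contact(distance)``, positive by construction.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if model is None:
        model = PowerLawModel()
    if pseudocount is None:
        pseudocount = (
            PseudocountPolicy(mode="none", model=model)
            if maps is None
            else PseudocountPolicy(model=model)
        )

    el_by_chrom: dict[str, list[RegulatoryElement]] = {}
    for e in elements:
        el_by_chrom.setdefault(e.chrom, []).append(e)

    missing_chroms: set[str] = set()
    rows: list[tuple[str, str, int, float]] = []
    for g in genes:
        els = el_by_chrom.get(g.chrom, [])
        if not els:
            continue
        mids = np.array([e.midpoint for e in els])
        dists = np.abs(mids - g.tss)
        within = np.flatnonzero(dists <= window)
        if within.size == 0:
            continue
        cmap = None if maps is None else maps.get(g.chrom)
        if maps is not None and cmap is None:
            missing_chroms.add(g.chrom)
        if cmap is None:
            base = model.expected_contact(dists[within].astype(float))
        else:
            tss_bin = cmap.bin_of(g.tss)
            base = np.array(
                [cmap.get(tss_bin, cmap.bin_of(els[i].midpoint)) for i in within],
                dtype=float,
            )
        contact = base + pseudocount.adjustment(dists[within].astype(float))
        for i, c, d in zip(within, contact, dists[within]):
            rows.append((g.gene_id, els[i].element_id, int(d), float(c)))

    if missing_chroms:
        warnings.warn(
            "no contact map for chromosome(s) "
            f"{sorted(missing_chroms)}; used power-law fallback"
        )
    pairs = pd.DataFrame(rows, columns=["gene_id", "element_id", "distance_bp", "contact"])
    return GeneEnhancerContacts(window=window, pairs=pairs, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# File interfaces


def read_contact_map(
    path: str | Path,
    chrom: str,
    resolution: int = DEFAULT_RESOLUTION,
    norm_path: str | Path | None = None,
) -> BinnedContactMap:
    """3-column text 'bin1_start bin2_start value' (bin starts in bp; Juicer
    short-dump dialect) plus an optional one-value-per-line balancing-factor
    file indexed by bin."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["b1", "b2", "value"])
    entries: dict[tuple[int, int], float] = {}
    for r in df.itertuples():
        i, j = int(r.b1) // resolution, int(r.b2) // resolution
        entries[BinnedContactMap._key(i, j)] = float(r.value)
    norm = None
    if norm_path is not None:
        vals = pd.read_csv(norm_path, header=None)[0].astype(float)
        norm = {i: v for i, v in enumerate(vals)}
    return BinnedContactMap(chrom, resolution, entries, norm)


def write_pair_contacts(contacts: GeneEnhancerContacts, path) -> None:
    contacts.pairs.to_csv(path, sep="\t", index=False)


def read_pair_contacts(path, window: int = DEFAULT_WINDOW) -> GeneEnhancerContacts:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "element_id", "distance_bp", "contact"}
    if need - set(df.columns):
        raise ValueError(f"contact table {path} needs columns {sorted(need)}")
    df["gene_id"] = df["gene_id"].astype(str)
    df["element_id"] = df["element_id"].astype(str)
    return GeneEnhancerContacts(window=window, pairs=df)
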