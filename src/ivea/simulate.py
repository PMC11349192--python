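"""Synthetic datasets drawn from the generative model with known latents.

Genes are laid out along synthetic chromosomes; each gene receives one
promoter-region element (which, as in the real pipeline, also acts as an
enhancer) and the remaining elements are distal.  Latent activities are drawn
from the model priors, contacts from a power-law of distance (with lognormal
dispersion) or a random sparse pattern, and counts from the Poisson
observation model.  All emitted files use the dialects of the loaders in
:mod:`ivea.elements`, :mod:`ivea.contacts` and :mod:`ivea.engine`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import DEFAULT_WINDOW, PowerLawModel
from .engine import Hyperparameters

__all__ = ["SimulationConfig", "GroundTruth", "SimulatedDataset",
           "sample_dataset", "make_fixture", "draw_counts"]

FIXTURES = ("tiny", "medium", "degenerate")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 20
    n_elements: int = 60  # total, including one promoter element per gene
    seed: int = 0
    chrom: str = "chrS"
    gene_spacing: int = 150_000
    element_min_bp: int = 300
    element_max_bp: int = 1500
    window: int = DEFAULT_WINDOW
    contact_mode: str = "powerlaw"  # or "random-sparse"
    contact_noise_sigma: float = 0.25
    sparse_keep_prob: float = 0.5  # random-sparse mode only
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    powerlaw: PowerLawModel = field(default_factory=PowerLawModel)
    target_mean_t: float | None = 2000.0  # rescales k; None keeps the raw draw
    fix_latents_to_prior_means: bool = False
    mean_lT_kb: float = 2.0
    burst_size_range: tuple = (0.5, 2.0)  # log-uniform

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_elements < 1:
            raise ValueError("n_genes and n_elements must be >= 1")
        if self.n_elements < self.n_genes:
            raise ValueError("need at least one element per gene (promoters)")
        if self.contact_mode not in ("powerlaw", "random-sparse"):
            raise ValueError(f"unknown contact mode {self.contact_mode!r}")


@dataclass
class GroundTruth:
    gene_ids: np.ndarray
    element_ids: np.ndarray
    v: np.ndarray
    oP: np.ndarray
    y: np.ndarray
    w: np.ndarray
    oE: np.ndarray
    k: float
    pairs: pd.DataFrame  # gene_id, element_id, contact, h


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: pd.DataFrame        # annotation dialect
    expression: pd.DataFrame   # gene_id, count, effective_length (nt)
    burst_sizes: pd.DataFrame  # gene_id, burst_size
    peaks: pd.DataFrame        # narrowPeak rows
    elements: pd.DataFrame     # sidecar element dialect
    promoters: pd.DataFrame    # gene_id, length_kb, read_count, constituents
    contacts: pd.DataFrame     # gene_id, element_id, distance_bp, contact
    truth: GroundTruth

    def gene_records(self):
        from .elements import GeneRecord

        return [
            GeneRecord(str(r.gene_id), str(r.symbol), str(r.chrom), str(r.strand),
                       int(r.tss), int(r.start), int(r.end))
            for r in self.genes.itertuples()
        ]

    def element_records(self):
        from .elements import RegulatoryElement

        return [
            RegulatoryElement(str(r.element_id), str(r.chrom), int(r.start),
                              int(r.end), int(r.read_count))
            for r in self.elements.itertuples()
        ]

    def promoter_records(self):
        from .elements import PromoterElement

        return [
            PromoterElement(str(r.gene_id), float(r.length_kb), int(r.read_count),
                            (str(r.constituents),))
            for r in self.promoters.itertuples()
        ]

    def expression_records(self):
        from .elements import ExpressionRecord, compute_tpm

        return compute_tpm(
            ExpressionRecord(str(r.gene_id), int(r.count), float(r.effective_length) / 1000.0)
            for r in self.expression.itertuples()
        )

    def contact_records(self):
        from .contacts import GeneEnhancerContacts

        return GeneEnhancerContacts(window=self.config.window, pairs=self.contacts.copy())

    def to_inference_input(self, cutoff_tpm: float = -1.0):
        """Assemble the engine input bundle; the default cutoff keeps every
        gene (including zero-count ones) for engine-level testing."""
        from .pipeline import assemble_inference_input

        burst = {str(r.gene_id): float(r.burst_size) for r in self.burst_sizes.itertuples()}
        inp, _ = assemble_inference_input(
            self.gene_records(), self.promoter_records(), self.expression_records(),
            self.element_records(), self.contact_records(),
            burst_sizes=burst, cutoff_tpm=cutoff_tpm,
        )
        return inp


def draw_counts(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Poisson observation draw used for t, xP and xE."""
    return rng.poisson(np.asarray(lam, dtype=float))


def sample_dataset(config: SimulationConfig) -> SimulatedDataset:
    rng = np.random.default_rng(config.seed)
    h = config.hyper
    n_g, n_r = config.n_genes, config.n_elements

    # --- layout: one promoter element per gene + distal elements ----------
    tss = (np.arange(n_g) + 1) * config.gene_spacing + rng.integers(
        0, config.gene_spacing // 3, n_g
    )
    widths = rng.integers(config.element_min_bp, config.element_max_bp + 1, n_r)
    starts = np.empty(n_r, dtype=int)
    starts[:n_g] = tss - widths[:n_g] // 2  # promoter elements straddle the TSS
    span = (n_g + 1) * config.gene_spacing
    starts[n_g:] = np.sort(rng.integers(1, span, n_r - n_g))
    ends = starts + widths
    # avoid coincident distal elements colliding with ids
    element_ids = np.array(
        [f"{config.chrom}:{s}-{e}" for s, e in zip(starts, ends)], dtype=object
    )
    if len(set(element_ids)) != n_r:
        keep, seen = [], set()
        for i, eid in enumerate(element_ids):
            while eid in seen:
                starts[i] += 7
                ends[i] += 7
                eid = f"{config.chrom}:{starts[i]}-{ends[i]}"
            element_ids[i] = eid
            seen.add(eid)
    mids = (starts + ends) // 2
    lE = widths / 1000.0

    gene_ids = np.array([f"G{i:04d}" for i in range(n_g)], dtype=object)
    strand = rng.choice(["+", "-"], n_g)
    lT = rng.lognormal(np.log(config.mean_lT_kb), 0.4, n_g)  # kb
    lo, hi = config.burst_size_range
    s_burst = np.exp(rng.uniform(np.log(lo), np.log(hi), n_g))
    lP = lE[:n_g]
    xP_rate_len = lP

    # --- latents ----------------------------------------------------------
    if config.fix_latents_to_prior_means:
        oP = np.full(n_g, h.alpha_o / h.beta_o)
        oE = np.full(n_r, h.alpha_o / h.beta_o)
        v = s_burst * oP
        w = lE * oE
        k = h.alpha_k / h.beta_k
    else:
        oP = rng.gamma(h.alpha_o, 1.0 / h.beta_o, n_g)
        oE = rng.gamma(h.alpha_o, 1.0 / h.beta_o, n_r)
        # guard against near-zero openness producing degenerate rates
        oP = np.maximum(oP, 1e-6)
        oE = np.maximum(oE, 1e-6)
        v = rng.gamma(h.alpha_v, (s_burst * oP) / h.alpha_v, n_g)
        w = rng.gamma(h.alpha_w, (lE * oE) / h.alpha_w, n_r)
        k = rng.gamma(h.alpha_k, 1.0 / h.beta_k)

    # --- contacts ---------------------------------------------------------
    rows = []
    for gi in range(n_g):
        d = np.abs(mids - tss[gi])
        within = np.flatnonzero(d <= config.window)
        c = config.powerlaw.expected_contact(d[within].astype(float))
        if config.contact_mode == "powerlaw":
            if config.contact_noise_sigma > 0:
                c = c * rng.lognormal(0.0, config.contact_noise_sigma, len(c))
        else:
            keep = rng.random(len(within)) < config.sparse_keep_prob
            keep[np.flatnonzero(within == gi)] = True  # keep own promoter
            within, c = within[keep], rng.lognormal(np.log(np.maximum(c[keep], 1e-12)), 1.0)
        for ri, cv in zip(within, c):
            rows.append((gi, ri, int(np.abs(mids[ri] - tss[gi])), float(cv)))
    pair_df = pd.DataFrame(rows, columns=["gi", "ri", "distance_bp", "contact"])

    cw = np.zeros(n_g)
    np.add.at(cw, pair_df["gi"].to_numpy(), pair_df["contact"].to_numpy() * w[pair_df["ri"].to_numpy()])
    if config.target_mean_t is not None:
        k = k * config.target_mean_t / float(np.mean(lT * k * v * cw))
    y = k * v * cw

    # --- observations -----------------------------------------------------
    t = draw_counts(rng, lT * y)
    xP = draw_counts(rng, xP_rate_len * oP)
    xE = draw_counts(rng, lE * oE)

    # --- ground-truth pair table -----------------------------------------
    gsum = np.zeros(n_g)
    contact_w = pair_df["contact"].to_numpy() * w[pair_df["ri"].to_numpy()]
    np.add.at(gsum, pair_df["gi"].to_numpy(), contact_w)
    truth_pairs = pd.DataFrame(
        {
            "gene_id": gene_ids[pair_df["gi"].to_numpy()],
            "element_id": element_ids[pair_df["ri"].to_numpy()],
            "contact": pair_df["contact"].to_numpy(),
            "h": contact_w / gsum[pair_df["gi"].to_numpy()],
        }
    )

    body_start = np.minimum(tss - 500, starts[:n_g]) - 1
    body_end = np.maximum(tss + 5000, ends[:n_g]) + 1
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": [f"SYM{i}" for i in range(n_g)],
            "chrom": config.chrom,
            "strand": strand,
            "tss": tss,
            "start": body_start,
            "end": body_end,
        }
    )
    expression = pd.DataFrame(
        {"gene_id": gene_ids, "count": t, "effective_length": np.round(lT * 1000).astype(int)}
    )
    burst = pd.DataFrame({"gene_id": gene_ids, "burst_size": s_burst})
    peaks = pd.DataFrame(
        {
            0: config.chrom, 1: starts, 2: ends,
            3: [f"peak{i}" for i in range(n_r)],
            4: 0, 5: ".", 6: xE, 7: -1.0, 8: -1.0, 9: widths // 2,
        }
    )
    elements = pd.DataFrame(
        {
            "element_id": element_ids, "chrom": config.chrom,
            "start": starts, "end": ends, "read_count": xE, "length_kb": lE,
        }
    )
    promoters = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length_kb": lP,
            "read_count": xP,
            "constituents": element_ids[:n_g],
        }
    )
    contacts = pd.DataFrame(
        {
            "gene_id": gene_ids[pair_df["gi"].to_numpy()],
            "element_id": element_ids[pair_df["ri"].to_numpy()],
            "distance_bp": pair_df["distance_bp"].to_numpy(),
            "contact": pair_df["contact"].to_numpy(),
        }
    )
    truth = GroundTruth(
        gene_ids=gene_ids, element_ids=element_ids, v=v, oP=oP, y=y,
        w=w, oE=oE, k=float(k), pairs=truth_pairs,
    )
    return SimulatedDataset(
        config=config, genes=genes, expression=expression, burst_sizes=burst,
        peaks=peaks, elements=elements, promoters=promoters, contacts=contacts,
        truth=truth,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    ds.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    ds.burst_sizes.to_csv(outdir / "burst_size.tsv", sep="\t", index=False)
    ds.peaks.to_csv(outdir / "peaks.narrowPeak", sep="\t", header=False, index=False)
    ds.elements.to_csv(outdir / "elements.tsv", sep="\t", index=False)
    ds.promoters.to_csv(outdir / "promoters.tsv", sep="\t", index=False)
    ds.contacts.to_csv(outdir / "contacts.tsv", sep="\t", index=False)
    t = ds.truth
    pd.DataFrame(
        {"gene_id": t.gene_ids, "v": t.v, "oP": t.oP, "y": t.y}
    ).to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"element_id": t.element_ids, "w": t.w, "oE": t.oE}
    ).to_csv(outdir / "truth_elements.tsv", sep="\t", index=False)
    t.pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
    manifest = {
        "k": t.k,
        "seed": ds.config.seed,
        "n_genes": ds.config.n_genes,
        "n_elements": ds.config.n_elements,
        "contact_mode": ds.config.contact_mode,
        "hyperparameters": ds.config.hyper.to_dict(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


def make_fixture(name: str, seed: int = 1) -> SimulatedDataset:
    """Named datasets used across the test suite.

    tiny: 3 genes x 5 elements with hand-checkable numbers.
    medium: 200 genes x 600 elements for parameter-recovery runs.
    degenerate: contains a zero-count gene, an element contacted by no gene,
    and a gene whose only contact is its own promoter element.
    """
    if name == "tiny":
        return sample_dataset(
            SimulationConfig(n_genes=3, n_elements=5, seed=seed, gene_spacing=50_000)
        )
    if name == "medium":
        return sample_dataset(
            SimulationConfig(
                n_genes=200, n_elements=600, seed=seed, gene_spacing=60_000,
                window=2_000_000,
            )
        )
    if name == "degenerate":
        ds = sample_dataset(
            SimulationConfig(n_genes=6, n_elements=14, seed=seed, gene_spacing=50_000)
        )
        # zero-count gene: observed RNA-seq count forced to 0
        ds.expression.loc[0, "count"] = 0
        # single-enhancer gene: keep only the promoter self-pair for gene 1
        g1 = ds.genes.loc[1, "gene_id"]
        own = ds.promoters.loc[1, "constituents"]
        drop = (ds.contacts["gene_id"] == g1) & (ds.contacts["element_id"] != own)
        ds.contacts.drop(index=ds.contacts.index[drop], inplace=True)
        ds.contacts.reset_index(drop=True, inplace=True)
        # uncontacted element: a distal element no gene touches
        orphan = "chrOrphan:1000-1600"
        ds.elements.loc[len(ds.elements)] = [orphan, "chrOrphan", 1000, 1600, 5, 0.6]
        ds.peaks.loc[len(ds.peaks)] = ["chrOrphan", 1000, 1600, "orphan", 0, ".", 5, -1.0, -1.0, 300]
        return ds
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURES}")
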