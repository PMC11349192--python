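"""Assembly of observed tables into the array bundle consumed by the engine.

Gene filtering applied here, in order: genes must have a promoter element,
expression strictly above the TPM cutoff, and at least one contact pair.
Ablation switches that rewrite the observed arrays (flat accessibility /
flat expression) also live here.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .contacts import GeneEnhancerContacts
from .elements import (
    DEFAULT_TPM_CUTOFF,
    ExpressionRecord,
    GeneRecord,
    PromoterElement,
    RegulatoryElement,
    compute_tpm,
)
from .engine import InferenceInput

__all__ = ["assemble_inference_input", "apply_flat_ablation"]

logger = logging.getLogger(__name__)


def assemble_inference_input(
    genes: Sequence[GeneRecord],
    promoters: Sequence[PromoterElement],
    expression: Sequence[ExpressionRecord],
    elements: Sequence[RegulatoryElement],
    contacts: GeneEnhancerContacts,
    burst_sizes: Mapping[str, float] | None = None,
    cutoff_tpm: float = DEFAULT_TPM_CUTOFF,
) -> tuple[InferenceInput, dict]:
    """Build the observed-array bundle, returning it with a filtering report."""
    expression = list(expression)
    if any(np.isnan(e.tpm) for e in expression):
        expression = compute_tpm(expression)
    expr_by_gene = {e.gene_id: e for e in expression}
    prom_by_gene = {p.gene_id: p for p in promoters}
    if len(prom_by_gene) != len(list(promoters)):
        raise ValueError("duplicate gene_id in promoter table")

    pair_genes = set(contacts.pairs["gene_id"])
    report = {"no_promoter": [], "below_cutoff": [], "no_expression": [], "no_contacts": []}
    kept: list[GeneRecord] = []
    for g in genes:
        if g.gene_id not in prom_by_gene:
            report["no_promoter"].append(g.gene_id)
        elif g.gene_id not in expr_by_gene:
            report["no_expression"].append(g.gene_id)
        elif not expr_by_gene[g.gene_id].tpm > cutoff_tpm:
            report["below_cutoff"].append(g.gene_id)
        elif g.gene_id not in pair_genes:
            report["no_contacts"].append(g.gene_id)
        else:
            kept.append(g)
    if not kept:
        raise ValueError("no genes left after filtering")
    for key, ids in report.items():
        if ids:
            logger.info("excluded %d genes (%s)", len(ids), key)

    gene_ids = np.array([g.gene_id for g in kept], dtype=object)
    element_ids = np.array([e.element_id for e in elements], dtype=object)
    g_index = {g: i for i, g in enumerate(gene_ids)}
    r_index = {r: i for i, r in enumerate(element_ids)}

    pairs = contacts.pairs[contacts.pairs["gene_id"].isin(g_index)]
    unknown = set(pairs["element_id"]) - set(r_index)
    if unknown:
        raise ValueError(f"contact table references unknown elements: {sorted(unknown)[:5]}")
    C = sparse.csr_matrix(
        (
            pairs["contact"].to_numpy(float),
            (
                pairs["gene_id"].map(g_index).to_numpy(),
                pairs["element_id"].map(r_index).to_numpy(),
            ),
        ),
        shape=(len(gene_ids), len(element_ids)),
    )

    if burst_sizes is None:
        burst_sizes = {}
    default_s = burst_sizes.get("__default__", 1.0)
    inp = InferenceInput(
        gene_ids=gene_ids,
        element_ids=element_ids,
        t=np.array([expr_by_gene[g].read_count for g in gene_ids], dtype=int),
        lT=np.array([expr_by_gene[g].effective_length_kb for g in gene_ids]),
        s=np.array([burst_sizes.get(g, default_s) for g in gene_ids]),
        xP=np.array([prom_by_gene[g].read_count for g in gene_ids], dtype=int),
        lP=np.array([prom_by_gene[g].length_kb for g in gene_ids]),
        xE=np.array([e.read_count for e in elements], dtype=int),
        lE=np.array([e.length_kb for e in elements]),
        C=C,
    )
    return inp, report


def apply_flat_ablation(
    inp: InferenceInput, flat_dhs: float | None = None, flat_rna: float | None = None
) -> InferenceInput:
    """Replace accessibility counts (promoter and element) and/or RNA-seq
    counts with a flat value, as in the input-perturbation ablations."""
    from dataclasses import replace as _replace

    kwargs = {}
    if flat_dhs is not None:
        kwargs["xP"] = np.full_like(inp.xP, int(flat_dhs))
        kwargs["xE"] = np.full_like(inp.xE, int(flat_dhs))
    if flat_rna is not None:
        kwargs["t"] = np.full_like(inp.t, int(flat_rna))
    if not kwargs:
        return inp
    return _replace(inp, **kwargs)
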