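"""Interaction scores and ranked predictions from a converged inference state.

The score of pair (g, r) is the relative contribution of element r to the
modelled expression of gene g:

    h_gr = c_gr w_r* / sum_r' c_gr' w_r'*        (w_r* = E_q[w_r])

The promoter-activity point estimate v_g* cancels in the ratio but is carried
in the output for interpretation.  Scores are emitted only for the contact
support, so each gene's scores sum to one.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import GeneEnhancerContacts
from .elements import GeneRecord, RegulatoryElement

__all__ = [
    "interaction_scores",
    "top_pairs_per_gene",
    "evaluate_labelled_pairs",
    "write_predictions",
    "write_bedpe",
]

PREDICTION_COLUMNS = [
    "chrom", "start", "end", "element_id", "gene_id", "tss", "distance_bp",
    "contact", "enhancer_activity", "promoter_activity", "score",
]


def interaction_scores(
    w_mean: Mapping[str, float],
    v_mean: Mapping[str, float],
    contacts: GeneEnhancerContacts,
    genes: Sequence[GeneRecord] | None = None,
    elements: Sequence[RegulatoryElement] | None = None,
) -> pd.DataFrame:
    """One scored record per stored contact pair; genes absent from the
    posterior are skipped with a warning."""
    df = contacts.pairs.copy()
    known = df["gene_id"].isin(v_mean.keys())
    if not known.all():
        warnings.warn(
            f"skipping {(~known).sum()} pairs for genes absent from the posterior"
        )
        df = df[known].copy()
    df["enhancer_activity"] = df["element_id"].map(w_mean).astype(float)
    if df["enhancer_activity"].isna().any():
        missing = df.loc[df["enhancer_activity"].isna(), "element_id"].unique()
        raise KeyError(f"elements missing from posterior: {list(missing[:5])}")
    df["promoter_activity"] = df["gene_id"].map(v_mean).astype(float)
    weight = df["contact"].to_numpy() * df["enhancer_activity"].to_numpy()
    totals = df.assign(_w=weight).groupby("gene_id")["_w"].transform("sum")
    df["score"] = weight / totals.to_numpy()

    gene_info = {g.gene_id: g for g in genes or ()}
    el_info = {e.element_id: e for e in elements or ()}
    df["tss"] = df["gene_id"].map(lambda g: gene_info[g].tss if g in gene_info else -1)
    df["chrom"] = df["element_id"].map(
        lambda r: el_info[r].chrom if r in el_info else "."
    )
    df["start"] = df["element_id"].map(
        lambda r: el_info[r].start if r in el_info else -1
    )
    df["end"] = df["element_id"].map(lambda r: el_info[r].end if r in el_info else -1)
    df = df[PREDICTION_COLUMNS]
    return df.sort_values(
        ["gene_id", "score", "distance_bp", "element_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def top_pairs_per_gene(pairs: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """The n highest-scoring pairs per gene; ties broken by (distance asc,
    element_id) for a deterministic cut."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = pairs.sort_values(
        ["gene_id", "score", "distance_bp", "element_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.groupby("gene_id", sort=True).head(n).reset_index(drop=True)


def evaluate_labelled_pairs(pairs: pd.DataFrame, labels) -> dict:
    """Area under the precision-recall curve over labelled pairs ranked by
    score.

    ``labels`` maps (gene_id, (chrom, start, end)) to True/False; a predicted
    pair inherits the label of any same-gene interval it overlaps by >= 1 bp.
    Unlabelled pairs are ignored.
    """
    from sklearn.metrics import average_precision_score, precision_recall_curve

    by_gene: dict[str, list] = {}
    for (gene_id, interval), positive in labels.items():
        chrom, start, end = interval
        by_gene.setdefault(str(gene_id), []).append((str(chrom), int(start), int(end), bool(positive)))

    y_true, y_score = [], []
    for r in pairs.itertuples():
        for chrom, start, end, positive in by_gene.get(str(r.gene_id), ()):
            if r.chrom == chrom and r.start < end and r.end > start:
                y_true.append(positive)
                y_score.append(r.score)
                break
    if not any(y_true):
        raise ValueError("no positive labelled pairs matched the predictions")
    precision, recall, _ = precision_recall_curve(y_true, y_score)
    return {
        "auprc": float(average_precision_score(y_true, y_score)),
        "n_matched": len(y_true),
        "n_positive": int(sum(y_true)),
        "precision": precision.tolist(),
        "recall": recall.tolist(),
    }


def write_predictions(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def write_bedpe(pairs: pd.DataFrame, path: str | Path) -> None:
    """Element interval <-> zero-length TSS interval, score in column 8."""
    bedpe = pd.DataFrame(
        {
            "chrom1": pairs["chrom"], "start1": pairs["start"], "end1": pairs["end"],
            "chrom2": pairs["chrom"], "start2": pairs["tss"], "end2": pairs["tss"],
            "name": pairs["element_id"] + "::" + pairs["gene_id"],
            "score": pairs["score"],
        }
    )
    bedpe.to_csv(path, sep="\t", header=False, index=False)
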