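"""Mean-field variational inference for the gamma-Poisson activity model.

Observed data per gene g: RNA-seq count t_g with effective transcript length
lT_g (kb), promoter accessibility count xP_g with length lP_g (kb), and a
sequence-based burst size s_g.  Per element r: accessibility count xE_r with
length lE_r (kb).  Contacts c_gr couple genes to elements.

Generative model (shape/rate parameterization of the gamma):

    t_g  ~ Poisson(lT_g * y_g),     y_g = k * v_g * sum_r c_gr w_r
    xP_g ~ Poisson(lP_g * oP_g)     xE_r ~ Poisson(lE_r * oE_r)
    v_g  ~ Gamma(a_v, a_v / (s_g * oP_g))
    w_r  ~ Gamma(a_w, a_w / (lE_r * oE_r))
    oP_g, oE_r ~ Gamma(a_o, b_o),   k ~ Gamma(a_k, b_k)

The factorized posterior has gamma factors for v, w, k and generalized
inverse Gaussian factors for the openness variables.  The intractable
E[ln sum_r c_gr w_r] in the bound is handled with a per-gene auxiliary
probability vector rho (Jensen on the log), re-optimized each sweep.

Variants: ``no_sg`` drops s_g from the promoter-activity prior (s_g -> 1);
``no_lE`` drops lE_r from the enhancer-activity prior only — the
accessibility observation model keeps the true lE_r.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, special

from .gig import GIGQ, gig_entropy, gig_expectations

__all__ = [
    "Hyperparameters",
    "GammaQ",
    "InferenceInput",
    "InferenceState",
    "gamma_expectations",
    "update_rho",
    "update_q_v",
    "update_q_w",
    "update_q_oP",
    "update_q_oE",
    "update_q_k",
    "compute_elbo",
    "run_inference",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL = 5e-3
DEFAULT_MAX_ITER = 500
VARIANTS = ("standard", "no_lE", "no_sg")


@dataclass(frozen=True)
class Hyperparameters:
    """Prior hyperparameters; defaults follow the tuned shape values
    alpha_v=80, alpha_w=10 with weakly informative openness/scale priors."""

    alpha_v: float = 80.0
    alpha_w: float = 10.0
    alpha_o: float = 1.0
    beta_o: float = 1e-3
    alpha_k: float = 1.0
    beta_k: float = 1e-3
    variant: str = "standard"

    def __post_init__(self) -> None:
        for name in ("alpha_v", "alpha_w", "alpha_o", "beta_o", "alpha_k", "beta_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    def to_dict(self) -> dict:
        return {
            "alpha_v": self.alpha_v, "alpha_w": self.alpha_w,
            "alpha_o": self.alpha_o, "beta_o": self.beta_o,
            "alpha_k": self.alpha_k, "beta_k": self.beta_k,
            "variant": self.variant,
        }


@dataclass(frozen=True)
class GammaQ:
    """Gamma factor(s) with shape ``a`` and rate ``b`` (arrays or scalars)."""

    a: np.ndarray
    b: np.ndarray


def gamma_expectations(q: GammaQ) -> dict:
    """mean = a/b and mean_log = digamma(a) - ln b of a gamma factor."""
    a = np.asarray(q.a, dtype=float)
    b = np.asarray(q.b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("gamma parameters must be strictly positive")
    return {"mean": a / b, "mean_log": special.digamma(a) - np.log(b)}


def _gamma_entropy(q: GammaQ) -> np.ndarray:
    a = np.asarray(q.a, dtype=float)
    b = np.asarray(q.b, dtype=float)
    return a - np.log(b) + special.gammaln(a) + (1.0 - a) * special.digamma(a)


@dataclass
class InferenceInput:
    """Observed arrays; genes and elements are indexed positionally, contacts
    are a genes x elements CSR matrix whose explicit entries define the pair
    support (all explicit values strictly positive)."""

    gene_ids: np.ndarray
    element_ids: np.ndarray
    t: np.ndarray
    lT: np.ndarray
    s: np.ndarray
    xP: np.ndarray
    lP: np.ndarray
    xE: np.ndarray
    lE: np.ndarray
    C: sparse.csr_matrix

    def __post_init__(self) -> None:
        self.C = sparse.csr_matrix(self.C)
        self.C.sort_indices()
        n_g, n_r = len(self.gene_ids), len(self.element_ids)
        if self.C.shape != (n_g, n_r):
            raise ValueError("contact matrix shape does not match gene/element counts")
        for name in ("lT", "s", "lP", "lE"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        for name in ("t", "xP", "xE"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any(self.C.data <= 0):
            raise ValueError("explicit contact entries must be strictly positive")
        if np.any(np.diff(self.C.indptr) == 0):
            empty = self.gene_ids[np.flatnonzero(np.diff(self.C.indptr) == 0)]
            raise ValueError(f"gene(s) with empty contact row: {list(empty[:5])}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_elements(self) -> int:
        return len(self.element_ids)

    def row_index(self) -> np.ndarray:
        """Gene index of each explicit contact entry (CSR order)."""
        return np.repeat(
            np.arange(self.n_genes), np.diff(self.C.indptr)
        )


@dataclass
class InferenceState:
    qv: GammaQ = None
    qw: GammaQ = None
    qoP: GIGQ = None
    qoE: GIGQ = None
    qk: GammaQ = None
    rho: np.ndarray = None  # aligned with C.data
    expect: dict = field(default_factory=dict)
    elbo_trace: list = field(default_factory=list)
    delta_trace: list = field(default_factory=list)
    iteration: int = 0
    converged: bool = False

    # -- read-only derived quantities -------------------------------------
    def burst_frequency(self, inp: InferenceInput) -> np.ndarray:
        """Per-gene sum_r c_gr E[w_r] (proportional to burst frequency)."""
        return inp.C @ self.expect["w"]

    def burst_size(self) -> np.ndarray:
        """Per-gene E[v_g] (proportional to burst size)."""
        return self.expect["v"]

    def expression(self, inp: InferenceInput) -> np.ndarray:
        """Posterior-mean latent expression E[k] E[v_g] sum_r c_gr E[w_r]."""
        return self.expect["k"] * self.expect["v"] * self.burst_frequency(inp)


def _effective_s(inp: InferenceInput, hyper: Hyperparameters) -> np.ndarray:
    return np.ones_like(inp.s) if hyper.variant == "no_sg" else inp.s


def _effective_lE(inp: InferenceInput, hyper: Hyperparameters) -> np.ndarray:
    return np.ones_like(inp.lE) if hyper.variant == "no_lE" else inp.lE


def initialize_state(inp: InferenceInput, hyper: Hyperparameters) -> InferenceState:
    """Moment-matched deterministic warm start: openness at its posterior-mean
    scale given counts, activities at their prior means, k from the expression
    balance.  The first action of a sweep is the rho update."""
    s = _effective_s(inp, hyper)
    lE_prior = _effective_lE(inp, hyper)
    e_oP = (inp.xP + hyper.alpha_o) / (inp.lP + hyper.beta_o)
    e_oE = (inp.xE + hyper.alpha_o) / (inp.lE + hyper.beta_o)
    e_v = s * e_oP
    e_w = lE_prior * e_oE
    cw = inp.C @ e_w
    e_k = inp.t.sum() / np.sum(inp.lT * e_v * cw)
    expect = {
        "oP": e_oP, "inv_oP": 1.0 / e_oP,
        "oE": e_oE, "inv_oE": 1.0 / e_oE,
        "v": e_v, "ln_v": np.log(e_v),
        "w": e_w, "ln_w": np.log(e_w),
        "k": e_k, "ln_k": np.log(e_k),
    }
    return InferenceState(expect=expect)


def update_rho(state: InferenceState, inp: InferenceInput) -> InferenceState:
    """rho_r(g) ∝ c_gr exp(E[ln w_r]) normalized over each gene's support,
    computed with a row-wise log-sum-exp."""
    log_num = np.log(inp.C.data) + state.expect["ln_w"][inp.C.indices]
    starts = inp.C.indptr[:-1]
    row = inp.row_index()
    row_max = np.maximum.reduceat(log_num, starts)
    shifted = np.exp(log_num - row_max[row])
    row_sum = np.add.reduceat(shifted, starts)
    state.rho = shifted / row_sum[row]
    return state


def update_q_w(state: InferenceState, inp: InferenceInput, hyper: Hyperparameters) -> InferenceState:
    row = inp.row_index()
    a = hyper.alpha_w + np.bincount(
        inp.C.indices, weights=inp.t[row] * state.rho, minlength=inp.n_elements
    )
    lE_prior = _effective_lE(inp, hyper)
    cross = inp.C.T @ (inp.lT * state.expect["v"])
    b = (hyper.alpha_w / lE_prior) * state.expect["inv_oE"] + state.expect["k"] * cross
    state.qw = GammaQ(a, b)
    e = gamma_expectations(state.qw)
    state.expect["w"], state.expect["ln_w"] = e["mean"], e["mean_log"]
    return state


def update_q_v(state: InferenceState, inp: InferenceInput, hyper: Hyperparameters) -> InferenceState:
    s = _effective_s(inp, hyper)
    a = hyper.alpha_v + inp.t
    b = (hyper.alpha_v / s) * state.expect["inv_oP"] + inp.lT * state.expect["k"] * (
        inp.C @ state.expect["w"]
    )
    state.qv = GammaQ(a, b)
    e = gamma_expectations(state.qv)
    state.expect["v"], state.expect["ln_v"] = e["mean"], e["mean_log"]
    return state


def update_q_oE(state: InferenceState, inp: InferenceInput, hyper: Hyperparameters) -> InferenceState:
    lE_prior = _effective_lE(inp, hyper)
    lam = hyper.alpha_o - hyper.alpha_w + inp.xE
    chi = 2.0 * hyper.alpha_w * state.expect["w"] / lE_prior
    psi = 2.0 * hyper.beta_o + 2.0 * inp.lE
    state.qoE = GIGQ(lam, chi, psi)
    e = gig_expectations(lam, chi, psi)
    state.expect["oE"], state.expect["inv_oE"] = e["mean"], e["inv_mean"]
    state.expect["ln_oE"] = e["mean_log"]
    return state


def update_q_oP(state: InferenceState, inp: InferenceInput, hyper: Hyperparameters) -> InferenceState:
    s = _effective_s(inp, hyper)
    lam = hyper.alpha_o - hyper.alpha_v + inp.xP
    chi = 2.0 * hyper.alpha_v * state.expect["v"] / s
    psi = 2.0 * hyper.beta_o + 2.0 * inp.lP
    state.qoP = GIGQ(lam, chi, psi)
    e = gig_expectations(lam, chi, psi)
    state.expect["oP"], state.expect["inv_oP"] = e["mean"], e["inv_mean"]
    state.expect["ln_oP"] = e["mean_log"]
    return state


def update_q_k(state: InferenceState, inp: InferenceInput, hyper: Hyperparameters) -> InferenceState:
    a = hyper.alpha_k + inp.t.sum()
    b = hyper.beta_k + np.sum(inp.lT * state.expect["v"] * (inp.C @ state.expect["w"]))
    state.qk = GammaQ(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    e = gamma_expectations(state.qk)
    state.expect["k"], state.expect["ln_k"] = float(e["mean"]), float(e["mean_log"])
    return state


def compute_elbo(state: InferenceState, inp: InferenceInput, hyper: Hyperparameters) -> float:
    """Evidence lower bound with the Jensen (rho) surrogate for
    E[ln sum_r c_gr w_r].  Additive constants that do not depend on q —
    the Poisson ln-factorial terms ln t_g!, ln xP_g!, ln xE_r! — are omitted.
    """
    if state.qv is None or state.rho is None:
        raise ValueError("compute_elbo requires a fully updated state")
    ex = state.expect
    s = _effective_s(inp, hyper)
    lE_prior = _effective_lE(inp, hyper)
    av, aw, ao, bo, ak, bk = (
        hyper.alpha_v, hyper.alpha_w, hyper.alpha_o,
        hyper.beta_o, hyper.alpha_k, hyper.beta_k,
    )

    row = inp.row_index()
    starts = inp.C.indptr[:-1]
    # per-gene Jensen bound on E[ln sum c w]
    contrib = state.rho * (np.log(inp.C.data) + ex["ln_w"][inp.C.indices])
    entropy_rho = -state.rho * np.log(state.rho)
    ln_sum_cw = np.add.reduceat(contrib + entropy_rho, starts)
    cw = inp.C @ ex["w"]

    terms = {}
    terms["lik_t"] = np.sum(
        inp.t * (np.log(inp.lT) + ex["ln_k"] + ex["ln_v"] + ln_sum_cw)
        - inp.lT * ex["k"] * ex["v"] * cw
    )
    terms["lik_xP"] = np.sum(inp.xP * (np.log(inp.lP) + ex["ln_oP"]) - inp.lP * ex["oP"])
    terms["lik_xE"] = np.sum(inp.xE * (np.log(inp.lE) + ex["ln_oE"]) - inp.lE * ex["oE"])
    terms["prior_v"] = np.sum(
        av * np.log(av / s)
        - special.gammaln(av)
        - av * ex["ln_oP"]
        + (av - 1.0) * ex["ln_v"]
        - (av / s) * ex["inv_oP"] * ex["v"]
    )
    terms["prior_w"] = np.sum(
        aw * np.log(aw / lE_prior)
        - special.gammaln(aw)
        - aw * ex["ln_oE"]
        + (aw - 1.0) * ex["ln_w"]
        - (aw / lE_prior) * ex["inv_oE"] * ex["w"]
    )
    terms["prior_oP"] = np.sum(
        ao * np.log(bo) - special.gammaln(ao) + (ao - 1.0) * ex["ln_oP"] - bo * ex["oP"]
    )
    terms["prior_oE"] = np.sum(
        ao * np.log(bo) - special.gammaln(ao) + (ao - 1.0) * ex["ln_oE"] - bo * ex["oE"]
    )
    terms["prior_k"] = (
        ak * np.log(bk) - special.gammaln(ak) + (ak - 1.0) * ex["ln_k"] - bk * ex["k"]
    )
    terms["entropy_v"] = np.sum(_gamma_entropy(state.qv))
    terms["entropy_w"] = np.sum(_gamma_entropy(state.qw))
    terms["entropy_k"] = float(np.sum(_gamma_entropy(state.qk)))
    terms["entropy_oP"] = np.sum(
        gig_entropy(
            state.qoP.lam, state.qoP.chi, state.qoP.psi,
            {"mean": ex["oP"], "inv_mean": ex["inv_oP"], "mean_log": ex["ln_oP"]},
        )
    )
    terms["entropy_oE"] = np.sum(
        gig_entropy(
            state.qoE.lam, state.qoE.chi, state.qoE.psi,
            {"mean": ex["oE"], "inv_mean": ex["inv_oE"], "mean_log": ex["ln_oE"]},
        )
    )
    for name, value in terms.items():
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite ELBO term: {name}")
    return float(sum(terms.values()))


def run_inference(
    inp: InferenceInput,
    hyper: Hyperparameters | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    track_elbo: bool = True,
) -> InferenceState:
    """Coordinate-ascent sweeps rho -> q(w) -> q(v) -> q(oE) -> q(oP) -> q(k)
    until every E[w_r] changes by less than ``tol`` relative, or ``max_iter``
    sweeps.  Fully deterministic.
    """
    if hyper is None:
        hyper = Hyperparameters()
    state = initialize_state(inp, hyper)
    for it in range(1, max_iter + 1):
        w_old = np.array(state.expect["w"], dtype=float, copy=True)
        try:
            update_rho(state, inp)
            update_q_w(state, inp, hyper)
            update_q_v(state, inp, hyper)
            update_q_oE(state, inp, hyper)
            update_q_oP(state, inp, hyper)
            update_q_k(state, inp, hyper)
        except FloatingPointError as err:
            raise FloatingPointError(f"sweep {it}: {err}") from err
        for name in ("w", "v", "oP", "oE"):
            if not np.all(np.isfinite(state.expect[name])):
                raise FloatingPointError(
                    f"non-finite expectation in family {name!r} at sweep {it}"
                )
        state.iteration = it
        delta = float(
            np.max(np.abs(state.expect["w"] - w_old) / np.maximum(w_old, 1e-12))
        )
        state.delta_trace.append(delta)
        if track_elbo:
            state.elbo_trace.append(compute_elbo(state, inp, hyper))
            logger.info(
                "sweep %d  elbo=%.6f  max_rel_dw=%.3e", it, state.elbo_trace[-1], delta
            )
        else:
            logger.info("sweep %d  max_rel_dw=%.3e", it, delta)
        if delta < tol:
            state.converged = True
            break
    return state


# ---------------------------------------------------------------------------
# Serialization


def load_inference_input(directory: str | Path) -> InferenceInput:
    """Read the genes.tsv / elements.tsv / contacts.tsv triplet."""
    directory = Path(directory)
    genes = pd.read_csv(directory / "genes.tsv", sep="\t")
    elements = pd.read_csv(directory / "elements.tsv", sep="\t")
    contacts = pd.read_csv(directory / "contacts.tsv", sep="\t")
    gene_ids = genes["gene_id"].astype(str).to_numpy()
    element_ids = elements["element_id"].astype(str).to_numpy()
    g_index = {g: i for i, g in enumerate(gene_ids)}
    r_index = {r: i for i, r in enumerate(element_ids)}
    rows = contacts["gene_id"].astype(str).map(g_index).to_numpy()
    cols = contacts["element_id"].astype(str).map(r_index).to_numpy()
    C = sparse.csr_matrix(
        (contacts["contact"].to_numpy(float), (rows, cols)),
        shape=(len(gene_ids), len(element_ids)),
    )
    return InferenceInput(
        gene_ids=gene_ids,
        element_ids=element_ids,
        t=genes["t"].to_numpy(int),
        lT=genes["lT"].to_numpy(float),
        s=genes["s"].to_numpy(float),
        xP=genes["xP"].to_numpy(int),
        lP=genes["lP"].to_numpy(float),
        xE=elements["xE"].to_numpy(int),
        lE=elements["lE"].to_numpy(float),
        C=C,
    )


def save_inference_input(inp: InferenceInput, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"gene_id": inp.gene_ids, "t": inp.t, "lT": inp.lT, "s": inp.s,
         "xP": inp.xP, "lP": inp.lP}
    ).to_csv(directory / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"element_id": inp.element_ids, "xE": inp.xE, "lE": inp.lE}
    ).to_csv(directory / "elements.tsv", sep="\t", index=False)
    coo = inp.C.tocoo()
    pd.DataFrame(
        {
            "gene_id": inp.gene_ids[coo.row],
            "element_id": inp.element_ids[coo.col],
            "contact": coo.data,
        }
    ).to_csv(directory / "contacts.tsv", sep="\t", index=False)


def save_state(
    state: InferenceState,
    inp: InferenceInput,
    directory: str | Path,
    hyper: Hyperparameters | None = None,
    config: dict | None = None,
) -> None:
    """Posterior dump: one TSV per variational family plus a JSON run record."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ex = state.expect
    pd.DataFrame(
        {"gene_id": inp.gene_ids, "shape": state.qv.a, "rate": state.qv.b,
         "mean": ex["v"], "mean_log": ex["ln_v"]}
    ).to_csv(directory / "q_v.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"element_id": inp.element_ids, "shape": state.qw.a, "rate": state.qw.b,
         "mean": ex["w"], "mean_log": ex["ln_w"]}
    ).to_csv(directory / "q_w.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"gene_id": inp.gene_ids, "lam": state.qoP.lam, "chi": state.qoP.chi,
         "psi": state.qoP.psi, "mean": ex["oP"], "inv_mean": ex["inv_oP"],
         "mean_log": ex["ln_oP"]}
    ).to_csv(directory / "q_oP.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"element_id": inp.element_ids, "lam": state.qoE.lam, "chi": state.qoE.chi,
         "psi": state.qoE.psi, "mean": ex["oE"], "inv_mean": ex["inv_oE"],
         "mean_log": ex["ln_oE"]}
    ).to_csv(directory / "q_oE.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"shape": [float(state.qk.a)], "rate": [float(state.qk.b)],
         "mean": [ex["k"]], "mean_log": [ex["ln_k"]]}
    ).to_csv(directory / "q_k.tsv", sep="\t", index=False)
    record = {
        "iterations": state.iteration,
        "converged": state.converged,
        "elbo_trace": state.elbo_trace,
        "delta_trace": state.delta_trace,
    }
    if hyper is not None:
        record["hyperparameters"] = hyper.to_dict()
    if config:
        record.update(config)
    (directory / "run.json").write_text(json.dumps(record, indent=2) + "\n")
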