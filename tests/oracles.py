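"""Independent brute-force oracles used to cross-check the package.

Everything here is written the slow, obvious way (pure-python loops, dense
matrices, numerical quadrature) so it shares no code path with the
implementations under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate


# --- interval operations ----------------------------------------------------

def brute_top_n(peaks, top_n):
    """(read_count desc, chrom, start) stable sort, first top_n."""
    ranked = sorted(peaks, key=lambda p: (-p.read_count, p.chrom, p.start))
    return ranked if top_n is None else ranked[:top_n]


def brute_resize(peak, width):
    if width is None:
        return (peak.chrom, peak.start, peak.end, peak.read_count)
    summit = peak.start + peak.summit_offset
    half = width // 2
    return (peak.chrom, max(0, summit - half), summit + (width - half), peak.read_count)


def brute_merge(intervals):
    """O(n^2) strict-overlap merging by repeated pairwise joins."""
    items = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                    items[i] = [a[0], min(a[1], b[1]), max(a[2], b[2]), a[3] + b[3]]
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((tuple(x) for x in items), key=lambda r: (r[0], r[1]))


def brute_promoters(genes, elements, flank):
    """Per-gene O(genes x elements) overlap scan against [tss-flank, tss+flank)."""
    out = {}
    excluded = []
    for g in genes:
        lo, hi = g.tss - flank, g.tss + flank
        hits = [
            e for e in elements
            if e.chrom == g.chrom and e.start < hi and e.end > lo
        ]
        if not hits:
            excluded.append(g.gene_id)
        else:
            out[g.gene_id] = (
                sum((e.end - e.start) / 1000.0 for e in hits),
                sum(e.read_count for e in hits),
            )
    return out, excluded


# --- contact-map operations -------------------------------------------------

def brute_fix_diagonal(entries):
    """Dense-logic diagonal fix on a dict {(i,j) i<=j: value}."""
    def get(i, j):
        v = entries.get((min(i, j), max(i, j)))
        return 0.0 if v is None or (isinstance(v, float) and math.isnan(v)) else v

    out = dict(entries)
    for (i, j) in entries:
        if i == j:
            out[(i, i)] = max(get(i - 1, i), get(i + 1, i), get(i, i - 1), get(i, i + 1))
    return out


def brute_low_kr(entries, norm, threshold, model, resolution):
    out = {}
    for (i, j), v in entries.items():
        bad = (isinstance(v, float) and math.isnan(v))
        if norm is not None:
            bad = bad or norm.get(i, np.inf) < threshold or norm.get(j, np.inf) < threshold
        out[(i, j)] = (
            float(model.expected_contact((j - i) * resolution)) if bad else v
        )
    return out


# --- precision-recall -------------------------------------------------------

def brute_average_precision(labels, scores):
    """AP = sum over positives, in score-descending order, of precision at
    each positive's rank (ties broken pessimistically is not needed here:
    test cases use distinct scores)."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    tp = 0
    ap = 0.0
    n_pos = sum(labels)
    for rank, i in enumerate(order, start=1):
        if labels[i]:
            tp += 1
            ap += tp / rank
    return ap / n_pos


# --- GIG quadrature ---------------------------------------------------------

def gig_quadrature(lam, chi, psi):
    """Moments of the GIG density by adaptive quadrature in u = ln x,
    centred at the mode of the log-transformed density and windowed by its
    curvature so narrow high-order densities are resolved."""
    # mode of the u-density; conjugate form avoids cancellation for lam < 0
    if lam >= 0:
        x_star = (lam + math.sqrt(lam * lam + chi * psi)) / psi
    else:
        x_star = chi / (math.sqrt(lam * lam + chi * psi) - lam)
    u_star = math.log(x_star)

    def log_f(u):  # unnormalized, includes the e^u Jacobian
        with np.errstate(over="ignore"):
            return lam * u - 0.5 * (chi * np.exp(-u) + psi * np.exp(u))

    h0 = log_f(u_star)

    def f(u):
        return float(np.exp(log_f(u) - h0))

    # Laplace width at the mode; pad generously for flat/heavy shapes
    sigma = 1.0 / math.sqrt(0.5 * (chi / x_star + psi * x_star))
    half = min(60.0 * sigma + 30.0, 2000.0)
    lo, hi = u_star - half, u_star + half
    pts = [u_star - 5 * sigma, u_star, u_star + 5 * sigma]
    opts = dict(limit=800, epsabs=1e-300, epsrel=1e-11, points=pts)
    z, _ = integrate.quad(f, lo, hi, **opts)

    def moment(log_g):  # integrand assembled in log space to dodge overflow
        val, _ = integrate.quad(
            lambda u: float(np.exp(log_g(u) + log_f(u) - h0)), lo, hi, **opts
        )
        return val / z

    mean_log_val, _ = integrate.quad(lambda u: u * f(u), lo, hi, **opts)
    return {
        "mean": moment(lambda u: u),
        "inv_mean": moment(lambda u: -u),
        "mean_log": mean_log_val / z,
    }


def gamma_closed_form(shape, rate):
    """mean, inv_mean (shape>1), mean_log of Gamma(shape, rate)."""
    from scipy.special import digamma

    return {
        "mean": shape / rate,
        "inv_mean": rate / (shape - 1.0) if shape > 1 else np.inf,
        "mean_log": digamma(shape) - math.log(rate),
    }


def gamma_quadrature_expectations(a, b, g):
    """E[g(x)] under Gamma(a, b) by quadrature (log-space, mode-centred)."""
    u_star = math.log(a / b)

    def log_f(u):
        return a * u - b * math.exp(u)

    h0 = log_f(u_star)
    f = lambda u: math.exp(min(log_f(u) - h0, 0.0))
    sigma = 1.0 / math.sqrt(a)  # curvature of the u-density at its mode
    half = 50.0 * sigma + 15.0
    lo, hi = u_star - half, u_star + half
    opts = dict(
        limit=800, epsabs=1e-300, epsrel=1e-12,
        points=[u_star - 5 * sigma, u_star, u_star + 5 * sigma],
    )
    z, _ = integrate.quad(f, lo, hi, **opts)
    val, _ = integrate.quad(lambda u: g(math.exp(u)) * f(u), lo, hi, **opts)
    return val / z
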