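"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: alignment scores by
exhaustive enumeration of all monotone alignments, binding sites by a plain
per-offset scan, amplicons by a double loop over site pairs, and Beta
quantiles by numerical inversion of the CDF on a fine grid.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s))


def brute_force_alignment_score(a: str, b: str, match, mismatch, gap_open, gap_extend):
    """Best score over every global alignment (gap of length L costs
    gap_open + L*gap_extend). Exponential; lengths <= ~7 only."""
    best = [-np.inf]

    def rec(i, j, last, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):
            pen = gap_extend + (gap_open if last != "X" else 0)
            rec(i + 1, j, "X", score + pen)
        if j < len(b):
            pen = gap_extend + (gap_open if last != "Y" else 0)
            rec(i, j + 1, "Y", score + pen)

    rec(0, 0, None, 0.0)
    return best[0]


def brute_force_binding_sites(primer: str, template: str, max_mismatches: int):
    """(start 1-based, strand, mismatches) for every offset on both strands."""
    sites = []
    n = len(primer)
    rc = revcomp(primer)
    for off in range(len(template) - n + 1):
        window = template[off : off + n]
        mm = sum(p != t for p, t in zip(primer, window))
        if mm <= max_mismatches:
            sites.append((off + 1, "+", mm))
        mm_rc = sum(p != t for p, t in zip(rc, window))
        if mm_rc <= max_mismatches:
            sites.append((off + 1, "-", mm_rc))
    sites.sort(key=lambda s: (s[0], s[1]))
    return sites


def brute_force_amplicons(fwd: str, rev: str, template: str, max_mismatches: int,
                          max_product: int):
    """(fwd_5prime, rev_5prime, length) for every convergent site pair of the
    two primers, including the swapped-role orientation."""
    products = []
    sites = {
        "f": brute_force_binding_sites(fwd, template, max_mismatches),
        "r": brute_force_binding_sites(rev, template, max_mismatches),
    }
    lens = {"f": len(fwd), "r": len(rev)}
    for left, right in (("f", "r"), ("r", "f")):
        for pos_l, strand_l, _ in sites[left]:
            if strand_l != "+":
                continue
            for pos_r, strand_r, _ in sites[right]:
                if strand_r != "-":
                    continue
                five_l = pos_l
                five_r = pos_r + lens[right] - 1
                length = five_r - five_l + 1
                if lens["f"] + lens["r"] <= length <= max_product:
                    products.append((five_l, five_r, length))
    products.sort()
    return products


def beta_quantile_by_quadrature(s: int, n: int, prob: float, grid: int = 200_001):
    """Quantile of Beta(s+1, n-s+1) by trapezoidal CDF inversion."""
    from math import lgamma

    p = np.linspace(0.0, 1.0, grid)
    a, b = s + 1, n - s + 1
    log_norm = lgamma(a + b) - lgamma(a) - lgamma(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        logpdf = (a - 1) * np.log(p) + (b - 1) * np.log1p(-p) + log_norm
    pdf = np.exp(logpdf)
    pdf[~np.isfinite(pdf)] = 0.0
    cdf = np.concatenate(([0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2) * (p[1] - p[0])))
    cdf /= cdf[-1]
    return float(np.interp(prob, cdf, p))
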