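"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with scalar Python loops and the math module only,
deliberately avoiding the vectorised code paths under test.
"""

from __future__ import annotations

import math
from itertools import combinations
from statistics import median


def wald_oracle_table(meth_rows, total_rows, idx_a, idx_b,
                      phi_prior_weight=20.0, phi_fallback=0.05):
    """Scalar re-derivation of the beta-binomial Wald test over a row pool.

    meth_rows/total_rows: list of per-row lists of counts across samples.
    Returns a list of dicts (mu_a, mu_b, diff, phi, wald, p, tested), with the
    phi shrinkage median taken over the rows supplied (the same pooling rule
    as the implementation's caller contract).
    """
    prelim = []
    for x_all, n_all in zip(meth_rows, total_rows):
        xa = [x_all[i] for i in idx_a if n_all[i] >= 1]
        na = [n_all[i] for i in idx_a if n_all[i] >= 1]
        xb = [x_all[i] for i in idx_b if n_all[i] >= 1]
        nb = [n_all[i] for i in idx_b if n_all[i] >= 1]
        tested = len(na) >= 2 and len(nb) >= 2
        sxa, sna, sxb, snb = sum(xa), sum(na), sum(xb), sum(nb)
        mu_a = sxa / sna if sna else float("nan")
        mu_b = sxb / snb if snb else float("nan")
        ss = sum((x / n - mu_a) ** 2 for x, n in zip(xa, na)) \
            + sum((x / n - mu_b) ** 2 for x, n in zip(xb, nb))
        va, vb = mu_a * (1 - mu_a), mu_b * (1 - mu_b)
        bin_part = va * sum(1 / n for n in na) + vb * sum(1 / n for n in nb)
        denom = va * (len(na) - sum(1 / n for n in na)) \
            + vb * (len(nb) - sum(1 / n for n in nb))
        if denom > 0:
            phi_hat = min(max((ss - bin_part) / denom, 0.0), 0.95)
        else:
            phi_hat = float("nan")
        prelim.append((xa, na, xb, nb, tested, mu_a, mu_b,
                       sxa, sna, sxb, snb, phi_hat))

    finite = [p[11] for p in prelim if p[4] and not math.isnan(p[11])]
    phi_med = median(finite) if finite else phi_fallback

    out = []
    for xa, na, xb, nb, tested, mu_a, mu_b, sxa, sna, sxb, snb, phi_hat in prelim:
        m = len(na) + len(nb)
        if math.isnan(phi_hat):
            phi = phi_med
        else:
            phi = (m * phi_hat + phi_prior_weight * phi_med) / (m + phi_prior_weight)
        mt_a = (sxa + 0.5) / (sna + 1.0)
        mt_b = (sxb + 0.5) / (snb + 1.0)
        var_a = mt_a * (1 - mt_a) * sum(n * (1 + (n - 1) * phi) for n in na) \
            / max(sna, 1) ** 2
        var_b = mt_b * (1 - mt_b) * sum(n * (1 + (n - 1) * phi) for n in nb) \
            / max(snb, 1) ** 2
        diff = mu_b - mu_a
        wald = 0.0 if diff == 0 else diff / math.sqrt(var_a + var_b)
        p = math.erfc(abs(wald) / math.sqrt(2.0))
        out.append({"mu_a": mu_a, "mu_b": mu_b, "diff": diff, "phi": phi,
                    "wald": wald, "p": p, "tested": tested})
    return out


def overlaps(a, b) -> int:
    """Overlap in bp between two (chrom, start, end) triples."""
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


def brute_force_any_overlap(regions, features, min_bp=1):
    """Per-region flag: overlaps any feature by >= min_bp (all-pairs check)."""
    return [any(overlaps(r, f) >= min_bp for f in features) for r in regions]


def brute_force_state_assignment(regions, states):
    """Per region, the label of the state with maximal bp overlap.

    Ties broken by the order of first appearance of the label in the state
    list; None without overlap.
    """
    first_seen: dict[str, int] = {}
    for _, _, _, lab in states:
        first_seen.setdefault(lab, len(first_seen))
    out = []
    for r in regions:
        best = None  # (bp, priority, label)
        for c, s, e, lab in states:
            bp = overlaps(r, (c, s, e))
            if bp <= 0:
                continue
            key = (-bp, first_seen[lab])
            if best is None or key < best[0]:
                best = (key, lab)
        out.append(best[1] if best else None)
    return out


def exact_permutation_p(universe_flags, query_indices):
    """Exact overlap-permutation p by full subset enumeration.

    universe_flags: per-universe-member booleans (overlaps the reference);
    p = fraction of |query|-subsets whose flagged count >= the observed count.
    """
    k = len(query_indices)
    observed = sum(universe_flags[i] for i in query_indices)
    total = ge = 0
    for subset in combinations(range(len(universe_flags)), k):
        total += 1
        if sum(universe_flags[i] for i in subset) >= observed:
            ge += 1
    return observed, ge / total
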