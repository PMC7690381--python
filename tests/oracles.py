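"""Deliberately naive reference implementations used as independent oracles.

Everything here is written with plain Python loops and the `statistics`
module, independent of the vectorized implementations under test.
"""

from __future__ import annotations

import math
import statistics
from typing import Sequence


def pair_sd_brute(x: Sequence[Sequence[float]]) -> list[list[float]]:
    """SD (n-1) of per-sample differences for every gene pair, by loops."""
    n = len(x)
    out = [[0.0] * n for _ in range(n)]
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            diffs = [a - b for a, b in zip(x[j], x[k])]
            out[j][k] = statistics.stdev(diffs)
    return out


def delta_ct_brute(x: Sequence[Sequence[float]]) -> list[float]:
    m = pair_sd_brute(x)
    n = len(x)
    return [sum(m[j][k] for k in range(n) if k != j) / (n - 1) for j in range(n)]


def genorm_brute(
    x: Sequence[Sequence[float]], ids: Sequence[str]
) -> tuple[list[str], dict[str, float], dict[str, float]]:
    """Iterative-exclusion geNorm: returns (elimination order, M value at
    elimination, rank) per gene, final pair tied at rank 1.5."""
    rows = {g: list(v) for g, v in zip(ids, x)}
    active = list(ids)
    values: dict[str, float] = {}
    ranks: dict[str, float] = {}
    elim: list[str] = []
    rank = float(len(ids))
    while len(active) > 2:
        m = {}
        for g in active:
            sds = [
                statistics.stdev(
                    [a - b for a, b in zip(rows[g], rows[h])]
                )
                for h in active
                if h != g
            ]
            m[g] = sum(sds) / len(sds)
        worst = max(active, key=lambda g: (m[g], g))
        values[worst] = m[worst]
        ranks[worst] = rank
        elim.append(worst)
        active.remove(worst)
        rank -= 1.0
    g, h = active
    final_m = statistics.stdev([a - b for a, b in zip(rows[g], rows[h])])
    for gg in active:
        values[gg] = final_m
        ranks[gg] = 1.5
    return elim, values, ranks


def bestkeeper_brute(
    x: Sequence[Sequence[float]],
) -> tuple[list[float], list[float], list[float]]:
    """(mean, MAD, CV%) per gene by loops."""
    means, mads, cvs = [], [], []
    for row in x:
        mu = statistics.mean(row)
        mad = sum(abs(v - mu) for v in row) / len(row)
        means.append(mu)
        mads.append(mad)
        cvs.append(mad / mu * 100.0)
    return means, mads, cvs


def normfinder_brute(
    x: Sequence[Sequence[float]], labels: Sequence[str]
) -> list[float]:
    """Grouped stability values by explicit loops: per-sample centering,
    group means/variances of the centered values, cross-group centering,
    moment estimate of the inter-group variance, shrinkage, and
    |bias| + SE averaged over groups (ungrouped SD fallback if the moment
    estimate is zero)."""
    n_genes, n_samp = len(x), len(x[0])
    sample_means = [
        sum(x[i][j] for i in range(n_genes)) / n_genes for j in range(n_samp)
    ]
    z = [[x[i][j] - sample_means[j] for j in range(n_samp)] for i in range(n_genes)]
    groups = sorted(set(labels))
    g_count = len(groups)
    cols = {g: [j for j, l in enumerate(labels) if l == g] for g in groups}
    d = [[0.0] * g_count for _ in range(n_genes)]
    s2 = [[0.0] * g_count for _ in range(n_genes)]
    for i in range(n_genes):
        for gi, g in enumerate(groups):
            vals = [z[i][j] for j in cols[g]]
            d[i][gi] = statistics.mean(vals)
            s2[i][gi] = statistics.variance(vals)
        bar = statistics.mean(d[i])
        d[i] = [v - bar for v in d[i]]
    acc = []
    for i in range(n_genes):
        for gi, g in enumerate(groups):
            noise = (1.0 - 1.0 / g_count) * s2[i][gi] / len(cols[g])
            acc.append(d[i][gi] ** 2 - noise)
    gamma = max(0.0, statistics.mean(acc) * g_count / (g_count - 1))
    if gamma == 0.0:
        return [statistics.stdev(z[i]) for i in range(n_genes)]
    out = []
    for i in range(n_genes):
        terms = []
        for gi, g in enumerate(groups):
            var_d = s2[i][gi] / len(cols[g])
            d_star = d[i][gi] * gamma / (gamma + var_d)
            se = math.sqrt(gamma * var_d / (gamma + var_d))
            terms.append(abs(d_star) + se)
        out.append(sum(terms) / len(terms))
    return out
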