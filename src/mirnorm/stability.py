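"""Expression-stability ranking of candidate reference miRNAs.

Four classic algorithms are implemented on the Ct scale (Ct is already a
log2-scale abundance with amplification efficiency fixed at 2, so the SD of
log2 expression ratios equals the SD of Ct differences):

* geNorm — average pairwise-ratio SD (M value) with iterative exclusion of
  the least stable gene until a most-stable pair remains.
* BestKeeper — descriptive dispersion per gene: mean absolute deviation of
  Ct around its arithmetic mean (the BestKeeper "SD [+-Ct]") and CV%.
* comparative delta-Ct — mean over partner genes of the SD of per-sample
  Ct differences.
* NormFinder — model-based decomposition into intra-group variance and
  shrunken inter-group bias.

Lower stability value = more stable.  A comprehensive ranking aggregates
the four by geometric mean of ranks; ties everywhere are broken
lexicographically by assay id so every output is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import CtMatrix, SampleTable

__all__ = [
    "StabilityResult",
    "AggregateRanking",
    "StabilityError",
    "complete_candidates",
    "pair_sd_matrix",
    "delta_ct_method",
    "genorm",
    "bestkeeper",
    "normfinder",
    "comprehensive_rank",
    "top_k_overlap",
]

logger = logging.getLogger(__name__)


class StabilityError(ValueError):
    pass


@dataclass
class StabilityResult:
    """Per-candidate stability values and ranks for one algorithm."""

    algorithm: str
    assay_ids: list[str]
    values: np.ndarray  # lower = more stable
    ranks: np.ndarray  # 1 = best; midpoint ties allowed
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=float)
        n = len(self.assay_ids)
        if self.values.shape != (n,) or self.ranks.shape != (n,):
            raise StabilityError("values/ranks length mismatch")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise StabilityError("stability values must be finite and >= 0")

    def value_of(self) -> Mapping[str, float]:
        return dict(zip(self.assay_ids, self.values))

    def rank_of(self) -> Mapping[str, float]:
        return dict(zip(self.assay_ids, self.ranks))

    def top_k(self, k: int) -> list[str]:
        """The k best-ranked assays; boundary ties resolved by assay id."""
        if k > len(self.assay_ids):
            raise StabilityError(
                f"k={k} exceeds candidate count {len(self.assay_ids)}"
            )
        order = sorted(
            range(len(self.assay_ids)),
            key=lambda i: (self.ranks[i], self.assay_ids[i]),
        )
        return [self.assay_ids[i] for i in order[:k]]


@dataclass
class AggregateRanking:
    """Geometric-mean-of-ranks aggregation across algorithms."""

    assay_ids: list[str]
    component_ranks: dict[str, np.ndarray]  # algorithm -> ranks
    geomean: np.ndarray
    final_rank: np.ndarray  # strict permutation of 1..n

    def ordered(self) -> list[str]:
        order = np.argsort(self.final_rank)
        return [self.assay_ids[i] for i in order]

    def best(self) -> str:
        return self.ordered()[0]

    def rank_of(self) -> Mapping[str, int]:
        return {a: int(r) for a, r in zip(self.assay_ids, self.final_rank)}


def _avg_rank(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def complete_candidates(ct: CtMatrix, candidates: Sequence[str]) -> list[str]:
    """Drop candidates with any undetected well (stability algorithms need
    complete cases; imputation is deliberately not attempted)."""
    kept = []
    for a in candidates:
        _, det = ct.row(a)
        if det.all():
            kept.append(a)
        else:
            logger.warning(
                "candidate %r has undetected wells; dropped from stability "
                "analysis",
                a,
            )
    return kept


def _candidate_grid(ct: CtMatrix) -> np.ndarray:
    if ct.n_assays < 2:
        raise StabilityError("need >=2 candidate assays")
    if ct.n_samples < 3:
        raise StabilityError("need >=3 samples for a stable SD")
    if not ct.detected.all():
        raise StabilityError(
            "undetected wells among candidates; drop incomplete candidates "
            "first (complete_candidates)"
        )
    return ct.values


def pair_sd_matrix(ct: CtMatrix) -> np.ndarray:
    """Symmetric matrix of SD(Ct_j - Ct_k) over samples (n-1 denominator).

    This is the shared statistic under geNorm's M value and the comparative
    delta-Ct method; per-sample additive shifts cancel in the differences.
    """
    x = _candidate_grid(ct)
    n = x.shape[0]
    out = np.zeros((n, n))
    for j in range(n):
        d = x[j] - x  # (n, samples)
        out[j] = d.std(axis=1, ddof=1)
    # enforce exact symmetry/zero diagonal against float noise
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return out


def _mean_pair_sd(pair_sd: np.ndarray) -> np.ndarray:
    n = pair_sd.shape[0]
    return pair_sd.sum(axis=1) / (n - 1)


def delta_ct_method(ct: CtMatrix) -> StabilityResult:
    """Comparative delta-Ct stability: mean over partners of the pairwise
    difference SD."""
    values = _mean_pair_sd(pair_sd_matrix(ct))
    return StabilityResult(
        algorithm="delta_ct",
        assay_ids=list(ct.assay_ids),
        values=values,
        ranks=_avg_rank(values),
    )


def genorm(ct: CtMatrix) -> StabilityResult:
    """geNorm M value with iterative exclusion.

    M_j is the mean pairwise-difference SD over the *current* candidate
    set; the gene with the largest M is removed and M recomputed until two
    genes remain.  Elimination order assigns ranks n, n-1, ..., 3; the final
    pair shares rank 1.5.  Each gene's reported stability value is its M at
    the iteration of its elimination (final pair: their common final M).
    """
    if ct.n_assays < 3:
        raise StabilityError("geNorm needs >=3 candidates")
    full_sd = pair_sd_matrix(ct)
    assays = list(ct.assay_ids)
    active = list(range(len(assays)))
    n = len(assays)
    values = np.empty(n)
    ranks = np.empty(n)
    elimination: list[str] = []
    trajectory: list[dict[str, float]] = []
    rank = float(n)
    while len(active) > 2:
        sub = full_sd[np.ix_(active, active)]
        m = _mean_pair_sd(sub)
        trajectory.append({assays[i]: float(v) for i, v in zip(active, m)})
        # worst = largest M; ties eliminate the lexicographically larger id
        worst_pos = max(
            range(len(active)), key=lambda p: (m[p], assays[active[p]])
        )
        gi = active[worst_pos]
        values[gi] = m[worst_pos]
        ranks[gi] = rank
        elimination.append(assays[gi])
        active.pop(worst_pos)
        rank -= 1.0
    final_m = float(full_sd[active[0], active[1]])
    for gi in active:
        values[gi] = final_m
        ranks[gi] = 1.5
    trajectory.append({assays[i]: final_m for i in active})
    return StabilityResult(
        algorithm="genorm",
        assay_ids=assays,
        values=values,
        ranks=ranks,
        extras={
            "elimination_order": elimination,
            "final_pair": sorted(assays[i] for i in active),
            "m_trajectory": trajectory,
        },
    )


def bestkeeper(ct: CtMatrix) -> StabilityResult:
    """BestKeeper descriptive dispersion.

    Per gene: arithmetic mean Ct, mean absolute deviation (MAD) around it —
    the BestKeeper "SD [+-Ct]" — and CV% = MAD/mean x 100.  Genes rank
    ascending by MAD.  Unlike the other algorithms this statistic is NOT
    invariant to per-sample shifts: shared technical variation inflates it.
    """
    if ct.n_assays < 1:
        raise StabilityError("need >=1 candidate")
    if ct.n_samples < 3:
        raise StabilityError("need >=3 samples")
    if not ct.detected.all():
        raise StabilityError("undetected wells among candidates")
    x = ct.values
    mean = x.mean(axis=1)
    if (mean <= 0).any():
        raise StabilityError("non-positive mean Ct; CV undefined")
    mad = np.abs(x - mean[:, None]).mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    cv = mad / mean * 100.0
    return StabilityResult(
        algorithm="bestkeeper",
        assay_ids=list(ct.assay_ids),
        values=mad,
        ranks=_avg_rank(mad),
        extras={"mean_ct": mean, "sd": sd, "cv_pct": cv},
    )


def _normfinder_ungrouped(z: np.ndarray) -> np.ndarray:
    """Single-group stability: intra-gene SD of sample-centered values."""
    return z.std(axis=1, ddof=1)


def normfinder(
    ct: CtMatrix,
    samples: SampleTable,
    grouping: str = "bc_vs_control",
) -> StabilityResult:
    """NormFinder variance-decomposition stability.

    Steps: (1) center each sample by its mean across candidate genes;
    (2) per gene i and group g take the group mean d_ig and within-group
    variance s2_ig of centered values; (3) center d_ig per gene across
    groups; (4) shrink d_ig toward 0 by the empirical variance ratio
    d*_ig = d_ig * gamma / (gamma + s2_ig/n_g), gamma being a
    method-of-moments estimate of the inter-group variance across genes;
    (5) stability_i = mean over groups of |d*_ig| + SE(d*_ig).

    ``grouping`` is ``"bc_vs_control"`` (default: all tumor subgroups pooled
    against controls), ``"subgroups"`` (each clinical group separate) or
    ``"none"``.  With one effective group the measure reduces to the
    intra-gene SD of sample-centered values.
    """
    if ct.n_assays < 3:
        raise StabilityError("NormFinder needs >=3 genes")
    x = _candidate_grid(ct)
    group_of = samples.group_of()
    if grouping == "bc_vs_control":
        labels = [
            "control" if group_of[s] == "control" else "BC"
            for s in ct.sample_ids
        ]
    elif grouping == "subgroups":
        labels = [group_of[s] for s in ct.sample_ids]
    elif grouping == "none":
        labels = ["all"] * ct.n_samples
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    z = x - x.mean(axis=0, keepdims=True)  # step 1: per-sample centering
    uniq = sorted(set(labels))
    if len(uniq) > 1:
        counts = {g: labels.count(g) for g in uniq}
        small = [g for g, c in counts.items() if c < 2]
        if small:
            raise StabilityError(f"group(s) with <2 samples: {small}")
    if len(uniq) == 1:
        if grouping not in ("none",):
            logger.info(
                "normfinder: single group present; falling back to the "
                "ungrouped variant"
            )
        values = _normfinder_ungrouped(z)
        return StabilityResult(
            algorithm="normfinder",
            assay_ids=list(ct.assay_ids),
            values=values,
            ranks=_avg_rank(values),
            extras={"grouping": "none"},
        )

    cols = {g: [j for j, lbl in enumerate(labels) if lbl == g] for g in uniq}
    n_genes = ct.n_assays
    n_groups = len(uniq)
    d = np.empty((n_genes, n_groups))
    s2 = np.empty((n_genes, n_groups))
    n_g = np.array([len(cols[g]) for g in uniq], dtype=float)
    for gi, g in enumerate(uniq):
        sub = z[:, cols[g]]
        d[:, gi] = sub.mean(axis=1)
        s2[:, gi] = sub.var(axis=1, ddof=1)
    d = d - d.mean(axis=1, keepdims=True)  # step 3: center across groups

    # step 4: method-of-moments inter-group variance.  After centering
    # across G groups, E[d_ig^2] ~= gamma*(G-1)/G + (1-1/G)*s2_ig/n_g.
    noise = (1.0 - 1.0 / n_groups) * (s2 / n_g[None, :])
    gamma = float(
        max(0.0, (d**2 - noise).mean() * n_groups / (n_groups - 1))
    )
    if gamma == 0.0:
        # no detectable inter-group variance anywhere: the shrinkage sends
        # every bias (and its SE) to zero, which cannot rank genes — fall
        # back to the ungrouped intra-gene SD
        logger.info(
            "normfinder: inter-group variance estimate is 0; using the "
            "ungrouped variant"
        )
        values = _normfinder_ungrouped(z)
        return StabilityResult(
            algorithm="normfinder",
            assay_ids=list(ct.assay_ids),
            values=values,
            ranks=_avg_rank(values),
            extras={"grouping": grouping, "gamma": 0.0},
        )
    var_d = s2 / n_g[None, :]
    shrink = gamma / (gamma + var_d)
    d_star = d * shrink
    # SE of the shrunken difference: sqrt(gamma * var_d / (gamma + var_d))
    se = np.sqrt(gamma * var_d / (gamma + var_d))
    values = (np.abs(d_star) + se).mean(axis=1)
    return StabilityResult(
        algorithm="normfinder",
        assay_ids=list(ct.assay_ids),
        values=values,
        ranks=_avg_rank(values),
        extras={
            "grouping": grouping,
            "groups": uniq,
            "gamma": gamma,
            "group_bias": d,
            "group_bias_shrunken": d_star,
            "within_group_var": s2,
        },
    )


def comprehensive_rank(results: Sequence[StabilityResult]) -> AggregateRanking:
    """Aggregate >=2 algorithm rankings by geometric mean of ranks.

    All results must cover the identical candidate set.  The final ranking
    sorts ascending by geometric mean with lexicographic assay-id
    tie-break, yielding a strict 1..n permutation.
    """
    if len(results) < 2:
        raise StabilityError("need >=2 stability results to aggregate")
    base = set(results[0].assay_ids)
    for r in results[1:]:
        if set(r.assay_ids) != base:
            diff = sorted(base.symmetric_difference(r.assay_ids))
            raise StabilityError(
                f"candidate sets differ between algorithms: {diff}"
            )
    assays = sorted(base)
    comp: dict[str, np.ndarray] = {}
    for r in sorted(results, key=lambda r: r.algorithm):
        rk = r.rank_of()
        comp[r.algorithm] = np.array([rk[a] for a in assays], dtype=float)
    stacked = np.vstack(list(comp.values()))
    geomean = np.exp(np.log(stacked).mean(axis=0))
    order = sorted(range(len(assays)), key=lambda i: (geomean[i], assays[i]))
    final = np.empty(len(assays))
    for pos, i in enumerate(order, start=1):
        final[i] = pos
    return AggregateRanking(
        assay_ids=assays,
        component_ranks=comp,
        geomean=geomean,
        final_rank=final,
    )


def top_k_overlap(
    results: Sequence[StabilityResult], k: int
) -> dict[frozenset[str], list[str]]:
    """Venn partition of the k best assays per algorithm.

    Returns every non-empty region as {algorithms sharing the assay} ->
    sorted member assays; region sizes sum to the size of the union of the
    top-k lists.
    """
    if len(results) < 2:
        raise StabilityError("need >=2 results for an overlap")
    tops = {r.algorithm: set(r.top_k(k)) for r in results}
    regions: dict[frozenset[str], list[str]] = {}
    union = set().union(*tops.values())
    for assay in sorted(union):
        key = frozenset(alg for alg, s in tops.items() if assay in s)
        regions.setdefault(key, []).append(assay)
    return regions
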