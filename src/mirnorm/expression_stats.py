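"""Group-difference testing and 2^-ddCt relative quantification.

A good normalizer must not itself differ between cases and controls, so
candidates are screened with an unpaired Student t-test on raw Ct.  The
chosen reference then normalizes a disease-related target miRNA via the
2^-ddCt method, and group effects on the fold-change are assessed with a
classic one-way ANOVA plus Tukey HSD post hoc.  Tests run on the log2
fold-change scale (-ddCt), where qPCR noise is closest to homoscedastic
normal; group summaries are reported as mean RQ +- SEM on the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io_formats import CtMatrix, SampleTable

__all__ = [
    "GroupTestResult",
    "RelQuantResult",
    "AnovaTukeyResult",
    "GROUP_SCHEMES",
    "compare_groups_ct",
    "ddct_relative_quant",
    "anova_tukey",
]


class ExpressionError(ValueError):
    pass


@dataclass
class GroupTestResult:
    assay_id: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    t_statistic: float
    p_value: float


@dataclass
class RelQuantResult:
    """Per-sample dCt/ddCt/RQ for one target/reference pair.

    dCt = Ct_target - Ct_reference; ddCt = dCt - mean dCt of the baseline
    group; RQ = 2^-ddCt.  The baseline group's ddCt averages to zero, so
    its geometric-mean RQ is exactly 1.
    """

    target: str
    reference: str
    baseline_group: str
    per_sample: pd.DataFrame  # sample_id, group, dct, ddct, rq
    group_summary: pd.DataFrame = field(init=False)  # group, n, mean_rq, sem_rq

    def __post_init__(self) -> None:
        rows = []
        for g, sub in self.per_sample.groupby("group", sort=True):
            rq = sub["rq"].to_numpy()
            sem = rq.std(ddof=1) / np.sqrt(len(rq)) if len(rq) > 1 else np.nan
            rows.append(
                {"group": g, "n": len(rq), "mean_rq": rq.mean(), "sem_rq": sem}
            )
        self.group_summary = pd.DataFrame(rows)


@dataclass
class AnovaTukeyResult:
    scheme: str
    group_labels: dict[str, str]  # original group -> scheme group
    p_omnibus: float
    tukey: pd.DataFrame  # group1, group2, estimate (log2 FC), p_adj, reject


def compare_groups_ct(
    ct: CtMatrix, samples: SampleTable, assay: str
) -> GroupTestResult:
    """Two-sided unpaired Student t-test of an assay's Ct between pooled
    tumor samples and controls (equal-variance, no Welch correction)."""
    vals, det = ct.row(assay)
    pos = {s: j for j, s in enumerate(ct.sample_ids)}
    parts = {}
    for name, ids in (
        ("BC", samples.bc_samples()),
        ("control", samples.control_samples()),
    ):
        v = np.array(
            [vals[pos[s]] for s in ids if s in pos and det[pos[s]]]
        )
        if len(v) < 2:
            raise ExpressionError(
                f"partition {name!r} has {len(v)} detected values for "
                f"{assay!r}; need >=2"
            )
        parts[name] = v
    a, b = parts["BC"], parts["control"]
    if a.mean() == b.mean() and np.ptp(np.concatenate([a, b])) == 0.0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        if not np.isfinite(p):  # identical means with zero pooled variance
            t, p = 0.0, 1.0
    return GroupTestResult(
        assay_id=assay,
        group_means={g: float(v.mean()) for g, v in parts.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in parts.items()},
        group_ns={g: int(len(v)) for g, v in parts.items()},
        t_statistic=float(t),
        p_value=float(p),
    )


def ddct_relative_quant(
    ct: CtMatrix,
    samples: SampleTable,
    target: str,
    reference: str,
    baseline_group: str = "control",
) -> RelQuantResult:
    """Fold-change of ``target`` relative to ``reference`` by 2^-ddCt.

    Samples where either assay is undetected are excluded.  The baseline is
    the arithmetic-mean dCt of ``baseline_group`` (so that group's RQ has
    geometric mean 1).
    """
    if target == reference:
        raise ExpressionError(
            f"self-normalization: target and reference are both {target!r}"
        )
    t_vals, t_det = ct.row(target)
    r_vals, r_det = ct.row(reference)
    group_of = samples.group_of()
    rows = []
    for j, s in enumerate(ct.sample_ids):
        if t_det[j] and r_det[j]:
            rows.append(
                {
                    "sample_id": s,
                    "group": group_of[s],
                    "dct": float(t_vals[j] - r_vals[j]),
                }
            )
    df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ExpressionError("no samples with both target and reference detected")
    base = df.loc[df["group"] == baseline_group, "dct"]
    if len(base) == 0:
        raise ExpressionError(f"baseline group {baseline_group!r} is empty")
    df["ddct"] = df["dct"] - base.mean()
    df["rq"] = np.exp2(-df["ddct"])
    return RelQuantResult(
        target=target,
        reference=reference,
        baseline_group=baseline_group,
        per_sample=df,
    )


GROUP_SCHEMES = ("full", "Ta-pooled", "NMIBC-vs-MIBC")


def _scheme_label(group: str, scheme: str) -> str:
    if scheme == "full":
        return group
    if scheme == "Ta-pooled":
        return "Ta" if group.startswith("Ta") else group
    if scheme == "NMIBC-vs-MIBC":
        if group == "control":
            return "control"
        if group.startswith(("Ta", "T1")):
            return "NMIBC"
        return "MIBC"  # T2+, T3+
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {GROUP_SCHEMES}")


def anova_tukey(
    rq: RelQuantResult, samples: SampleTable, scheme: str = "full"
) -> AnovaTukeyResult:
    """One-way ANOVA + Tukey HSD of the fold-change across group schemes.

    ``full`` keeps every clinical subgroup plus control; ``Ta-pooled``
    merges all Ta-stage subgroups; ``NMIBC-vs-MIBC`` merges Ta/T1 into
    NMIBC and T2+/T3+ into MIBC.  Tests run on log2 RQ (= -ddCt); the
    reported pairwise estimate is the log2 fold-change difference.
    """
    df = rq.per_sample.copy()
    df["scheme_group"] = [_scheme_label(g, scheme) for g in df["group"]]
    labels = {g: _scheme_label(g, scheme) for g in sorted(set(df["group"]))}
    counts = df["scheme_group"].value_counts()
    too_small = sorted(counts[counts < 2].index)
    if too_small or len(counts) < 2:
        raise ExpressionError(
            f"scheme {scheme!r} yields group(s) of size <2: {too_small}"
            if too_small
            else f"scheme {scheme!r} yields fewer than 2 groups"
        )
    df["log2rq"] = -df["ddct"]
    groups = [
        sub["log2rq"].to_numpy() for _, sub in df.groupby("scheme_group", sort=True)
    ]
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0.0:
        p_omni = 1.0
    else:
        _, p_omni = stats.f_oneway(*groups)
        if not np.isfinite(p_omni):
            p_omni = 1.0
    tk = pairwise_tukeyhsd(
        df["log2rq"].to_numpy(), df["scheme_group"].to_numpy(), alpha=0.05
    )
    summary = tk.summary()
    tukey = pd.DataFrame(summary.data[1:], columns=summary.data[0]).rename(
        columns={"meandiff": "estimate", "p-adj": "p_adj"}
    )[["group1", "group2", "estimate", "p_adj", "reject"]]
    # full precision values, not the rounded summary strings
    tukey["estimate"] = tk.meandiffs
    tukey["p_adj"] = tk.pvalues
    return AnovaTukeyResult(
        scheme=scheme,
        group_labels=labels,
        p_omnibus=float(p_omni),
        tukey=tukey,
    )
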