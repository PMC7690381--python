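"""End-to-end screening and validation workflows.

``run_screening`` chains inter-plate calibration, spike-in QC, the Ct
detection filter, the four stability algorithms, the comprehensive
ranking, the top-k overlap, candidate group t-tests and 2^-ddCt
quantification of the target under each top-k normalizer, writing every
result as a provenance-stamped CSV plus a markdown report.
``run_validation`` checks a chosen reference in an independent cohort and
re-quantifies the target under it across clinical-group schemes.

Every number in the report is read back from a written table; with a fixed
seed and config the whole bundle is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression_stats import (
    GROUP_SCHEMES,
    ExpressionError,
    anova_tukey,
    compare_groups_ct,
    ddct_relative_quant,
)
from .io_formats import (
    CtMatrix,
    ResultTable,
    SampleTable,
    read_ct_matrix,
    read_sample_table,
    write_ct_matrix,
    write_result_table,
    write_sample_table,
)
from .qc import SpikeInSet, detection_filter, interplate_calibrate, spikein_group_check
from .stability import (
    bestkeeper,
    complete_candidates,
    comprehensive_rank,
    delta_ct_method,
    genorm,
    normfinder,
    top_k_overlap,
)
from .synthetic import default_screening_spec, default_validation_spec, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_screening", "run_validation"]

logger = logging.getLogger(__name__)

ALGORITHMS = ("genorm", "bestkeeper", "delta_ct", "normfinder")


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a screening/validation run needs.

    Either ``ct_path``/``samples_path`` point at CSV inputs, or
    ``simulate`` selects a built-in synthetic cohort ("screening" or
    "validation") drawn with ``seed``.
    """

    ct_path: str | None = None
    samples_path: str | None = None
    simulate: str | None = None
    spikes: SpikeInSet = field(default_factory=SpikeInSet)
    threshold: float = 35.0
    algorithms: tuple[str, ...] = ALGORITHMS
    k: int = 10
    target: str | None = None
    reference: str | None = None
    baseline_group: str = "control"
    alpha: float = 0.05
    out_dir: str = "mirnorm_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
        if self.simulate is None and (self.ct_path is None or self.samples_path is None):
            raise ValueError("need ct_path+samples_path or simulate")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "spikes" in raw and isinstance(raw["spikes"], dict):
            sp = dict(raw["spikes"])
            if "isolation_spikes" in sp:
                sp["isolation_spikes"] = tuple(sp["isolation_spikes"])
            raw["spikes"] = SpikeInSet(**sp)
        if "algorithms" in raw:
            raw["algorithms"] = tuple(raw["algorithms"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spikes"]["isolation_spikes"] = list(d["spikes"]["isolation_spikes"])
        d["algorithms"] = list(d["algorithms"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> dict[str, str]:
    return {
        "tool": f"mirnorm {__version__}",
        "seed": str(config.seed),
        "config": config.config_hash(),
    }


def _load_inputs(
    config: PipelineConfig,
) -> tuple[CtMatrix, SampleTable]:
    if config.simulate is not None:
        if config.simulate == "screening":
            spec = default_screening_spec(seed=config.seed)
        elif config.simulate == "validation":
            spec = default_validation_spec(seed=config.seed)
        else:
            raise PipelineError(
                f"inputs: unknown simulation cohort {config.simulate!r}"
            )
        ct, table, _ = generate_cohort(spec)
        return ct, table
    try:
        ct = read_ct_matrix(config.ct_path)
        table = read_sample_table(config.samples_path)
    except Exception as exc:
        raise PipelineError(f"inputs: {exc}") from exc
    return ct, table


def _stage(name: str):
    """Wrap stage errors so failures name the stage."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"{name}: {exc}") from exc
            return False

    return _Ctx()


def _stability_table(results, agg, provenance) -> ResultTable:
    assays = agg.assay_ids
    cols: dict[str, list] = {"assay_id": assays}
    by_alg = {r.algorithm: r for r in results}
    for alg in ("genorm", "bestkeeper", "delta_ct", "normfinder"):
        if alg in by_alg:
            val = by_alg[alg].value_of()
            rnk = by_alg[alg].rank_of()
            cols[f"{alg.replace('delta_ct', 'deltact')}_value"] = [
                val[a] for a in assays
            ]
            cols[f"{alg.replace('delta_ct', 'deltact')}_rank"] = [
                rnk[a] for a in assays
            ]
    cols["geomean_rank"] = list(agg.geomean)
    cols["rank"] = [int(r) for r in agg.final_rank]
    return ResultTable(pd.DataFrame(cols), provenance)


def _spike_qc_table(report, provenance) -> ResultTable:
    rows = []
    for c in report.spike_checks:
        for g in sorted(c.group_means):
            rows.append(
                {
                    "assay_id": c.assay_id,
                    "group": g,
                    "mean_ct": c.group_means[g],
                    "sd_ct": c.group_sds[g],
                    "p_value": c.p_value,
                    "passed": int(c.passed),
                }
            )
    return ResultTable(pd.DataFrame(rows), provenance)


def run_screening(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full screening workflow; returns a bundle manifest."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    bundle: dict = {"out_dir": str(out)}

    with _stage("inputs"):
        ct, table = _load_inputs(config)
        missing = [s for s in ct.sample_ids if s not in set(table.sample_ids)]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing[:5]}")
        write_ct_matrix(ct, out / "input_ct.csv")
        write_sample_table(table, out / "input_samples.csv")

    with _stage("calibrate"):
        offsets: dict[str, float] = {}
        if table.has_plates() and config.spikes.ipc_spike in ct.assay_ids:
            ct, offsets = interplate_calibrate(ct, table, config.spikes)
        write_result_table(
            ResultTable(
                pd.DataFrame(
                    {
                        "plate_id": sorted(offsets) or ["(none)"],
                        "offset_ct": [offsets[p] for p in sorted(offsets)] or [0.0],
                    }
                ),
                prov,
            ),
            out / "plate_offsets.csv",
        )
        bundle["plate_offsets"] = offsets

    with _stage("qc"):
        qc_report = spikein_group_check(ct, table, config.spikes, config.alpha)
        write_result_table(_spike_qc_table(qc_report, prov), out / "spikein_qc.csv")
        bundle["qc_passed"] = qc_report.all_passed

    with _stage("filter"):
        candidates = detection_filter(ct, table, config.threshold, config.spikes)
        if config.k > len(candidates):
            raise ValueError(
                f"k={config.k} exceeds the {len(candidates)} candidates "
                "passing the detection filter"
            )
        candidates = complete_candidates(ct, candidates)
        if config.k > len(candidates):
            raise ValueError(
                f"k={config.k} exceeds the {len(candidates)} complete-case candidates"
            )
        bundle["n_candidates"] = len(candidates)
        pd.DataFrame({"assay_id": candidates}).to_csv(
            out / "candidates.csv", index=False, lineterminator="\n"
        )

    with _stage("stability"):
        cand_ct = ct.subset(assays=candidates)
        results = []
        for alg in config.algorithms:
            if alg == "genorm":
                results.append(genorm(cand_ct))
            elif alg == "bestkeeper":
                results.append(bestkeeper(cand_ct))
            elif alg == "delta_ct":
                results.append(delta_ct_method(cand_ct))
            elif alg == "normfinder":
                results.append(normfinder(cand_ct, table))
        agg = comprehensive_rank(results)
        write_result_table(_stability_table(results, agg, prov), out / "stability.csv")
        bundle["best_normalizer"] = agg.best()
        bundle["final_ranking"] = agg.ordered()

    with _stage("overlap"):
        regions = top_k_overlap(results, config.k)
        rows = [
            {
                "algorithms": "+".join(sorted(key)),
                "n": len(members),
                "assays": ";".join(members),
            }
            for key, members in sorted(
                regions.items(), key=lambda kv: (-len(kv[0]), "+".join(sorted(kv[0])))
            )
        ]
        pd.DataFrame(rows).to_csv(out / "topk_overlap.csv", index=False, lineterminator="\n")
        bundle["overlap"] = {
            "+".join(sorted(k_)): v for k_, v in regions.items()
        }

    with _stage("group_tests"):
        top = agg.ordered()[: config.k]
        rows = []
        for assay in top:
            r = compare_groups_ct(ct, table, assay)
            rows.append(
                {
                    "assay_id": assay,
                    "mean_ct_bc": r.group_means["BC"],
                    "mean_ct_control": r.group_means["control"],
                    "sd_ct_bc": r.group_sds["BC"],
                    "sd_ct_control": r.group_sds["control"],
                    "t": r.t_statistic,
                    "p_value": r.p_value,
                    "significant": int(r.p_value < config.alpha),
                }
            )
        group_tests = pd.DataFrame(rows)
        write_result_table(ResultTable(group_tests, prov), out / "candidate_group_tests.csv")
        bundle["stable_candidates"] = [
            row["assay_id"] for row in rows if not row["significant"]
        ]

    with _stage("relquant"):
        target = config.target
        relquant_rows = []
        if target is not None and target in ct.assay_ids:
            for ref in top:
                if ref == target:
                    continue
                rq = ddct_relative_quant(ct, table, target, ref, config.baseline_group)
                try:
                    at = anova_tukey(rq, table, scheme="full")
                    p_omni = at.p_omnibus
                except ExpressionError:
                    p_omni = np.nan
                for _, row in rq.group_summary.iterrows():
                    relquant_rows.append(
                        {
                            "reference": ref,
                            "group": row["group"],
                            "n": int(row["n"]),
                            "mean_rq": row["mean_rq"],
                            "sem_rq": row["sem_rq"],
                            "p_anova": p_omni,
                        }
                    )
        pd.DataFrame(
            relquant_rows
            or [],
            columns=["reference", "group", "n", "mean_rq", "sem_rq", "p_anova"],
        ).to_csv(out / "target_relquant.csv", index=False, lineterminator="\n", float_format="%.6g")
        bundle["target"] = target

    with _stage("report"):
        _write_screening_report(out, config, bundle)
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
    )
    return bundle


def _write_screening_report(out: Path, config: PipelineConfig, bundle: dict) -> None:
    stability = pd.read_csv(out / "stability.csv", comment="#")
    tests = pd.read_csv(out / "candidate_group_tests.csv", comment="#")
    best = stability.sort_values("rank").iloc[0]["assay_id"]
    lines = [
        "# Screening report",
        "",
        f"Seed: {config.seed}; config hash: {config.config_hash()}.",
        "",
        f"- Candidates passing the mean-Ct < {config.threshold:g} filter: "
        f"{bundle['n_candidates']}",
        f"- QC (spike-in group checks): {'pass' if bundle['qc_passed'] else 'FAIL'}",
        f"- Most stable candidate (comprehensive ranking): **{best}**",
        "",
        f"## Top {config.k} candidates",
        "",
        "| final rank | assay | geomean rank | BC-vs-control p | stable at "
        f"alpha={config.alpha:g} |",
        "|---|---|---|---|---|",
    ]
    top = stability.sort_values("rank").head(config.k)
    pmap = dict(zip(tests["assay_id"], tests["p_value"]))
    for _, row in top.iterrows():
        p = pmap.get(row["assay_id"], float("nan"))
        lines.append(
            f"| {int(row['rank'])} | {row['assay_id']} | "
            f"{row['geomean_rank']:.4g} | {p:.4g} | "
            f"{'yes' if p >= config.alpha else 'no'} |"
        )
    lines.append("")
    (out / "report.md").write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_validation(
    config: PipelineConfig, chosen_reference: str, out_dir: str | Path | None = None
) -> dict:
    """Validate a chosen reference in an independent cohort.

    Checks the reference's BC-vs-control stability at ``alpha`` and
    re-quantifies the target under it in every clinical-group scheme;
    schemes infeasible in the cohort (a group below two samples) are
    reported as not estimable rather than aborting.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    bundle: dict = {"out_dir": str(out), "reference": chosen_reference}

    with _stage("inputs"):
        ct, table = _load_inputs(config)
        if len(ct.sample_ids) == 0:
            raise ValueError("empty validation cohort")
        if chosen_reference not in ct.assay_ids:
            raise ValueError(f"reference {chosen_reference!r} not on the panel")
        _, det = ct.row(chosen_reference)
        if not det.all():
            bad = [s for s, d in zip(ct.sample_ids, det) if not d]
            raise ValueError(
                f"reference {chosen_reference!r} undetected in sample(s) {bad[:5]}"
            )

    with _stage("stability_check"):
        r = compare_groups_ct(ct, table, chosen_reference)
        passed = r.p_value >= config.alpha
        write_result_table(
            ResultTable(
                pd.DataFrame(
                    [
                        {
                            "assay_id": chosen_reference,
                            "mean_ct_bc": r.group_means["BC"],
                            "mean_ct_control": r.group_means["control"],
                            "t": r.t_statistic,
                            "p_value": r.p_value,
                            "passed": int(passed),
                        }
                    ]
                ),
                prov,
            ),
            out / "reference_stability.csv",
        )
        bundle["stability_passed"] = bool(passed)
        bundle["stability_p"] = r.p_value

    with _stage("relquant"):
        scheme_rows = []
        bundle["schemes"] = {}
        if config.target is not None and config.target in ct.assay_ids:
            rq = ddct_relative_quant(
                ct, table, config.target, chosen_reference, config.baseline_group
            )
            rq.per_sample.to_csv(
                out / "target_per_sample.csv", index=False, lineterminator="\n",
                float_format="%.6g",
            )
            for scheme in GROUP_SCHEMES:
                try:
                    at = anova_tukey(rq, table, scheme=scheme)
                except ExpressionError as exc:
                    scheme_rows.append(
                        {
                            "scheme": scheme,
                            "p_anova": float("nan"),
                            "note": f"not estimable: {exc}",
                        }
                    )
                    bundle["schemes"][scheme] = None
                    continue
                scheme_rows.append(
                    {"scheme": scheme, "p_anova": at.p_omnibus, "note": ""}
                )
                at.tukey.assign(scheme=scheme).to_csv(
                    out / f"tukey_{scheme.replace('-', '_')}.csv",
                    index=False,
                    lineterminator="\n",
                    float_format="%.6g",
                )
                bundle["schemes"][scheme] = at.p_omnibus
        pd.DataFrame(
            scheme_rows, columns=["scheme", "p_anova", "note"]
        ).to_csv(out / "scheme_anova.csv", index=False, lineterminator="\n", float_format="%.6g")

    with _stage("report"):
        ref_tab = pd.read_csv(out / "reference_stability.csv", comment="#")
        schemes = pd.read_csv(out / "scheme_anova.csv")
        lines = [
            "# Validation report",
            "",
            f"Reference: **{chosen_reference}**; seed {config.seed}; "
            f"config hash {config.config_hash()}.",
            "",
            f"- Stability check (BC vs control t-test): p = "
            f"{float(ref_tab['p_value'][0]):.4g} -> "
            f"{'PASS' if int(ref_tab['passed'][0]) else 'FAIL'} at alpha = "
            f"{config.alpha:g}",
            "",
            "## Target fold-change by grouping scheme",
            "",
            "| scheme | ANOVA p | note |",
            "|---|---|---|",
        ]
        for _, row in schemes.iterrows():
            p = row["p_anova"]
            p_str = f"{p:.4g}" if np.isfinite(p) else "-"
            note = row["note"] if isinstance(row["note"], str) else ""
            lines.append(f"| {row['scheme']} | {p_str} | {note} |")
        lines.append("")
        (out / "report.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
    )
    return bundle
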