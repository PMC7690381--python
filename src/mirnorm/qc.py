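"""Quality control for qPCR panels: inter-plate calibration, spike-in
group-stability checks and the candidate detection filter.

Spike-ins are synthetic non-human RNAs added at fixed amount: UniSp2/UniSp4
monitor RNA isolation, UniSp6 the reverse-transcription reaction, and the
inter-plate calibrator (IPC) aligns runs of the same panel across plates.
Because the input amount is constant, spike-in Ct must not differ between
clinical groups; a significant group effect flags a technical problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import CtMatrix, SampleTable

__all__ = [
    "SpikeInSet",
    "SpikeInCheck",
    "QCReport",
    "interplate_calibrate",
    "spikein_group_check",
    "detection_filter",
]

logger = logging.getLogger(__name__)


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class SpikeInSet:
    """Identifiers of the control assays on the panel."""

    isolation_spikes: tuple[str, ...] = ("UniSp2", "UniSp4")
    rt_spike: str = "UniSp6"
    ipc_spike: str = "spike-in 3"
    negative_control: str | None = None

    def group_checked(self) -> tuple[str, ...]:
        """Spike-ins subject to the between-group stability check."""
        return (*self.isolation_spikes, self.rt_spike)

    def all_ids(self) -> tuple[str, ...]:
        ids = [*self.isolation_spikes, self.rt_spike, self.ipc_spike]
        if self.negative_control is not None:
            ids.append(self.negative_control)
        return tuple(ids)

    def require_present(self, ct: CtMatrix, which: tuple[str, ...]) -> None:
        missing = [a for a in which if a not in ct.assay_ids]
        if missing:
            raise QCError(f"spike-in assay(s) absent from matrix: {missing}")


@dataclass
class SpikeInCheck:
    assay_id: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    p_value: float
    passed: bool


@dataclass
class QCReport:
    spike_checks: list[SpikeInCheck]
    plate_offsets: dict[str, float] = field(default_factory=dict)
    negative_detected: int | None = None
    alpha: float = 0.05

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.spike_checks)


def interplate_calibrate(
    ct: CtMatrix, samples: SampleTable, spikes: SpikeInSet
) -> tuple[CtMatrix, dict[str, float]]:
    """Align plates on the inter-plate calibrator.

    For each plate p, offset_p = mean(IPC Ct on plate p) − mean(IPC Ct over
    all wells); every Ct on plate p is reduced by offset_p, equalizing the
    IPC plate means while preserving within-plate differences exactly.
    Offsets weighted by well count sum to zero.
    """
    spikes.require_present(ct, (spikes.ipc_spike,))
    plate_of = samples.plate_of()
    missing = [s for s in ct.sample_ids if plate_of.get(s) is None]
    if missing:
        raise QCError(f"plate_id missing for sample(s): {missing[:5]}")
    ipc_vals, ipc_det = ct.row(spikes.ipc_spike)
    plates: dict[str, list[int]] = {}
    for j, s in enumerate(ct.sample_ids):
        plates.setdefault(str(plate_of[s]), []).append(j)
    for plate, cols in plates.items():
        if not ipc_det[cols].all():
            raise QCError(f"IPC {spikes.ipc_spike!r} undetected on plate {plate}")
    if len(plates) == 1:
        return ct.copy(), {next(iter(plates)): 0.0}
    grand = float(ipc_vals[ipc_det].mean())
    out = ct.copy()
    offsets: dict[str, float] = {}
    for plate, cols in plates.items():
        off = float(ipc_vals[cols].mean() - grand)
        offsets[plate] = off
        out.values[:, cols] -= off
    return out, offsets


def _anova_groups(values: list[np.ndarray]) -> float:
    """One-way ANOVA p-value with the degenerate zero-variance case mapped
    to p = 1 (no evidence of a group effect in perfectly flat data)."""
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0.0:
        return 1.0
    f, p = stats.f_oneway(*values)
    if not np.isfinite(p):
        return 1.0
    return float(p)


def spikein_group_check(
    ct: CtMatrix,
    samples: SampleTable,
    spikes: SpikeInSet,
    alpha: float = 0.05,
) -> QCReport:
    """Test each spike-in for Ct differences across clinical groups.

    A spike-in failing the one-way ANOVA at ``alpha`` indicates that
    isolation or retrotranscription efficiency varied systematically with
    group — a technical confounder that would masquerade as biology.
    """
    spikes.require_present(ct, spikes.group_checked())
    group_of = samples.group_of()
    checks: list[SpikeInCheck] = []
    for assay in spikes.group_checked():
        vals, det = ct.row(assay)
        by_group: dict[str, list[float]] = {}
        for j, s in enumerate(ct.sample_ids):
            if det[j]:
                by_group.setdefault(group_of[s], []).append(float(vals[j]))
        usable = {g: np.asarray(v) for g, v in by_group.items() if len(v) >= 2}
        if len(usable) < 2:
            raise QCError(
                f"spike-in {assay!r}: need >=2 groups with >=2 samples"
            )
        p = _anova_groups(list(usable.values()))
        checks.append(
            SpikeInCheck(
                assay_id=assay,
                group_means={g: float(v.mean()) for g, v in usable.items()},
                group_sds={g: float(v.std(ddof=1)) for g, v in usable.items()},
                p_value=p,
                passed=p >= alpha,
            )
        )
    neg = None
    if spikes.negative_control is not None:
        spikes.require_present(ct, (spikes.negative_control,))
        _, det = ct.row(spikes.negative_control)
        neg = int(det.sum())
    return QCReport(spike_checks=checks, negative_detected=neg, alpha=alpha)


def detection_filter(
    ct: CtMatrix,
    samples: SampleTable,
    threshold: float = 35.0,
    spikes: SpikeInSet | None = None,
) -> list[str]:
    """Candidate normalizers: assays with mean detected Ct strictly below
    ``threshold`` both in pooled tumor samples and in controls.

    Spike-ins and negative controls never qualify.  Assays with zero
    detected wells in either partition are excluded (and logged).  Output
    preserves the matrix's assay order.
    """
    excluded_ids = set(spikes.all_ids()) if spikes is not None else set()
    sample_pos = {s: j for j, s in enumerate(ct.sample_ids)}
    bc_cols = [sample_pos[s] for s in samples.bc_samples() if s in sample_pos]
    ctrl_cols = [
        sample_pos[s] for s in samples.control_samples() if s in sample_pos
    ]
    candidates: list[str] = []
    for i, assay in enumerate(ct.assay_ids):
        if assay in excluded_ids:
            continue
        keep = True
        for cols in (bc_cols, ctrl_cols):
            det = ct.detected[i, cols]
            if not det.any():
                logger.info(
                    "detection_filter: %r has no detected wells in a "
                    "partition; excluded",
                    assay,
                )
                keep = False
                break
            if not float(ct.values[i, cols][det].mean()) < threshold:
                keep = False
                break
        if keep:
            candidates.append(assay)
    return candidates
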