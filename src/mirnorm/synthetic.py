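"""Seeded synthetic urine-qPCR cohorts with known ground truth.

The generative model mirrors the structure the stability analysis assumes:

    Ct_ij = mu_i + group_offset_i(g(j)) + s_j + eps_ij

with a per-sample technical offset s_j ~ N(0, sample_effect_sd^2) shared by
every assay of sample j (pipetting/input variation — exactly what a
normalizer exists to cancel), assay noise eps_ij ~ N(0, sigma_i^2), and
group offsets encoding disease-dependent expression (a negative Ct shift is
higher expression).  Wells beyond the censoring threshold are recorded as
undetected, emulating the instrument's late-cycle cutoff.  Everything is
reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import GROUP_LABELS, CtMatrix, SampleTable
import pandas as pd

__all__ = [
    "AssayModel",
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "default_screening_spec",
    "default_validation_spec",
]

ROLES = ("stable", "endogenous", "target", "spikein", "ipc", "negative")


@dataclass(frozen=True)
class AssayModel:
    """One assay's generative parameters."""

    assay_id: str
    baseline_ct: float  # mu_i, cycles
    sigma: float  # residual noise SD, cycles
    group_offsets: dict[str, float] = field(default_factory=dict)
    role: str = "endogenous"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"{self.assay_id}: sigma must be >= 0")
        if self.role not in ROLES:
            raise ValueError(f"{self.assay_id}: unknown role {self.role!r}")
        bad = sorted(set(self.group_offsets) - set(GROUP_LABELS))
        if bad:
            raise ValueError(f"{self.assay_id}: unknown group(s) {bad}")

    def offset(self, group: str) -> float:
        return self.group_offsets.get(group, 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort."""

    n_per_group: dict[str, int]
    assays: tuple[AssayModel, ...]
    sample_effect_sd: float = 1.0
    censor_threshold: float = 40.0
    seed: int = 0
    cohort: str = "screening"
    n_plates: int = 1

    def __post_init__(self) -> None:
        bad = sorted(set(self.n_per_group) - set(GROUP_LABELS))
        if bad:
            raise ValueError(f"unknown group label(s): {bad}")
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 1")
        if self.sample_effect_sd < 0:
            raise ValueError("sample_effect_sd must be >= 0")
        if self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")
        ids = [a.assay_id for a in self.assays]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate assay ids in spec")
        if not self.assays:
            raise ValueError("spec contains no assays")

    @property
    def n_assays(self) -> int:
        return len(self.assays)

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_group.values())

    def assays_with_role(self, role: str) -> list[str]:
        return [a.assay_id for a in self.assays if a.role == role]

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What the generator actually drew, for oracle-style tests."""

    designated_normalizer: str | None
    target_assay: str | None
    target_effects: dict[str, float]
    group_offsets: dict[str, dict[str, float]]  # assay -> group -> Ct shift
    sample_effects: dict[str, float]  # sample -> s_j


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[CtMatrix, SampleTable, GroundTruth]:
    """Draw one cohort from the spec's generative model.

    ``seed`` overrides ``spec.seed`` when given.  Samples are named
    ``<group>_<k>``, assigned to plates round-robin; wells with Ct above
    the censoring threshold come back undetected.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    groups: list[str] = []
    sample_ids: list[str] = []
    for g, n in spec.n_per_group.items():
        for k in range(1, n + 1):
            groups.append(g)
            sample_ids.append(f"{g}_{k:03d}")
    n_s = len(sample_ids)
    n_a = spec.n_assays
    s_j = rng.normal(0.0, spec.sample_effect_sd, size=n_s)
    values = np.empty((n_a, n_s))
    for i, assay in enumerate(spec.assays):
        offs = np.array([assay.offset(g) for g in groups])
        eps = rng.normal(0.0, assay.sigma, size=n_s) if assay.sigma > 0 else 0.0
        values[i] = assay.baseline_ct + offs + s_j + eps
    detected = values <= spec.censor_threshold
    values_out = np.where(detected, values, np.nan)
    ct = CtMatrix([a.assay_id for a in spec.assays], sample_ids, values_out, detected)
    plate_ids = [f"P{(j % spec.n_plates) + 1}" for j in range(n_s)]
    table = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "cohort": spec.cohort,
                "plate_id": plate_ids,
            }
        )
    )
    stable = spec.assays_with_role("stable")
    targets = spec.assays_with_role("target")
    target_model = next(
        (a for a in spec.assays if a.role == "target"), None
    )
    truth = GroundTruth(
        designated_normalizer=stable[0] if stable else None,
        target_assay=targets[0] if targets else None,
        target_effects=dict(target_model.group_offsets) if target_model else {},
        group_offsets={
            a.assay_id: dict(a.group_offsets) for a in spec.assays
        },
        sample_effects=dict(zip(sample_ids, s_j)),
    )
    return ct, table, truth


def _severity_offsets(amplitude: float) -> dict[str, float]:
    """A monotone-with-severity expression increase (negative Ct shift),
    strongest in T1G3, scaled by ``amplitude``."""
    shape = {
        "control": 0.0,
        "TaG1": -0.25,
        "TaG2": -0.35,
        "TaG3": -0.5,
        "T1G2": -0.6,
        "T1G3": -1.0,
        "T2G2": -0.6,
        "T2G3": -0.7,
        "T3G3": -0.7,
    }
    return {g: v * amplitude for g, v in shape.items() if v != 0.0}


def _panel_assays() -> tuple[AssayModel, ...]:
    """A 40-assay panel: one designated stable normalizer, a
    severity-responsive target, 33 unstable endogenous competitors (group
    effects of 0.5-2 Ct and/or noise SD >= 0.8, a few expressed too late to
    pass the detection filter), four spike-ins and a negative control."""
    assays: list[AssayModel] = [
        AssayModel("miR-ref-01", 28.0, 0.10, {}, role="stable"),
        AssayModel(
            "miR-tgt-01",
            26.0,
            0.40,
            {
                "TaG1": -0.5,
                "TaG2": -0.7,
                "TaG3": -1.0,
                "T1G2": -1.2,
                "T1G3": -1.5,
                "T2G2": -1.0,
                "T2G3": -1.0,
                "T3G3": -1.0,
            },
            role="target",
        ),
    ]
    # unstable competitors: cycle through noise-driven and bias-driven modes
    for k in range(1, 34):
        mu = 21.0 + 0.35 * k
        if k in (31, 32, 33):  # low-abundance assays the Ct filter removes
            mu = 35.5 + 0.8 * (k - 31)
        if k % 2 == 1:
            sigma = 0.8 + 0.1 * (k % 5)  # pure-noise instability
            offs: dict[str, float] = {}
        else:
            sigma = 0.3
            amp = 0.5 + 0.5 * ((k // 2 - 1) % 4)  # 0.5 .. 2.0 Ct
            # alternate up-/down-regulation so dysregulated genes do not
            # share one pattern and mutually cancel in pairwise differences
            sign = 1.0 if k % 4 == 0 else -1.0
            offs = _severity_offsets(sign * amp)
        assays.append(AssayModel(f"miR-u{k:02d}", mu, sigma, offs))
    assays += [
        AssayModel("UniSp2", 19.0, 0.15, {}, role="spikein"),
        AssayModel("UniSp4", 24.0, 0.15, {}, role="spikein"),
        AssayModel("UniSp6", 21.0, 0.12, {}, role="spikein"),
        AssayModel("spike-in 3", 20.0, 0.05, {}, role="ipc"),
        AssayModel("neg-ctrl", 45.0, 0.0, {}, role="negative"),
    ]
    return tuple(assays)


def default_screening_spec(seed: int = 0) -> CohortSpec:
    """Screening-stage cohort: 15 controls and 35 tumor samples
    (10 TaG1, 8 TaG3, 5 T1G3, 12 T2G3) on the 40-assay panel above plus a
    negative control, with 1.0-Ct per-sample technical variation."""
    return CohortSpec(
        n_per_group={
            "control": 15,
            "TaG1": 10,
            "TaG3": 8,
            "T1G3": 5,
            "T2G3": 12,
        },
        assays=_panel_assays(),
        sample_effect_sd=1.0,
        censor_threshold=40.0,
        seed=seed,
        cohort="screening",
        n_plates=2,
    )


def default_validation_spec(seed: int = 0) -> CohortSpec:
    """Validation-stage cohort: 57 controls and 153 tumor samples spanning
    the full stage/grade spectrum (33 TaG1, 54 TaG2, 13 TaG3, 9 T1G2,
    29 T1G3, 4 T2G2, 10 T2G3, 1 T3G3)."""
    return CohortSpec(
        n_per_group={
            "control": 57,
            "TaG1": 33,
            "TaG2": 54,
            "TaG3": 13,
            "T1G2": 9,
            "T1G3": 29,
            "T2G2": 4,
            "T2G3": 10,
            "T3G3": 1,
        },
        assays=_panel_assays(),
        sample_effect_sd=1.0,
        censor_threshold=40.0,
        seed=seed,
        cohort="validation",
        n_plates=4,
    )
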