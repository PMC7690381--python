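"""Generate a synthetic screening cohort and look at its structure.

The generator draws Ct values from mu_i + group_offset + sample_offset +
noise, censoring late cycles as undetected — the structure a normalizer
search assumes about real urine qPCR panels.
"""

import numpy as np

from mirnorm import default_screening_spec, generate_cohort

spec = default_screening_spec(seed=1)
ct, samples, truth = generate_cohort(spec)

print(f"panel: {ct.n_assays} assays x {ct.n_samples} samples")
counts = samples.frame["group"].value_counts().sort_index()
print(f"groups: {{{', '.join(f'{g}: {int(n)}' for g, n in counts.items())}}}")
print(f"designated stable normalizer: {truth.designated_normalizer}")
print(f"target assay: {truth.target_assay} with Ct offsets {truth.target_effects}")

vals, det = ct.row(truth.designated_normalizer)
print(
    f"{truth.designated_normalizer}: mean Ct {vals[det].mean():.2f}, "
    f"SD {vals[det].std(ddof=1):.2f} (SD is dominated by the shared "
    "per-sample offset the normalizer will cancel)"
)
undetected = int((~ct.detected).sum())
print(f"undetected wells (late-Ct censoring): {undetected}")
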