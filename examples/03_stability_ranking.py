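"""Rank candidate normalizers with the four stability algorithms and
aggregate them into a comprehensive ranking.

Each algorithm returns a stability value per candidate (lower = more
stable); the aggregate ranking is the geometric mean of the four ranks.
"""

from mirnorm import (
    SpikeInSet,
    bestkeeper,
    complete_candidates,
    comprehensive_rank,
    default_screening_spec,
    delta_ct_method,
    detection_filter,
    generate_cohort,
    genorm,
    normfinder,
    top_k_overlap,
)

ct, samples, truth = generate_cohort(default_screening_spec(seed=1))
candidates = complete_candidates(
    ct, detection_filter(ct, samples, 35.0, SpikeInSet())
)
sub = ct.subset(assays=candidates)

results = [genorm(sub), bestkeeper(sub), delta_ct_method(sub), normfinder(sub, samples)]
for r in results:
    best = min(zip(r.values, r.assay_ids))
    print(f"{r.algorithm:>10}: most stable = {best[1]} (value {best[0]:.3f})")
print("geNorm final pair:", results[0].extras["final_pair"])

agg = comprehensive_rank(results)
print("\ncomprehensive ranking (top 5):")
for assay in agg.ordered()[:5]:
    print(f"  rank {agg.rank_of()[assay]}: {assay} (geomean {dict(zip(agg.assay_ids, agg.geomean))[assay]:.2f})")
print(f"planted stable assay was {truth.designated_normalizer}")

regions = top_k_overlap(results, k=10)
four_way = regions.get(frozenset(r.algorithm for r in results), [])
print(f"\nassays in all four top-10 lists: {four_way}")
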