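"""Build one subject's T1 and ASL networks and vectorise them into features.

The T1 network is a Gaussian kernel of regional mean cortical thickness
(weights in (0, 1]); the ASL network is the Pearson correlation of per-region
CBF quantile descriptors (weights in [-1, 1]). Both are 78x78, symmetric with
unit diagonal, and flatten to 3003 upper-triangle edge features each.
"""

from brainnetdx import (
    CohortConfig,
    cbf_network,
    gm_network,
    regional_summaries,
    simulate_cohort,
    upper_triangle_vector,
)

subject = simulate_cohort(CohortConfig(n_asd=2, n_td=2, base_seed=1))[0]
summaries = regional_summaries(subject, q=50)

t1 = gm_network(summaries)
asl = cbf_network(summaries)
print(f"T1 network:  {t1.weights.shape}, entries in "
      f"[{t1.weights.min():.4f}, {t1.weights.max():.4f}]")
print(f"ASL network: {asl.weights.shape}, entries in "
      f"[{asl.weights.min():.4f}, {asl.weights.max():.4f}]")

vec, meta = upper_triangle_vector(t1)
print(f"edge features per modality: {len(vec)}")
modality, a, b = meta[0]
print(f"first edge ({modality}, regions {a}-{b}): similarity {vec[0]:.4f}")
print(f"region 0 summary: mean thickness {summaries[0].mean_thickness:.3f} mm, "
      f"SD {summaries[0].sd_thickness:.3f} mm, "
      f"{summaries[0].cbf_quantiles.size} CBF quantiles")
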