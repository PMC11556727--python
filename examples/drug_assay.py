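"""A two-arm Golgi-perturbation assay on matched phantoms.

Generates matched control and brefeldin-A spheroids (same seeds, identical
pipeline), measures per-cell Golgi fragment counts and EGFP-Rab6A footprint
areas in both arms, and runs the assay statistics: the Kolmogorov-Smirnov
normality check (single-cell data are not normal), then the unpaired
two-sample Wilcoxon rank-sum comparison.
"""

from spheroquant.recovery import run_arm
from spheroquant.stats import assay_report, ks_normality

N = 3  # phantoms per arm; increase for tighter estimates

control, _ = run_arm(base_seed=11, n_phantoms=N, phenotype="control",
                     channels=("golgi",), egfp_model="rab6a_golgi")
bfa, _ = run_arm(base_seed=11, n_phantoms=N, phenotype="bfa",
                 channels=("golgi",), egfp_model="rab6a_golgi")

frag_c = control["golgi_fragment_count"]
frag_b = bfa["golgi_fragment_count"]
ks = ks_normality(frag_c.to_numpy())
print(f"cells: {len(frag_c)} control, {len(frag_b)} BFA")
print(f"normality of control fragment counts: KS p = {ks.p_value:.3g} "
      f"(-> rank-based comparison)")

table, text = assay_report(frag_c, frag_b, "control", "BFA")
print("\nGolgi fragment count per cell:")
print(f"  {text}")

table, text = assay_report(control["egfp_footprint_um2"],
                           bfa["egfp_footprint_um2"], "control", "BFA")
print("\nEGFP-Rab6A footprint area per cell:")
print(f"  {text}")
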