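"""Compute dual-isotope lung targeting factors over replicate sections.

Per compartment: mean drug intensity / plasma concentration, per route; the
targeting factor is the inhaled-to-IV ratio of these normalized exposures —
the fold gain in local exposure bought by inhaled delivery at matched
systemic exposure.  Ground truth here is 5 / 31 / 45 fold for alveolar /
sub-epithelium / epithelium.
"""

from lungtarget import compute_targeting_report, default_scenario, simulate_replicates
from lungtarget.analytes import by_role
from lungtarget.pipeline import analyze_section
from lungtarget.targeting import plot_targeting_report

scenario = default_scenario()
analytes = scenario.analyte_definitions()

sections = [
    analyze_section(dataset, analytes, k=6, seed=7 + i)
    for i, (dataset, _truth) in enumerate(simulate_replicates(scenario, 3, seed=7))
]
report = compute_targeting_report(
    sections,
    by_role(analytes, "drug_inhaled"),
    by_role(analytes, "drug_iv"),
    plasma=scenario.plasma,
)

print(f"n = {report.n_replicates} replicate sections")
for compartment, tf in report.factors.items():
    sd = report.factors_sd[compartment]
    true_tf = scenario.ground_truth_tf[compartment]
    print(f"  {compartment:16s} TF = {tf:5.1f} ± {sd:4.1f}   (truth {true_tf:.0f})")
print(f"  whole section    TF = {report.section_level_factor:5.1f}")
# recovered factors sit within a few percent of the simulated ground truth,
# with segmentation-derived (not ground-truth) ROIs

from pathlib import Path

Path("scratch").mkdir(exist_ok=True)
plot_targeting_report(report, "scratch/targeting.png")
print("wrote scratch/targeting.png (three-panel bar chart)")
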