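"""Quantify distribution heterogeneity (RSD) and marker colocalization.

An inhaled aerosol deposits patchily, so its pixel-to-pixel relative standard
deviation is far higher than that of the same drug arriving evenly through
the blood.  Pearson correlation against endogenous markers shows which
histological structure each route targets.
"""

from lungtarget import (
    compute_tissue_mask,
    correlation_table,
    default_scenario,
    extract_ion_image,
    pixel_rsd,
    simulate_msi,
    tic_normalize,
)
from lungtarget.analytes import by_role

scenario = default_scenario()
dataset, _truth = simulate_msi(scenario, seed=42)
normalized = tic_normalize(dataset)
mask = compute_tissue_mask(dataset=dataset)
print(f"tissue mask: {mask.n_pixels} on-tissue pixels")

analytes = scenario.analyte_definitions()
roles = ("drug_inhaled", "drug_iv", "marker_alveolar", "marker_bronchiolar", "marker_vessel")
images = {r: extract_ion_image(normalized, by_role(analytes, r)) for r in roles}

for route in ("drug_inhaled", "drug_iv"):
    rsd = pixel_rsd(images[route], mask.grid, route=route)
    print(f"{route:13s} RSD = {rsd.rsd_percent:6.1f}%  ({rsd.n_pixels} pixels)")
# the inhaled channel is several-fold more heterogeneous than the IV channel

table = correlation_table(images, mask.grid)
print("\nPearson correlation (%) over the tissue mask:")
print(table.round(0).to_string())
# the inhaled drug correlates best with the bronchiolar marker, the IV drug
# with the alveolar marker - route determines the targeted structure
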