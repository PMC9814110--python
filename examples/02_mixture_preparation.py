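"""Concentration-preparation arithmetic for the CMIT/MIT biocide mixture.

The 3:1 CMIT/MIT mixture has no single molecular weight and only 14.2%
combined active ingredient, so tested concentrations need a weighted-MW and
purity correction before endpoints are comparable across chemicals.
"""

from sensipod import (default_mw_concentration_correction, hclat_dose_series,
                      purity_adjust, round_sig, weighted_mw)
from sensipod.datasets import (CMIT_MIT_COMPONENTS, CMIT_MIT_PURITY,
                               DEFAULT_MW_ASSUMPTION)

mw = weighted_mw(CMIT_MIT_COMPONENTS)
print(f"weighted MW of CMIT/MIT:            {mw:.2f} g/mol")

# KeratinoSens working solution was prepared assuming MW 200 g/mol; the true
# starting molar concentration corrects 2000 uM by purity and the MW ratio.
start_um = default_mw_concentration_correction(
    2000.0, CMIT_MIT_PURITY, mw / DEFAULT_MW_ASSUMPTION)
print(f"corrected KeratinoSens start:       {start_um:.1f} uM")

# h-CLAT: starting concentration is 1.2 x CV75 (CV75 21.4 ug/mL as prepared),
# then adjusted to active-ingredient terms by the 14.2% purity.
start = hclat_dose_series(21.4, "PBS")[0]
print(f"h-CLAT start (1.2 x CV75):          {round_sig(start, 3)} ug/mL")
print(f"purity-adjusted h-CLAT start:       {round_sig(purity_adjust(start, CMIT_MIT_PURITY), 3)} ug/mL")

# 141.36 g/mol, 401.8 uM, 25.7 -> 3.65 ug/mL: the as-tested concentrations
# that enter the endpoint calculators for the mixture.
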