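"""Score a qPCR-based DamID (qDamID) site panel.

Per site: % methylation = digested / undigested x 100 (DpnII cuts only
unmethylated GATC, so surviving template measures methylation), then
POI enrichment = the site's share of total methylation in Dam-POI
minus its share in Dam-only.
"""

import pandas as pd

from damidcall.qdamid import qdamid_profile

measurements = pd.DataFrame({
    "site":       ["GATC_1", "GATC_1", "GATC_2", "GATC_2", "GATC_3", "GATC_3"],
    "condition":  ["Dam", "POI", "Dam", "POI", "Dam", "POI"],
    "digested":   [10.0, 45.0, 40.0, 40.0, 30.0, 15.0],
    "undigested": [100.0, 100.0, 100.0, 100.0, 100.0, 100.0],
})

profile = qdamid_profile(measurements)
print(profile.to_string(index=False))
print(f"\nsubtract scores sum to {profile['subtract'].sum():+.2e}"
      " (zero by construction)")

# A positive subtract score marks a site where the Dam-POI fusion
# methylates more than untethered Dam — i.e. candidate POI binding.
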