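"""qPCR-based DamID (qDamID) quantification.

Genomic DNA from Dam-only and Dam-POI cells is split into a DpnII-
digested (+DpnII) and an undigested (-DpnII) aliquot; DpnII cuts only
*unmethylated* GATC, so the fraction of template surviving digestion at
a site measures its adenine-methylation level:

    %GATC_x = digested / undigested * 100

POI enrichment at site x is then expressed as the difference of the
site's normalized share between the two conditions:

    subtract_x = %x(POI) / sum_i %i(POI) - %x(Dam) / sum_i %i(Dam)

Shares cancel any condition-wide scaling, and the subtract scores over
the assayed site panel sum to zero by construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "percent_methylation",
    "damid_subtract",
    "qdamid_profile",
    "read_qpcr_csv",
]

PCT_FLAG_LIMIT = 120.0  # percentages above this are flagged as suspect

def percent_methylation(digested, undigested):
    """Percent methylation at a site: digested / undigested * 100.

    Both quantities are absolute template amounts from the qPCR
    standard curve (triplicate-averaged upstream); any shared unit
    cancels.  Values can exceed 100 with measurement noise.
    """
    digested = np.asarray(digested, dtype=float)
    undigested = np.asarray(undigested, dtype=float)
    if np.any(undigested <= 0):
        raise ValueError("undigested quantity must be positive "
                         "(percent methylation undefined)")
    if np.any(digested < 0):
        raise ValueError("digested quantity must be non-negative")
    pct = digested / undigested * 100.0
    if np.any(pct > PCT_FLAG_LIMIT):
        logger.warning("percent methylation above %g%% at %d site(s); "
                       "check the qPCR quantities", PCT_FLAG_LIMIT,
                       int(np.sum(pct > PCT_FLAG_LIMIT)))
    return pct if pct.ndim else float(pct)

def damid_subtract(percent_poi: np.ndarray, percent_dam: np.ndarray) -> np.ndarray:
    """Per-site enrichment of the POI fusion over untethered Dam.

    Difference of normalized shares over the same site panel; scores
    sum to zero across sites.
    """
    poi = np.asarray(percent_poi, dtype=float)
    dam = np.asarray(percent_dam, dtype=float)
    if poi.shape != dam.shape:
        raise ValueError("site panels differ between conditions")
    total_poi = poi.sum()
    total_dam = dam.sum()
    if total_poi <= 0:
        raise ValueError("total percent methylation is zero in condition POI")
    if total_dam <= 0:
        raise ValueError("total percent methylation is zero in condition Dam")
    return poi / total_poi - dam / total_dam

def read_qpcr_csv(path) -> pd.DataFrame:
    """CSV with columns site, condition (Dam|POI), digested, undigested.

    Replicate rows per (site, condition) are averaged, matching the
    triplicate-mean convention of the assay.
    """
    df = pd.read_csv(path)
    required = {"site", "condition", "digested", "undigested"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    bad = set(df["condition"]) - {"Dam", "POI"}
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}; expected Dam/POI")
    return (df.groupby(["site", "condition"], sort=False, as_index=False)
              [["digested", "undigested"]].mean())

def qdamid_profile(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-site percent methylation and subtract score table.

    Input columns: site, condition, digested, undigested (one row per
    site per condition, or replicates to be averaged).  Output: site,
    pct_dam, pct_poi, subtract.
    """
    df = (measurements.groupby(["site", "condition"], sort=False, as_index=False)
          [["digested", "undigested"]].mean())
    wide_d = df.pivot(index="site", columns="condition", values="digested")
    wide_u = df.pivot(index="site", columns="condition", values="undigested")
    for cond in ("Dam", "POI"):
        if cond not in wide_d.columns or wide_d[cond].isna().any():
            raise ValueError(f"missing measurements for condition {cond!r}")
    sites = wide_d.index.to_list()
    pct_dam = percent_methylation(wide_d["Dam"].to_numpy(),
                                  wide_u["Dam"].to_numpy())
    pct_poi = percent_methylation(wide_d["POI"].to_numpy(),
                                  wide_u["POI"].to_numpy())
    sub = damid_subtract(pct_poi, pct_dam)
    return pd.DataFrame({"site": sites, "pct_dam": pct_dam,
                         "pct_poi": pct_poi, "subtract": sub})
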