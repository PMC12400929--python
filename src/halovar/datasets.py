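"""Small published reference tables carried as package data.

These are inputs (printed study values), not results computed here.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["MESOCOSM_D13_ENDPOINTS", "endpoint_fold_changes"]

#: Relative abundance (percent of the total community) of the four
#: Hqr. walsbyi genomovars in the intensely disturbed (D13) mesocosm at
#: day 0 and day 813, as reported for the competitive read recruitment.
MESOCOSM_D13_ENDPOINTS = pd.DataFrame(
    {"day0": [10.5, 7.3, 6.4, 1.6], "day813": [0.2, 1.1, 0.1, 0.1]},
    index=["Hqrw1", "Hqrw2", "Hqrw3", "Hqrw4"],
)


def endpoint_fold_changes(endpoints: pd.DataFrame = MESOCOSM_D13_ENDPOINTS) -> pd.DataFrame:
    """Fold changes implied by endpoint abundances: each genomovar's
    decline (day0/day813) and its final dominance relative to Hqrw1."""
    out = pd.DataFrame(index=endpoints.index)
    out["decline_fold"] = endpoints["day0"] / endpoints["day813"]
    out["final_vs_hqrw1_fold"] = endpoints["day813"] / endpoints.loc["Hqrw1", "day813"]
    return out
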