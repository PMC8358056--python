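"""Packaged reference data.

The bundled membership matrix is the published comprehensive-evaluation
table for ten *Iris germanica* cultivars: membership degrees for six
physiological indices (Chl, REC, SOD, MDA, SP, Pro) after drought stress.
It is shipped so the composite scoring and ranking can be reproduced
exactly without any raw assay data.
"""

from __future__ import annotations

import pandas as pd

from .membership import MembershipTable

_IRIS_INDICES = ["Chl", "REC", "SOD", "MDA", "SP", "Pro"]

# Row order follows the published table.
_IRIS_MEMBERSHIPS = {
    "Cherry Garden": [0.00, 0.89, 0.83, 0.25, 0.96, 0.84],
    "Tantara": [0.55, 1.00, 0.00, 0.00, 1.00, 0.03],
    "Blood Stone": [0.89, 0.20, 0.87, 0.15, 0.93, 0.82],
    "Music Box": [0.58, 0.77, 0.70, 0.16, 0.90, 0.84],
    "Memory of Harvest": [0.72, 0.01, 0.36, 1.00, 0.37, 0.60],
    "Clarence": [0.60, 0.89, 0.22, 0.50, 0.00, 0.08],
    "X'Brassie": [1.00, 0.18, 0.92, 0.17, 0.69, 1.00],
    "Little Dream": [0.78, 0.16, 1.00, 0.59, 0.91, 0.58],
    "Immortality": [0.27, 0.87, 0.91, 0.27, 0.66, 0.02],
    "White and Gold": [0.95, 0.00, 0.74, 0.56, 0.62, 0.00],
}


def load_iris_membership() -> MembershipTable:
    """The published 10 x 6 cultivar membership matrix, ready to score."""
    df = pd.DataFrame.from_dict(
        _IRIS_MEMBERSHIPS, orient="index", columns=_IRIS_INDICES
    )
    return MembershipTable(memberships=df, source="supplied")
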