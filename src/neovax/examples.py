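"""Worked-example inputs used in the documentation and smoke checks.

``WORKED_EXAMPLE_SCORES`` holds the published normalized seven-variable
scores of the six neoantigens selected for one cutaneous-melanoma
patient — the standard worked example for the score-table bypass of the
design pipeline. Rows are in the original publication order, which the
assembly step preserves.
"""

from __future__ import annotations

import pandas as pd

#: columns: neoantigen, imm, hlaI, hlaII, hpl, tap, ap, vf (all normalized)
WORKED_EXAMPLE_SCORES: tuple[tuple[str, float, float, float, float, float, float, float], ...] = (
    ("DWLEWLRQLSLELLK", 0.556, 0.875, 1.000, 0.366, 0.722, 0.516, 0.199),
    ("FRDQSLSYHHTMVVQ", 0.335, 1.000, 0.000, 0.501, 0.558, 0.453, 0.304),
    ("IGRFANYFRNLLPSN", 0.851, 0.665, 0.529, 0.410, 0.567, 0.555, 0.333),
    ("MRHSFFSEVNWQDVY", 0.878, 0.000, 0.452, 0.535, 0.720, 0.427, 0.339),
    ("RLFMHHVFLEPITCV", 1.000, 0.366, 0.432, 0.000, 0.603, 0.000, 0.762),
    ("CSRRFYQFTKLLDSV", 0.518, 0.562, 0.788, 0.398, 0.608, 0.379, 0.466),
)


def worked_example_table() -> pd.DataFrame:
    """The worked example as a normalized score table indexed by
    neoantigen, columns in ScoreVector order (imm, hlaI, hlaII, vf, ap,
    hpl, tap)."""
    df = pd.DataFrame(
        WORKED_EXAMPLE_SCORES,
        columns=["neoantigen", "imm", "hlaI", "hlaII", "hpl", "tap", "ap", "vf"],
    ).set_index("neoantigen")
    return df[["imm", "hlaI", "hlaII", "vf", "ap", "hpl", "tap"]]
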