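"""Published long-axis group displacement reference table.

Per-segment, per-border group means and SDs (mm) of the overall,
longitudinal and radial maximum displacements for the four LV-function
groups, as reported by the motion study.  Used as the default input to
the margin constructors when no fitted displacement data is supplied.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_TABLE = None


def reference_displacements() -> pd.DataFrame:
    """The bundled group displacement table (long-axis components)."""
    global _TABLE
    if _TABLE is None:
        with resources.files("lvmotion.data").joinpath(
                "reference_displacements.csv").open() as fh:
            _TABLE = pd.read_csv(fh)
    return _TABLE.copy()


def segment_means(group: str, segment: int) -> dict:
    """Displacement means for one group/segment as margin-constructor input.

    Returns ``{"epi": (longitudinal, radial), "endo": (longitudinal,
    radial)}``; segment 17 has no endocardial points and raises.
    """
    tab = reference_displacements()
    out = {}
    for border in ("epi", "endo"):
        vals = {}
        for comp in ("longitudinal", "radial"):
            row = tab[(tab["component"] == comp) & (tab["segment"] == segment)
                      & (tab["border"] == border)]
            if row.empty:
                raise ValueError(
                    f"no reference data for segment {segment} {border} "
                    f"({comp}); segment 17 has no endocardial points")
            vals[comp] = float(row[f"{group}_mean"].iloc[0])
        out[border] = (vals["longitudinal"], vals["radial"])
    return out
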