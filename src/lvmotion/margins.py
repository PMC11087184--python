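"""ITV margin construction from segment displacement means.

Two image-matching strategies are supported:

* ``whole_lv_match`` — the end-diastolic LV is matched to the blurred
  average image, so the epicardial border already sits at the outer edge
  of the motion envelope.  The full endocardial radial displacement is
  applied inward and the full longitudinal displacements apically; no
  outer or basal margin (the wall moves predominantly towards the
  central axis and apex from end-diastole).
* ``target_centered`` — the target is matched to the centre of the
  blurred wall, so half of each mean displacement is applied in both
  radial directions and both longitudinal directions.

``combined_margin`` reproduces the cardiac + respiratory + setup margin
arithmetic: each motion extent is halved and rounded to 0.1 mm *before*
summing, then the setup margin is added.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

STRATEGIES = ("whole_lv_match", "target_centered")


@dataclass
class MarginSpec:
    """Directional ITV margins (mm) for one segment and strategy."""

    outer_epi: float
    inner_endo: float
    apical_epi: float
    apical_endo: float
    basal_epi: float
    basal_endo: float
    strategy: str

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for name, v in asdict(self).items():
            if name != "strategy" and v < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _check_disp(disp: dict) -> None:
    for border in ("epi", "endo"):
        if border not in disp:
            raise ValueError(f"missing {border!r} displacements")
        longitudinal, radial = disp[border]
        if longitudinal < 0 or radial < 0:
            raise ValueError("displacements must be nonnegative")


def itv_whole_lv_match(disp: dict, assume_inward_apical: bool = True
                       ) -> MarginSpec:
    """Margins when the entire LV is matched on the average image.

    ``disp`` maps border -> (longitudinal mean, radial mean) in mm.
    With ``assume_inward_apical`` (default) the wall is taken to move
    only towards the central axis and apex from end-diastole, so no
    outer or basal margin is applied; disabling it applies the full
    displacements on all sides for atypical motion patterns.
    """
    _check_disp(disp)
    epi_long, epi_radial = disp["epi"]
    endo_long, endo_radial = disp["endo"]
    inward = assume_inward_apical
    return MarginSpec(
        outer_epi=0.0 if inward else epi_radial,
        inner_endo=endo_radial,
        apical_epi=epi_long,
        apical_endo=endo_long,
        basal_epi=0.0 if inward else epi_long,
        basal_endo=0.0 if inward else endo_long,
        strategy="whole_lv_match",
    )


def itv_target_centered(disp: dict) -> MarginSpec:
    """Margins when the target is matched to the blurred wall centre.

    Each mean displacement is halved and applied in the corresponding
    radial and longitudinal directions; halves are kept at two-decimal
    precision (e.g. 6.1 mm -> 3.05 mm).
    """
    _check_disp(disp)
    epi_long, epi_radial = disp["epi"]
    endo_long, endo_radial = disp["endo"]
    half = lambda x: round(x / 2.0, 2)
    return MarginSpec(
        outer_epi=half(epi_radial),
        inner_endo=half(endo_radial),
        apical_epi=half(epi_long),
        apical_endo=half(endo_long),
        basal_epi=half(epi_long),
        basal_endo=half(endo_long),
        strategy="target_centered",
    )


def combined_margin(cardiac_extent: float, respiratory_extent: float,
                    setup_margin: float) -> tuple[float, float, float, float]:
    """(cardiac, respiratory, combined ITV, total) margin components, mm.

    Each motion extent contributes half its value, rounded to 0.1 mm
    before summation; the setup (PTV) margin is added on top.
    """
    if min(cardiac_extent, respiratory_extent, setup_margin) < 0:
        raise ValueError("margin inputs must be nonnegative")
    cardiac = round(cardiac_extent / 2.0, 1)
    respiratory = round(respiratory_extent / 2.0, 1)
    itv = round(cardiac + respiratory, 10)
    total = round(itv + setup_margin, 10)
    return cardiac, respiratory, itv, total
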