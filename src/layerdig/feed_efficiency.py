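"""Laying percentage, egg mass, feed conversion ratio and residual feed consumption.

Two feed-efficiency indicators are supported:

* FCR — feed consumed per unit egg mass produced over the recording
  period; lower is more efficient. Undefined for a non-laying bird and
  reported as missing rather than infinite.
* RFC — observed feed consumption minus that predicted from daily body
  weight, egg mass and body-weight gain through a linear model,
  RFC = DFC_total - (b0 + b1*DBW + b2*EM + b3*BWG). Positive residuals
  mark birds that ate more than their production justifies. The
  b-coefficients are population- and environment-specific and must be
  supplied by the user; the shipped default is the null model (all zero),
  under which RFC is simply observed feed consumption.

Body-weight gain is taken as zero by default: over a one-week window in
adult hens it is negligible relative to feed intake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .trial_data import BirdRecord

__all__ = [
    "RFCCoefficients",
    "EfficiencyIndicators",
    "laying_percentage",
    "egg_mass",
    "fcr",
    "rfc",
    "compute_efficiency",
]


@dataclass(frozen=True)
class RFCCoefficients:
    """Linear-model coefficients for expected feed consumption.

    b0 in g; b1 per g of daily body weight; b2 per g of egg mass; b3 per g
    of body-weight gain.
    """

    b0: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0

    def __post_init__(self) -> None:
        for name in ("b0", "b1", "b2", "b3"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"RFC coefficient {name} must be finite")


@dataclass(frozen=True)
class EfficiencyIndicators:
    """Per-bird efficiency phenotypes. ``fcr`` is NaN for non-layers."""

    lp: float
    em: float
    dbw: float
    fcr: float
    rfc: float
    bwg: float = 0.0
    flags: tuple[str, ...] = ()


def laying_percentage(eggs_laid: int, expected_eggs: int) -> float:
    """Eggs laid as a percentage of eggs expected over the collection window."""
    if expected_eggs <= 0:
        raise ValueError("expected_eggs must be > 0")
    return eggs_laid / expected_eggs * 100.0


def egg_mass(mean_egg_weight: float, lp: float) -> float:
    """Daily egg mass (g/day): mean egg weight scaled by the laying percentage."""
    if mean_egg_weight < 0 or lp < 0:
        raise ValueError("mean_egg_weight and lp must be >= 0")
    return mean_egg_weight * lp / 100.0


def fcr(dfc: float, em: float, period_days: int = 7) -> float:
    """Feed conversion ratio: (sum of daily feed / EM) / period.

    With a constant daily feed consumption this reduces to dfc / em, the
    dimensionless feed-per-egg-mass ratio. Returns NaN when em == 0 (the
    bird laid nothing; FCR is undefined and the bird should be flagged
    downstream rather than carry an infinity).
    """
    if period_days <= 0:
        raise ValueError("period_days must be > 0")
    if em == 0:
        return math.nan
    return (dfc * period_days / em) / period_days


def rfc(
    dfc_total: float,
    dbw: float,
    em: float,
    coeffs: RFCCoefficients,
    bwg: float = 0.0,
) -> float:
    """Residual feed consumption (g): observed minus model-predicted feed."""
    if coeffs is None:
        raise ValueError("RFC coefficients must be provided")
    return dfc_total - (coeffs.b0 + coeffs.b1 * dbw + coeffs.b2 * em + coeffs.b3 * bwg)


def compute_efficiency(
    bird: BirdRecord,
    coeffs: RFCCoefficients | None = None,
    *,
    bwg: float = 0.0,
    rfc_per_day: bool = False,
) -> EfficiencyIndicators:
    """All efficiency indicators for one bird.

    ``rfc_per_day`` switches the RFC feed term from total feed over the
    recording period (the default, in g) to the daily mean.
    """
    coeffs = coeffs if coeffs is not None else RFCCoefficients()
    lp = laying_percentage(bird.eggs_laid, bird.expected_eggs)
    em = egg_mass(bird.mean_egg_weight or 0.0, lp)
    f = fcr(bird.dfc, em, bird.period_days)
    dfc_term = bird.dfc if rfc_per_day else bird.dfc * bird.period_days
    r = rfc(dfc_term, bird.dbw, em, coeffs, bwg)
    flags = ("no_eggs",) if em == 0 else ()
    return EfficiencyIndicators(
        lp=lp, em=em, dbw=bird.dbw, fcr=f, rfc=r, bwg=bwg, flags=flags
    )
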