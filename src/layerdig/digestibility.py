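"""Apparent total-tract digestibility coefficients from manure mass balance.

The apparent digestibility coefficient (DC) of a nutrient is the percentage
of intake not recovered in excreta,

    DC = 100 * (intake - excretion) / intake .

For birds, faeces and urine are voided together, so the nitrogen recovered
in manure mixes faecal (undigested) N with urinary N excreted mainly as
uric acid. DC_N is therefore computed on manure N corrected by subtracting
the N stoichiometrically bound in uric acid (C5H4N4O3), separating the
digestive signal from post-absorptive N metabolism.

Bookkeeping of bases matters throughout:

* assay contents arrive on the *air-dried-sample* basis (g/kg air-dried
  manure) and are converted to the dry-matter basis via the air-dried
  sample's own DM content;
* the daily amount of manure DM is the air-dry recovery (ADM, g/kg fresh)
  times the fresh daily manure weight;
* feed contents arrive as-fed and are converted to g/kg DM via the feed's
  DM content;
* organic matter is defined as DM minus ash on both the feed and the
  manure side.

A DC can legitimately fall below zero when the excreted amount exceeds
intake (a mass-balance violation from measurement error or feed wastage);
such values are flagged, never clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .trial_data import BirdRecord, FeedComposition, ManureAssay

__all__ = [
    "URIC_ACID_N_FRACTION",
    "NutrientOnDmBasis",
    "DigestibilityCoefficients",
    "airdry_to_dm_basis",
    "correct_nitrogen_for_uric_acid",
    "manure_dm_amount",
    "feed_dm_amount",
    "dc_dry_matter",
    "dc_nutrient",
    "compute_all_dcs",
]

#: Mass fraction of nitrogen in uric acid, 4 N atoms per C5H4N4O3 molecule.
URIC_ACID_N_FRACTION = 4 * 14.007 / 168.11  # ~0.33328


@dataclass(frozen=True)
class NutrientOnDmBasis:
    """Manure analyte contents converted to g/kg dry matter."""

    nitrogen_dm: float
    nitrogen_corrected_dm: float
    fat_dm: float
    ash_dm: float
    org_dm: float
    uric_acid_dm: float


@dataclass(frozen=True)
class DigestibilityCoefficients:
    """Per-bird apparent digestibility coefficients, in percent.

    ``flags`` carries data-quality annotations (e.g. ``negative_dc``,
    ``zero_manure``) rather than silently altering values.
    """

    dc_dm: float
    dc_fat: float
    dc_n: float
    dc_org: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("dc_dm", "dc_fat", "dc_n", "dc_org"):
            v = getattr(self, name)
            if v > 100:
                raise ValueError(f"{name} = {v} exceeds 100 %")


def airdry_to_dm_basis(
    assay: ManureAssay, *, ua_n_fraction: float = URIC_ACID_N_FRACTION
) -> NutrientOnDmBasis:
    """Convert assay contents from the air-dried basis to g/kg DM.

    content_dm = content_ad * 1000 / dm_ad for each analyte; organic matter
    is the DM-minus-ash complement, org_dm = 1000 - ash_dm. The uric-acid
    nitrogen correction is applied on the DM basis.
    """
    if assay.dm_ad <= 0:
        raise ValueError(f"assay {assay.bird_id}: dm_ad must be > 0")
    f = 1000.0 / assay.dm_ad
    nitrogen_dm = assay.nitrogen_ad * f
    uric_acid_dm = assay.uric_acid_ad * f
    ash_dm = assay.ash_ad * f
    return NutrientOnDmBasis(
        nitrogen_dm=nitrogen_dm,
        nitrogen_corrected_dm=correct_nitrogen_for_uric_acid(
            nitrogen_dm, uric_acid_dm, ua_n_fraction=ua_n_fraction
        ),
        fat_dm=assay.fat_ad * f,
        ash_dm=ash_dm,
        org_dm=1000.0 - ash_dm,
        uric_acid_dm=uric_acid_dm,
    )


def correct_nitrogen_for_uric_acid(
    nitrogen_dm: float,
    uric_acid_dm: float,
    *,
    ua_n_fraction: float = URIC_ACID_N_FRACTION,
) -> float:
    """Subtract uric-acid-bound N from total manure N (both g/kg DM).

    Floors at zero with a warning if the correction exceeds total N, which
    indicates inconsistent assays.
    """
    if nitrogen_dm < 0 or uric_acid_dm < 0:
        raise ValueError("nitrogen_dm and uric_acid_dm must be >= 0")
    corrected = nitrogen_dm - ua_n_fraction * uric_acid_dm
    if corrected < 0:
        warnings.warn(
            f"uric-acid N ({ua_n_fraction * uric_acid_dm:.2f} g/kg DM) exceeds total "
            f"manure N ({nitrogen_dm:.2f} g/kg DM); corrected N floored at 0",
            stacklevel=2,
        )
        return 0.0
    return corrected


def manure_dm_amount(adm: float, dmw: float) -> float:
    """Daily manure dry matter (g/day) from air-dry recovery and fresh weight.

    manure_dm = adm / 1000 * dmw, with adm in g/kg fresh manure and dmw the
    fresh daily manure weight in g/day.
    """
    if adm < 0 or dmw < 0:
        raise ValueError("adm and dmw must be >= 0")
    return adm / 1000.0 * dmw


def feed_dm_amount(dfc: float, feed_dm: float) -> float:
    """Daily feed dry-matter intake (g/day): dfc * feed_dm / 1000."""
    if dfc < 0 or feed_dm < 0:
        raise ValueError("dfc and feed_dm must be >= 0")
    return dfc * feed_dm / 1000.0


def dc_dry_matter(manure_dm: float, feed_dm_in: float) -> float:
    """Dry-matter digestibility: 100 - manure_dm / feed_dm_in * 100."""
    if feed_dm_in <= 0:
        raise ValueError("feed_dm_in must be > 0")
    return 100.0 - manure_dm / feed_dm_in * 100.0


def dc_nutrient(
    manure_dm: float,
    content_manure: float,
    feed_dm_in: float,
    content_feed: float,
) -> float:
    """Nutrient digestibility from amounts (g DM/day) and contents (g/kg DM).

    DC = 100 - (manure_dm * content_manure) / (feed_dm_in * content_feed) * 100.
    For nitrogen, ``content_manure`` must be the uric-acid-corrected value.
    """
    if feed_dm_in <= 0:
        raise ValueError("feed_dm_in must be > 0")
    if content_feed <= 0:
        raise ValueError("DC undefined: nutrient absent from feed (content_feed <= 0)")
    return 100.0 - (manure_dm * content_manure) / (feed_dm_in * content_feed) * 100.0


def compute_all_dcs(
    bird: BirdRecord,
    assay: ManureAssay,
    feed: FeedComposition,
    *,
    ua_n_fraction: float = URIC_ACID_N_FRACTION,
    feed_is_dm_basis: bool = False,
) -> DigestibilityCoefficients:
    """Full DC chain for one bird: DM, fat, UA-corrected N and organic matter.

    Feed contents are treated as as-fed and converted to g/kg DM unless
    ``feed_is_dm_basis`` is set. A bird with zero manure output yields
    100 % across the board with a ``zero_manure`` flag; negative DCs are
    flagged ``negative_dc``.
    """
    if feed.dm <= 0:
        raise ValueError("feed dm must be > 0")
    man_dm = manure_dm_amount(assay.adm, bird.dmw)
    feed_dm_in = feed_dm_amount(bird.dfc, feed.dm)
    contents = airdry_to_dm_basis(assay, ua_n_fraction=ua_n_fraction)

    to_dm = 1.0 if feed_is_dm_basis else 1000.0 / feed.dm
    feed_n_dm = feed.nitrogen * to_dm
    feed_fat_dm = feed.fat * to_dm
    feed_ash_dm = feed.ash * to_dm
    feed_org_dm = 1000.0 - feed_ash_dm

    flags: list[str] = []
    if bird.dmw == 0 or man_dm == 0:
        flags.append("zero_manure")
    dcs = DigestibilityCoefficients(
        dc_dm=dc_dry_matter(man_dm, feed_dm_in),
        dc_fat=dc_nutrient(man_dm, contents.fat_dm, feed_dm_in, feed_fat_dm),
        dc_n=dc_nutrient(man_dm, contents.nitrogen_corrected_dm, feed_dm_in, feed_n_dm),
        dc_org=dc_nutrient(man_dm, contents.org_dm, feed_dm_in, feed_org_dm),
        flags=tuple(flags),
    )
    if min(dcs.dc_dm, dcs.dc_fat, dcs.dc_n, dcs.dc_org) < 0:
        dcs = DigestibilityCoefficients(
            dc_dm=dcs.dc_dm,
            dc_fat=dcs.dc_fat,
            dc_n=dcs.dc_n,
            dc_org=dcs.dc_org,
            flags=dcs.flags + ("negative_dc",),
        )
    return dcs
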