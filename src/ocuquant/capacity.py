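"""Vitreal target carrying-capacity arithmetic.

A long-acting intravitreal drug is retained by weak binding to an abundant,
slowly turning-over vitreous component.  Whether a candidate target can
hold a clinically relevant dose is pure stoichiometry: its molar abundance
per eye (concentration × vitreal volume / binding-unit MW) against the
molar dose, through an explicit binding footprint (how many repeating units
one drug molecule occludes).

Canonical unit facts: 1 nmol of a ``u``-Da unit weighs ``u`` ng; 1 nmol of
a ``k``-kDa protein weighs ``k`` µg.  Hyaluronan's repeating disaccharide
unit is 384 Da; the human vitreous is taken as 4.0 ml by default (standard
anatomical value — the calculations log it as an explicit assumption).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "HYALURONAN_DISACCHARIDE_DA",
    "HUMAN_VITREAL_VOLUME_ML",
    "TargetSpec",
    "molar_abundance",
    "drug_carrying_capacity",
    "required_sites_for_dose",
    "dose_nmol_from_mg",
]

HYALURONAN_DISACCHARIDE_DA = 384.0
HUMAN_VITREAL_VOLUME_ML = 4.0


@dataclass(frozen=True)
class TargetSpec:
    """A candidate vitreal binding target.

    ``concentration_range`` is (low, median, high) in µg/ml; ``unit_mw_da``
    is the molecular weight of the repeating/binding unit in Da;
    ``binding_footprint`` is the number of units occluded per bound drug
    molecule (≥ 1).
    """

    name: str
    concentration_range: tuple[float, float, float]
    unit_mw_da: float
    binding_footprint: float = 1.0
    vitreal_volume_ml: float = HUMAN_VITREAL_VOLUME_ML

    def __post_init__(self) -> None:
        low, med, high = self.concentration_range
        if not (0 <= low <= med <= high):
            raise ValueError("concentration range must satisfy 0 <= low <= median <= high")
        if self.unit_mw_da <= 0:
            raise ValueError("unit molecular weight must be positive")
        if self.binding_footprint < 1:
            raise ValueError("binding footprint must be >= 1 unit per drug molecule")
        if self.vitreal_volume_ml <= 0:
            raise ValueError("vitreal volume must be positive")


def molar_abundance(target: TargetSpec) -> tuple[float, float, float]:
    """nmol of binding units per eye for each concentration-range endpoint.

    ``nmol = µg/ml × ml / (Da/1000)`` — e.g. hyaluronan at 34 µg/ml in a
    4 ml vitreous is 136 µg = 136 000 ng / 384 ng·nmol⁻¹ ≈ 354 nmol of
    disaccharide units.
    """
    return tuple(
        conc * target.vitreal_volume_ml / (target.unit_mw_da / 1000.0)
        for conc in target.concentration_range
    )


def available_sites(target: TargetSpec) -> tuple[float, float, float]:
    """nmol of drug-binding sites per eye: unit abundance / footprint."""
    return tuple(units / target.binding_footprint for units in molar_abundance(target))


def drug_carrying_capacity(
    binding_sites_nmol: float, drug_mw_kda: float, stoichiometry: float = 1.0
) -> float:
    """Drug mass (mg per eye) the available sites can hold.

    ``mg = nmol sites × (drug per site) × kDa / 1000`` since 1 nmol of a
    k-kDa protein weighs k µg.
    """
    if drug_mw_kda <= 0:
        raise ValueError("drug molecular weight must be positive")
    if binding_sites_nmol < 0:
        raise ValueError("binding sites must be nonnegative")
    if stoichiometry <= 0:
        raise ValueError("stoichiometry must be positive")
    return binding_sites_nmol * stoichiometry * drug_mw_kda / 1000.0


def required_sites_for_dose(dose_nmol: float, stoichiometry: float = 1.0) -> float:
    """nmol of target sites needed to bind a molar dose at the stated stoichiometry."""
    if dose_nmol < 0:
        raise ValueError("dose must be nonnegative")
    if stoichiometry <= 0:
        raise ValueError("stoichiometry must be positive")
    return dose_nmol / stoichiometry


def dose_nmol_from_mg(dose_mg: float, drug_mw_kda: float) -> float:
    """mg dose -> nmol (e.g. 0.5 mg of a 49 kDa Fab ≈ 10.2 nmol)."""
    if drug_mw_kda <= 0:
        raise ValueError("drug molecular weight must be positive")
    if dose_mg < 0:
        raise ValueError("dose must be nonnegative")
    return 1000.0 * dose_mg / drug_mw_kda
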