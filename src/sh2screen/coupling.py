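"""Double-mutant-cycle thermodynamics for binding affinities.

A mutation's effect on binding free energy is ΔΔG = RT·ln(Kd_state /
Kd_wt): negative for affinity-enhancing changes. For two mutations A and
B measured singly and together against the same peptide, the interaction
(coupling) free energy is

    ΔΔG_int = ΔΔG_AB − ΔΔG_A − ΔΔG_B
            = RT·ln((Kd_AB · Kd_wt) / (Kd_A · Kd_B)),

which is zero when the two effects are additive, symmetric under
exchanging A and B, and negative when the double mutant binds tighter
than additivity predicts. Equivalently it is RT·ln of the ratio of the
fold-change of A in the wild-type background to its fold-change in the
B background: attenuation of a mutation's effect by the second mutation
gives positive coupling (sub-additive), enhancement gives negative
coupling (super-additive). Energies are in kcal·mol⁻¹ at 298.15 K by
default (R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹); a kJ flag converts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .library_io import ValidationError

__all__ = [
    "R_KCAL",
    "KCAL_TO_KJ",
    "CouplingCycle",
    "ddg_from_fold",
    "coupling_energy",
    "coupling_from_folds",
]

#: Gas constant, kcal·mol⁻¹·K⁻¹.
R_KCAL = 1.9872e-3

KCAL_TO_KJ = 4.184


def _convert(value_kcal: float, kilojoules: bool) -> float:
    return value_kcal * KCAL_TO_KJ if kilojoules else value_kcal


def ddg_from_fold(fold: float, temperature: float = 298.15,
                  kilojoules: bool = False) -> float:
    """Binding free-energy change from an affinity fold-change.

    ``fold = Kd_reference / Kd_variant`` (> 1 means the variant binds
    tighter); ΔΔG = −RT·ln(fold), negative for affinity-enhancing
    changes. Units kcal·mol⁻¹ unless ``kilojoules``.
    """
    if fold <= 0:
        raise ValidationError("fold-change must be positive")
    if temperature <= 0:
        raise ValidationError("temperature must be positive (kelvin)")
    return _convert(-R_KCAL * temperature * math.log(fold), kilojoules)


@dataclass
class CouplingCycle:
    """Four-state thermodynamic cycle on one peptide.

    Kd values (µM, same peptide and conditions) for the wild type, each
    single mutant, and the double mutant.
    """

    kd_wt: float
    kd_a: float
    kd_b: float
    kd_ab: float
    label_wt: str = "WT"
    label_a: str = "A"
    label_b: str = "B"
    label_ab: str = "AB"
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("kd_wt", "kd_a", "kd_b", "kd_ab"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive (kelvin)")

    @property
    def rt(self) -> float:
        """RT in kcal·mol⁻¹."""
        return R_KCAL * self.temperature

    def _ddg(self, kd_state: float) -> float:
        return self.rt * math.log(kd_state / self.kd_wt)

    @property
    def ddg_a(self) -> float:
        """ΔΔG of mutation A alone, kcal·mol⁻¹ (negative = tighter)."""
        return self._ddg(self.kd_a)

    @property
    def ddg_b(self) -> float:
        return self._ddg(self.kd_b)

    @property
    def ddg_ab(self) -> float:
        return self._ddg(self.kd_ab)


def coupling_energy(cycle: CouplingCycle, kilojoules: bool = False) -> float:
    """Interaction free energy ΔΔG_int of a double-mutant cycle.

    ΔΔG_int = ΔΔG_AB − ΔΔG_A − ΔΔG_B
            = RT·ln((Kd_AB·Kd_wt)/(Kd_A·Kd_B)).
    Zero for an additive cycle; negative when the double mutant binds
    tighter than additivity predicts; invariant under exchanging the A
    and B labels.
    """
    value = cycle.ddg_ab - cycle.ddg_a - cycle.ddg_b
    return _convert(value, kilojoules)


def coupling_from_folds(
    fold_in_wt: float,
    fold_in_other_background: float,
    temperature: float = 298.15,
    kilojoules: bool = False,
) -> float:
    """Coupling energy from a mutation's fold-changes in two backgrounds.

    ``ΔΔG_int = RT·ln(fold_in_wt / fold_in_other_background)`` where the
    folds are Kd(before)/Kd(after) for the same mutation applied in the
    wild-type background and in the second-mutant background. This
    recovers :func:`coupling_energy` algebraically
    (``fold_in_wt = Kd_wt/Kd_A``, ``fold_in_other = Kd_B/Kd_AB``), and
    lets coupling be computed directly from reported fold-changes when
    raw Kd values are not at hand: an effect attenuated by the second
    mutation couples positively, an enhanced effect negatively.
    """
    if fold_in_wt <= 0 or fold_in_other_background <= 0:
        raise ValidationError("fold-changes must be positive")
    value = (
        R_KCAL * temperature * math.log(fold_in_wt / fold_in_other_background)
    )
    return _convert(value, kilojoules)
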