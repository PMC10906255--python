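"""Cation-adduct mass arithmetic.

Low-mass LDI fingerprints of plasma detect small metabolites mainly as
singly charged cation adducts ([M+H]+, [M+Na]+, [M+K]+).  The m/z of an
adduct ion is the neutral monoisotopic mass plus the isotopic mass of the
cation minus one electron mass.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _ptmass

#: electron rest mass in Da (CODATA); pyteomics tabulates it as "e*"
ELECTRON_MASS: float = _ptmass.nist_mass["e*"][0][0]

_H1 = _ptmass.nist_mass["H"][1][0]
_NA23 = _ptmass.nist_mass["Na"][23][0]
_K39 = _ptmass.nist_mass["K"][39][0]


@dataclass(frozen=True)
class AdductRule:
    """A singly charged cation-adduct rule.

    ``mass_shift`` is the m/z offset added to the neutral monoisotopic
    mass; it includes the electron-mass correction unless the rule was
    built with ``electron_correction=False`` (legacy tables that quote
    the bare atomic mass).
    """

    name: str
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError(f"only singly charged rules supported, got charge={self.charge}")


def _rule(name: str, atom_mass: float, electron_correction: bool = True) -> AdductRule:
    shift = atom_mass - (ELECTRON_MASS if electron_correction else 0.0)
    return AdductRule(name=name, mass_shift=shift)


def default_rules(electron_correction: bool = True) -> dict[str, AdductRule]:
    """The three cation adducts of the fingerprinting window."""
    return {
        "[M+H]+": _rule("[M+H]+", _H1, electron_correction),
        "[M+Na]+": _rule("[M+Na]+", _NA23, electron_correction),
        "[M+K]+": _rule("[M+K]+", _K39, electron_correction),
    }


DEFAULT_RULES = default_rules()


def adduct_mz(monoisotopic_mass: float, rule: AdductRule | str) -> float:
    """m/z of the singly charged adduct of a neutral of given mass.

    Parameters
    ----------
    monoisotopic_mass:
        Neutral monoisotopic mass in Da (may be 0 for the hypothetical
        bare-cation check).
    rule:
        An :class:`AdductRule` or the name of one of the default rules.
    """
    if isinstance(rule, str):
        try:
            rule = DEFAULT_RULES[rule]
        except KeyError:
            raise KeyError(
                f"unknown adduct rule {rule!r}; known: {sorted(DEFAULT_RULES)}"
            ) from None
    if monoisotopic_mass < 0:
        raise ValueError("monoisotopic mass must be nonnegative")
    return (monoisotopic_mass + rule.mass_shift) / rule.charge


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula, from the NIST atomic-mass table."""
    return float(_ptmass.calculate_mass(formula=formula))
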