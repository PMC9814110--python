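"""Concentration-preparation arithmetic for mixtures and impure test articles.

Multi-constituent biocides (e.g. the 3:1 CMIT/MIT mixture) are tested at
nominal concentrations that must be corrected for measured purity and, when
the working solution was prepared under a default molecular-weight
assumption, for the ratio between the constituents' mole-fraction-weighted
molecular weight and that default.
"""

from __future__ import annotations

from typing import Iterable, Tuple

from .errors import InvalidInputError


def weighted_mw(components: Iterable[Tuple[float, float]]) -> float:
    """Mole-fraction-weighted molecular weight of a mixture.

    `components` is an iterable of ``(mw_g_per_mol, mole_fraction)`` pairs;
    the fractions must sum to 1 within 1e-6.
    """
    comps = list(components)
    if not comps:
        raise InvalidInputError("at least one component required")
    total = sum(f for _, f in comps)
    if abs(total - 1.0) > 1e-6:
        raise InvalidInputError(f"mole fractions sum to {total}, not 1")
    if any(mw <= 0 or f < 0 for mw, f in comps):
        raise InvalidInputError("molecular weights must be positive, fractions non-negative")
    return float(sum(mw * f for mw, f in comps))


def purity_adjust(concentration: float, purity_fraction: float) -> float:
    """Scale a nominal concentration by the active-ingredient purity fraction."""
    if not (0.0 < purity_fraction <= 1.0):
        raise InvalidInputError(f"purity fraction {purity_fraction} outside (0, 1]")
    if concentration < 0:
        raise InvalidInputError("concentration must be non-negative")
    return concentration * purity_fraction


def default_mw_concentration_correction(nominal: float, purity_fraction: float,
                                        mw_ratio: float) -> float:
    """Correct a concentration prepared under a default-MW assumption.

    When a mixture without a defined molecular weight is prepared at a default
    MW (e.g. 200 g/mol), the true molar concentration is the nominal value
    times the combined purity, divided by the ratio of the weighted MW to the
    default (``mw_ratio``).
    """
    if mw_ratio <= 0:
        raise InvalidInputError("MW ratio must be positive")
    if not (0.0 < purity_fraction <= 1.0):
        raise InvalidInputError(f"purity fraction {purity_fraction} outside (0, 1]")
    if nominal <= 0:
        raise InvalidInputError("nominal concentration must be positive")
    return nominal * purity_fraction / mw_ratio
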