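"""Concentration-response series and threshold-crossing interpolation.

Every quantitative endpoint in the nonanimal skin-sensitization assays — the
KeratinoSens EC1.5, the h-CLAT CV75/EC150/EC200 and the LLNA EC3 — is the
concentration at which a piecewise-linear interpolant of an ordered
concentration-response series crosses a fixed threshold. This module provides
the shared series container and the single crossing routine behind all of
them. Interpolation can be linear in concentration or in log10 concentration;
the in vitro endpoints conventionally use the log scale (serial-dilution
designs are geometric), the LLNA EC3 the arithmetic scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import InvalidInputError, SchemaError


class ResponseKind(str, Enum):
    FOLD_INDUCTION = "fold_induction"
    VIABILITY_PERCENT = "viability_percent"
    RFI_PERCENT = "rfi_percent"
    DEPLETION_PERCENT = "depletion_percent"
    STIMULATION_INDEX = "stimulation_index"


#: Concentration unit tags used across the assays.
Unit = Literal["uM", "ug/mL", "% w/v"]


@dataclass(frozen=True)
class DoseResponseSeries:
    """An ordered concentration grid with one response per concentration.

    Parameters
    ----------
    concentrations
        Strictly increasing positive concentrations.
    responses
        Responses paired with `concentrations` (same length).
    response_kind
        What the responses measure (fold induction, viability %, RFI %,
        peptide depletion %, or LLNA stimulation index).
    unit
        Concentration unit tag ("uM", "ug/mL" or "% w/v").
    """

    concentrations: tuple
    responses: tuple
    response_kind: ResponseKind
    unit: str = "uM"

    def __init__(self, concentrations: Sequence[float], responses: Sequence[float],
                 response_kind: ResponseKind | str, unit: str = "uM"):
        conc = tuple(float(c) for c in concentrations)
        resp = tuple(float(r) for r in responses)
        kind = ResponseKind(response_kind)
        if len(conc) < 2:
            raise SchemaError("a dose-response series needs at least 2 concentrations")
        if len(conc) != len(resp):
            raise SchemaError(
                f"{len(conc)} concentrations but {len(resp)} responses")
        if any(c <= 0 for c in conc):
            raise SchemaError("concentrations must be positive")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise SchemaError("concentrations must be strictly increasing")
        if any(not np.isfinite(r) for r in resp):
            raise SchemaError("responses must be finite")
        if kind is ResponseKind.VIABILITY_PERCENT and any(r < 0 for r in resp):
            raise SchemaError("viability responses must be non-negative")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        object.__setattr__(self, "response_kind", kind)
        object.__setattr__(self, "unit", unit)

    def __len__(self) -> int:
        return len(self.concentrations)

    def same_grid(self, other: "DoseResponseSeries", rtol: float = 1e-9) -> bool:
        return len(self) == len(other) and np.allclose(
            self.concentrations, other.concentrations, rtol=rtol)


def crossing_concentration(
    series: DoseResponseSeries,
    threshold: float,
    direction: Literal["up", "down"],
    scale: Literal["linear", "log"] = "log",
) -> Optional[float]:
    """Lowest concentration at which the interpolated response crosses `threshold`.

    The series is interpolated piecewise-linearly, either directly in
    concentration (``scale="linear"``) or in log10 concentration
    (``scale="log"``, the serial-dilution convention). Scanning from the
    lowest concentration upward, the first event wins:

    * a tested concentration whose response equals the threshold exactly is
      returned as-is;
    * a segment that straddles the threshold in the requested direction
      (``"up"``: rising through it; ``"down"``: falling through it) yields the
      interpolated crossing concentration.

    Returns ``None`` when no such crossing exists within the tested range —
    including the case where the whole series is already beyond the threshold
    (the crossing would lie below the lowest tested concentration).
    """
    if not np.isfinite(threshold):
        raise InvalidInputError("threshold must be finite")
    if direction not in ("up", "down"):
        raise InvalidInputError(f"unknown direction {direction!r}")
    if scale not in ("linear", "log"):
        raise InvalidInputError(f"unknown scale {scale!r}")

    conc = np.asarray(series.concentrations, dtype=float)
    resp = np.asarray(series.responses, dtype=float)
    x = np.log10(conc) if scale == "log" else conc

    for i in range(len(conc)):
        if resp[i] == threshold:
            return float(conc[i])
        if i + 1 < len(conc):
            lo, hi = resp[i], resp[i + 1]
            rising = lo < threshold < hi
            falling = lo > threshold > hi
            if (direction == "up" and rising) or (direction == "down" and falling):
                t = (threshold - lo) / (hi - lo)
                xc = x[i] + t * (x[i + 1] - x[i])
                return float(10.0 ** xc) if scale == "log" else float(xc)
    return None


def interpolate_response(series: DoseResponseSeries, concentration: float,
                         scale: Literal["linear", "log"] = "log") -> float:
    """Piecewise-linear interpolated response at `concentration` (clamped to
    the tested range at either end)."""
    conc = np.asarray(series.concentrations, dtype=float)
    resp = np.asarray(series.responses, dtype=float)
    if scale == "log":
        return float(np.interp(np.log10(concentration), np.log10(conc), resp))
    return float(np.interp(concentration, conc, resp))
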