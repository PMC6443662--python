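"""Concentration unit handling.

Titration inputs mix pM, nM and µM; everything is converted to molar on
input and kept in molar internally.  Unit bugs are the dominant failure
mode in binding analysis, so parsing is explicit and strict.
"""

from __future__ import annotations

import re

__all__ = ["parse_concentration", "format_concentration", "MOLAR_PREFIXES"]

MOLAR_PREFIXES: dict[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
}

_CONC_RE = re.compile(r"^\s*([+-]?\d+\.?\d*(?:[eE][+-]?\d+)?)\s*([fpnuµμm]?M)\s*$")


def parse_concentration(value: float | str) -> float:
    """Return a concentration in molar.

    Numbers pass through unchanged (assumed molar already); strings must
    carry an explicit unit, e.g. ``"150pM"``, ``"33.1 nM"``, ``"10 µM"``.
    """
    if isinstance(value, (int, float)):
        conc = float(value)
    else:
        m = _CONC_RE.match(value)
        if m is None:
            raise ValueError(
                f"cannot parse concentration {value!r}; expected e.g. '150pM', '33.1 nM'"
            )
        conc = float(m.group(1)) * MOLAR_PREFIXES[m.group(2)]
    if conc < 0:
        raise ValueError(f"negative concentration: {value!r}")
    return conc


def format_concentration(molar: float) -> str:
    """Human-readable concentration with the most natural SI prefix."""
    if molar == 0:
        return "0 M"
    for unit, scale in [("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9), ("pM", 1e-12)]:
        if abs(molar) >= scale:
            return f"{molar / scale:.3g} {unit}"
    return f"{molar / 1e-15:.3g} fM"
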