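"""Gel and sol fractions of a crosslinked network from washing masses.

A freshly crosslinked sample of precursor dry mass W0 is washed until all
uncrosslinked material (the sol) is extracted, then dried again to mass W1.
Two conventions are exposed:

``mass_retained`` (default)
    gel% = 100 * W1/W0 — the crosslinked mass share that survives washing.
    This is the quantity the reported gel percentages of these gels (82, 77,
    66% for PEG-400/1000/2000 crosslinkers) describe.

``as_printed``
    gel% = 100 * (W0 - W1)/W0 — the literal formula some sources print for
    "gel fraction", which actually evaluates the washed-out complement.

The two conventions are exact complements and in both sol% = 100 - gel%.
The discrepancy is surfaced rather than silently resolved; see
docs/methods.md.
"""

from __future__ import annotations

from .io_schema import SolGelMasses

__all__ = ["gel_sol_fraction", "CONVENTIONS"]

CONVENTIONS = ("mass_retained", "as_printed")


def gel_sol_fraction(
    masses: SolGelMasses, convention: str = "mass_retained"
) -> tuple[float, float]:
    """Gel and sol percentages from pre/post-washing dry masses.

    Returns
    -------
    (gel_pct, sol_pct):
        Both in percent; their sum is exactly 100.
    """
    if convention not in CONVENTIONS:
        raise ValueError(
            f"convention must be one of {CONVENTIONS}, got {convention!r}"
        )
    # ratio first: w1/w0 <= 1 exactly in floating point, so gel never
    # exceeds 100 and gel + (100 - gel) == 100
    retained = 100.0 * (masses.w1_mg / masses.w0_mg)
    washed_out = 100.0 - retained
    if convention == "mass_retained":
        return retained, washed_out
    return washed_out, retained
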