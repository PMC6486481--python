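"""Reference structures for the glycans that exit the ER.

The Golgi input pool is drawn from Man8, Man9 and mono-glucosylated Man9
(Man9Glc).  Man8 is the B isomer (missing the alpha-1,2 mannose of the
central arm); Man9Glc carries a single 3.1-linked Glc on the terminal
mannose of the A arm, which blocks alpha-1,2-mannosidase trimming of that
arm until endo-mannosidase removes the Glc-Man unit.
"""

from __future__ import annotations

from .notation import GlycanStructure, parse_linear

MAN5 = "GlcNAc4.1GlcNAc4.1Man(3.1Man:)_m6.1Man(3.1Man:)_m6.1Man:@"
MAN8 = (
    "GlcNAc4.1GlcNAc4.1Man(3.1Man2.1Man2.1Man:)_m6.1Man(3.1Man:)_m6.1Man2.1Man:@"
)
MAN9 = (
    "GlcNAc4.1GlcNAc4.1Man(3.1Man2.1Man2.1Man:)_m6.1Man"
    "(3.1Man2.1Man:)_m6.1Man2.1Man:@"
)
MAN9GLC = (
    "GlcNAc4.1GlcNAc4.1Man(3.1Man2.1Man2.1Man3.1Glc:)_m6.1Man"
    "(3.1Man2.1Man:)_m6.1Man2.1Man:@"
)

ER_EXIT_SPECIES = {"Man8": MAN8, "Man9": MAN9, "Man9Glc": MAN9GLC}


def er_exit_structure(name: str) -> GlycanStructure:
    """Parsed structure for one of the ER-exit species Man8/Man9/Man9Glc."""
    try:
        return parse_linear(ER_EXIT_SPECIES[name])
    except KeyError:
        raise KeyError(
            f"unknown ER-exit species {name!r}; expected one of "
            f"{sorted(ER_EXIT_SPECIES)}"
        ) from None
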