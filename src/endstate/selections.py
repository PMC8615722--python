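"""Compact atom-selection expressions.

Syntax: ``chain:resi:atoms`` where ``atoms`` is an atom name, a ``+``-joined
list of atom names, or one of the named groups below.  ``chain:resi`` selects
the whole residue.
"""

from __future__ import annotations

import numpy as np

from .io import ToySystem

__all__ = ["NAMED_GROUPS", "parse_selection"]

#: Named atom groups resolved within a residue.
NAMED_GROUPS: dict[str, tuple[str, ...]] = {
    "charged_group": ("NZ",),
    "phosphate": ("P", "OP1", "OP2"),
    "ring": ("N9", "C8", "N7", "C5", "C4"),
    "alkyl": ("CB", "CG"),
}


def parse_selection(system: ToySystem, expr: str) -> np.ndarray:
    """Resolve a selection expression to an array of atom indices.

    Raises ``ValueError`` for malformed expressions or empty selections.
    """
    parts = expr.strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"bad selection {expr!r}: expected chain:resi[:atoms]")
    chain, resi_s = parts[0], parts[1]
    try:
        resi = int(resi_s)
    except ValueError as err:
        raise ValueError(f"bad selection {expr!r}: residue index not an integer") from err
    in_res = (system.chain_ids == chain) & (system.residue_ids == resi)
    if len(parts) == 2:
        idx = np.nonzero(in_res)[0]
    else:
        names = NAMED_GROUPS.get(parts[2], tuple(parts[2].split("+")))
        idx = np.nonzero(in_res & np.isin(system.names, names))[0]
    if len(idx) == 0:
        raise ValueError(f"selection {expr!r} matches no atoms")
    return idx
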