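"""Minimal conjunctive atom-selection grammar.

Expressions are keyword/value pairs joined by ``and``::

    name P
    resname WAT and element O
    group phosphate and resid 3

Keywords: ``name``, ``element``, ``resname``, ``resid``, ``group``.
Matching is exact (case-sensitive for names/resnames, case-insensitive for
elements).  An empty result is legal; a grammar violation raises
``SelectionError`` with the offending token position.
"""

from __future__ import annotations

import numpy as np

from .core_io import AtomSelection, Topology

KEYWORDS = ("name", "element", "resname", "resid", "group")


class SelectionError(ValueError):
    """Raised on a malformed selection expression."""


def select(topology: Topology, expression: str) -> AtomSelection:
    """Evaluate a selection expression against a topology.

    Returns atom indices in ascending order (deterministic for a given
    expression).
    """
    tokens = expression.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = np.ones(topology.n_atoms, dtype=bool)
    i = 0
    while i < len(tokens):
        key = tokens[i]
        if key not in KEYWORDS:
            raise SelectionError(
                f"expected one of {KEYWORDS} at token {i} ({key!r}) in "
                f"{expression!r}")
        if i + 1 >= len(tokens):
            raise SelectionError(f"keyword {key!r} at token {i} lacks a value")
        value = tokens[i + 1]
        if key == "name":
            mask &= topology.names == value
        elif key == "element":
            mask &= np.char.upper(topology.elements.astype(str)) == value.upper()
        elif key == "resname":
            mask &= topology.resnames == value
        elif key == "resid":
            try:
                rid = int(value)
            except ValueError:
                raise SelectionError(
                    f"resid value at token {i + 1} is not an integer: {value!r}")
            mask &= topology.resids == rid
        elif key == "group":
            if topology.groups is None:
                raise SelectionError("topology has no group map")
            mask &= topology.groups == value
        i += 2
        if i < len(tokens):
            if tokens[i] != "and":
                raise SelectionError(
                    f"expected 'and' at token {i}, got {tokens[i]!r}")
            i += 1
            if i >= len(tokens):
                raise SelectionError("dangling 'and' at end of expression")
    return AtomSelection(np.nonzero(mask)[0])
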