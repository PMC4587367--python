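"""Tiny atom-selection grammar.

Supports ``name``, ``resid`` (single ids and ``a-b`` ranges) and ``element``
clauses combined with ``and`` / ``or`` and parentheses, e.g.::

    name CA or name CB
    resid 3-5 and name CA

Selections always resolve to an index array ordered by atom index; an empty
result raises :class:`~mdtop.errors.SelectionError` rather than passing
silently.
"""

from __future__ import annotations

import re

import numpy as np

from .errors import SelectionError
from .topology import ToyTopology

_KEYWORDS = {"name", "resid", "element", "and", "or", "(", ")"}


def _tokenize(expr: str) -> list[str]:
    tokens = re.findall(r"\(|\)|[^\s()]+", expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], top: ToyTopology):
        self.tokens = tokens
        self.pos = 0
        self.top = top

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.next()
        if tok == "(":
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        if tok == "name":
            return self._match(self.top.names, self._values())
        if tok == "element":
            vals = {v.upper() for v in self._values()}
            return np.isin(np.char.upper(self.top.elements.astype(str)), sorted(vals))
        if tok == "resid":
            ids = set()
            for v in self._values():
                m = re.fullmatch(r"(\d+)-(\d+)", v)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    ids.update(range(lo, hi + 1))
                elif v.isdigit():
                    ids.add(int(v))
                else:
                    raise SelectionError(f"bad resid token {v!r}")
            return np.isin(self.top.res_ids, sorted(ids))
        raise SelectionError(f"unknown selection keyword {tok!r}")

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.next())
        if not vals:
            raise SelectionError("selection keyword without values")
        return vals

    @staticmethod
    def _match(arr: np.ndarray, vals: list[str]) -> np.ndarray:
        return np.isin(arr, vals)


def select_atoms(topology: ToyTopology, expression: str) -> np.ndarray:
    """Resolve a selection expression to an ordered atom-index array."""
    mask = _Parser(_tokenize(expression), topology).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return idx


def resolve_selection(topology: ToyTopology, selection) -> np.ndarray:
    """Accept either an expression string or an explicit index array."""
    if isinstance(selection, str):
        return select_atoms(topology, selection)
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise SelectionError("empty index selection")
    return idx
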