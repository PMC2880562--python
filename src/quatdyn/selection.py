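"""A small atom-selection language.

Grammar (case-insensitive keywords)::

    expr     := term ('or' term)*
    term     := factor ('and' factor)*
    factor   := 'not' factor | '(' expr ')' | primitive
    primitive:= 'all' | 'none' | 'calpha' | 'heavy' | 'hydrogen'
              | 'protein' | 'ligand' | 'hetero'
              | 'chain'   id[,id...]
              | 'resname' name[,name...]
              | 'name'    name[,name...]
              | 'element' sym[,sym...]
              | 'resnum'  n | n-m | n,m,...

Examples: ``"calpha"``, ``"chain A and resnum 110"``,
``"heavy and not ligand"``, ``"name CA,CB and chain A,B,C"``.

Selections depend only on atom metadata, never on coordinates, so an
index list is valid for every frame of a trajectory.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .errors import SelectionError

__all__ = ["select"]

_KEYWORDS = {
    "and", "or", "not", "all", "none", "calpha", "heavy", "hydrogen",
    "protein", "ligand", "hetero", "chain", "resname", "name", "element",
    "resnum",
}


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    n = len(expression)
    while i < n:
        c = expression[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < n and not expression[j].isspace() and expression[j] not in "()":
            j += 1
        tokens.append((expression[i:j], i))
        i = j
    return tokens


class _Parser:
    def __init__(self, expression: str):
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.pos = 0

    # -- token helpers -------------------------------------------------

    def _peek(self) -> tuple[str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        tok = self._peek()
        if tok is None:
            raise SelectionError(
                f"unexpected end of selection expression at position "
                f"{len(self.expression)}: {self.expression!r}"
            )
        self.pos += 1
        return tok

    def _error(self, message: str, position: int) -> SelectionError:
        return SelectionError(
            f"selection parse error at position {position}: {message} "
            f"in {self.expression!r}"
        )

    # -- grammar -------------------------------------------------------

    def parse(self) -> Callable:
        pred = self._expr()
        tok = self._peek()
        if tok is not None:
            raise self._error(f"unexpected token {tok[0]!r}", tok[1])
        return pred

    def _expr(self) -> Callable:
        left = self._term()
        while (tok := self._peek()) is not None and tok[0].lower() == "or":
            self._next()
            right = self._term()
            left = (lambda a, f=left, g=right: f(a) or g(a))
        return left

    def _term(self) -> Callable:
        left = self._factor()
        while (tok := self._peek()) is not None and tok[0].lower() == "and":
            self._next()
            right = self._factor()
            left = (lambda a, f=left, g=right: f(a) and g(a))
        return left

    def _factor(self) -> Callable:
        tok = self._next()
        word = tok[0].lower()
        if word == "not":
            inner = self._factor()
            return lambda a, f=inner: not f(a)
        if tok[0] == "(":
            inner = self._expr()
            closing = self._next()
            if closing[0] != ")":
                raise self._error("expected ')'", closing[1])
            return inner
        if tok[0] == ")":
            raise self._error("unmatched ')'", tok[1])
        return self._primitive(word, tok[1])

    def _values(self, keyword: str, position: int) -> list[str]:
        values: list[str] = []
        while (tok := self._peek()) is not None:
            text = tok[0]
            if text in "()" or text.lower() in _KEYWORDS:
                break
            self._next()
            values.extend(v for v in text.split(",") if v)
        if not values:
            raise self._error(f"{keyword!r} needs at least one value", position)
        return values

    def _primitive(self, word: str, position: int) -> Callable:
        if word == "all":
            return lambda a: True
        if word == "none":
            return lambda a: False
        if word == "calpha":
            return lambda a: a.is_calpha
        if word == "heavy":
            return lambda a: a.is_heavy
        if word == "hydrogen":
            return lambda a: not a.is_heavy
        if word == "protein":
            return lambda a: not a.is_ligand
        if word == "ligand":
            return lambda a: a.is_ligand
        if word == "hetero":
            return lambda a: a.is_hetero
        if word == "chain":
            vals = set(self._values("chain", position))
            return lambda a: a.chain_id in vals
        if word == "resname":
            vals = {v.upper() for v in self._values("resname", position)}
            return lambda a: a.residue_name.upper() in vals
        if word == "name":
            vals = {v.upper() for v in self._values("name", position)}
            return lambda a: a.name.upper() in vals
        if word == "element":
            vals = {v.capitalize() for v in self._values("element", position)}
            return lambda a: a.element.capitalize() in vals
        if word == "resnum":
            numbers: set[int] = set()
            for v in self._values("resnum", position):
                if "-" in v[1:]:  # allow leading minus, though resnums are ≥ 1
                    lo, _, hi = v.partition("-") if not v.startswith("-") else (
                        v[: v.index("-", 1)], "-", v[v.index("-", 1) + 1 :]
                    )
                    try:
                        numbers.update(range(int(lo), int(hi) + 1))
                    except ValueError:
                        raise self._error(f"bad residue range {v!r}", position)
                else:
                    try:
                        numbers.add(int(v))
                    except ValueError:
                        raise self._error(f"bad residue number {v!r}", position)
            return lambda a: a.residue_number in numbers
        raise self._error(f"unknown keyword {word!r}", position)


def select(model, expression: str) -> np.ndarray:
    """Evaluate ``expression`` against a model; returns sorted atom indices.

    An empty result is a valid empty index array, not an error.
    """
    predicate = _Parser(expression).parse()
    idx = [a.index for a in model.atoms if predicate(a)]
    return np.array(idx, dtype=int)
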