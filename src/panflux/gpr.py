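"""Gene-protein-reaction (GPR) boolean expressions.

A GPR is a boolean tree over gene identifiers: AND nodes model enzyme
complexes (all subunits required), OR nodes model isozymes (any one
suffices).  A reaction with no gene association is represented by
``None`` and is always catalyzable — gene deletions never touch it.

Expressions are immutable.  The module provides a parser for the
conventional ``"(g1 and g2) or g3"`` string syntax used in SBML notes
fields, evaluation against a deletion set, and substitution/simplification
used when translating a GPR from one strain's gene namespace to another's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, Sequence, Union

__all__ = [
    "Gene",
    "And",
    "Or",
    "Gpr",
    "genes",
    "evaluate",
    "parse_gpr",
    "format_gpr",
    "translate",
    "restrict",
    "GprSyntaxError",
]


@dataclass(frozen=True)
class Gene:
    """Leaf node: a single gene identifier."""

    id: str

    def __repr__(self) -> str:
        return f"Gene({self.id!r})"


@dataclass(frozen=True, init=False)
class _NAry:
    children: tuple

    def __init__(self, *children: "Gpr") -> None:
        if len(children) < 1:
            raise ValueError("boolean node needs at least one child")
        flat = []
        for c in children:
            if type(c) is type(self):
                flat.extend(c.children)  # associative flattening
            else:
                flat.append(c)
        object.__setattr__(self, "children", tuple(flat))


class And(_NAry):
    """All children must be satisfied (enzyme complex)."""


class Or(_NAry):
    """Any child suffices (isozymes)."""


Gpr = Union[Gene, And, Or]
OptionalGpr = Optional[Gpr]


def genes(gpr: OptionalGpr) -> frozenset:
    """All gene ids appearing as leaves of *gpr* (empty for ``None``)."""
    if gpr is None:
        return frozenset()
    if isinstance(gpr, Gene):
        return frozenset([gpr.id])
    out = set()
    for child in gpr.children:
        out |= genes(child)
    return frozenset(out)


def evaluate(gpr: OptionalGpr, deleted_genes) -> bool:
    """Is the reaction still catalyzable after deleting *deleted_genes*?

    ``None`` (no gene association) always evaluates True; a leaf is True
    iff its gene is not deleted; AND requires all children, OR any child.
    """
    if gpr is None:
        return True
    if isinstance(gpr, Gene):
        return gpr.id not in deleted_genes
    if isinstance(gpr, And):
        return all(evaluate(c, deleted_genes) for c in gpr.children)
    if isinstance(gpr, Or):
        return any(evaluate(c, deleted_genes) for c in gpr.children)
    raise TypeError(f"not a GPR node: {gpr!r}")


class GprSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed."""


def _tokenize(text: str) -> Iterator[str]:
    buf = []
    for ch in text:
        if ch in "()":
            if buf:
                yield "".join(buf)
                buf = []
            yield ch
        elif ch.isspace():
            if buf:
                yield "".join(buf)
                buf = []
        else:
            buf.append(ch)
    if buf:
        yield "".join(buf)


def parse_gpr(text: Optional[str]) -> OptionalGpr:
    """Parse ``"(g1 and g2) or g3"`` syntax into a GPR tree.

    ``and``/``or`` are matched case-insensitively; ``&&``/``||`` and
    ``&``/``|`` are accepted as synonyms.  An empty or whitespace-only
    string parses to ``None``.  AND binds tighter than OR.
    """
    if text is None or not text.strip():
        return None
    tokens = list(_tokenize(text))
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def is_op(tok, names):
        return tok is not None and tok.lower() in names

    def parse_or():
        node = parse_and()
        parts = [node]
        while is_op(peek(), ("or", "||", "|")):
            advance()
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else Or(*parts)

    def parse_and():
        node = parse_atom()
        parts = [node]
        while is_op(peek(), ("and", "&&", "&")):
            advance()
            parts.append(parse_atom())
        return parts[0] if len(parts) == 1 else And(*parts)

    def parse_atom():
        tok = peek()
        if tok is None:
            raise GprSyntaxError(f"unexpected end of GPR: {text!r}")
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise GprSyntaxError(f"unbalanced parentheses in GPR: {text!r}")
            advance()
            return node
        if tok == ")" or is_op(tok, ("and", "or", "&&", "||", "&", "|")):
            raise GprSyntaxError(f"unexpected token {tok!r} in GPR: {text!r}")
        return Gene(advance())

    tree = parse_or()
    if pos != len(tokens):
        raise GprSyntaxError(f"trailing tokens in GPR: {text!r}")
    return tree


def format_gpr(gpr: OptionalGpr) -> str:
    """Render a GPR tree back to ``and``/``or`` string syntax."""
    if gpr is None:
        return ""
    if isinstance(gpr, Gene):
        return gpr.id
    op = " and " if isinstance(gpr, And) else " or "
    parts = []
    for child in gpr.children:
        s = format_gpr(child)
        if not isinstance(child, Gene):
            s = f"({s})"
        parts.append(s)
    return op.join(parts)


# Sentinels for constant-valued results of substitution.  A reaction whose
# translated GPR is ALWAYS_OFF has lost all genetic support in the target
# strain; ALWAYS_ON cannot arise from translation but closes the algebra.
ALWAYS_ON = True
ALWAYS_OFF = False


def translate(gpr: OptionalGpr, mapping: Mapping[str, Sequence[str]]):
    """Substitute each leaf gene with its ortholog(s) in another strain.

    *mapping* takes a gene id to the (possibly empty) list of orthologous
    gene ids in the target strain.  Co-orthologs become OR alternatives;
    a gene with no ortholog becomes constant False.  The result is a
    simplified tree, or the constants ``ALWAYS_OFF`` / ``ALWAYS_ON`` when
    the whole expression collapses.  ``None`` stays ``None``.
    """
    if gpr is None:
        return None
    if isinstance(gpr, Gene):
        targets = list(mapping.get(gpr.id, ()))
        if not targets:
            return ALWAYS_OFF
        if len(targets) == 1:
            return Gene(targets[0])
        return Or(*[Gene(t) for t in targets])
    parts = [translate(c, mapping) for c in gpr.children]
    return _combine(type(gpr), parts)


def restrict(gpr: OptionalGpr, kept_genes):
    """Drop leaves outside *kept_genes*, simplifying the tree.

    Used for core-model construction: a leaf gene not conserved across the
    family becomes constant False.  Returns a tree or a boolean constant.
    """
    if gpr is None:
        return None
    if isinstance(gpr, Gene):
        return gpr if gpr.id in kept_genes else ALWAYS_OFF
    parts = [restrict(c, kept_genes) for c in gpr.children]
    return _combine(type(gpr), parts)


def _combine(node_type, parts):
    if node_type is And:
        if any(p is ALWAYS_OFF for p in parts):
            return ALWAYS_OFF
        parts = [p for p in parts if p is not ALWAYS_ON]
        if not parts:
            return ALWAYS_ON
    else:  # Or
        if any(p is ALWAYS_ON for p in parts):
            return ALWAYS_ON
        parts = [p for p in parts if p is not ALWAYS_OFF]
        if not parts:
            return ALWAYS_OFF
    if len(parts) == 1:
        return parts[0]
    return node_type(*parts)
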