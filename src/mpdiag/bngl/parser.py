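"""Plain-text BNGL reader for the supported dialect.

Hand-rolled recursive-descent parsing: the dialect is line-oriented with a
small expression sub-grammar for molecule/complex patterns, so a grammar
library would add a dependency without simplifying anything.
"""

from __future__ import annotations

import re

from mpdiag.errors import BnglSyntaxError, ModelValidationError, UnsupportedConstructError
from mpdiag.bngl.model import (
    ANY_BOND,
    BOUND_ANY,
    ComplexPattern,
    ComponentDef,
    ComponentPattern,
    Model,
    MoleculePattern,
    MoleculeTypeDef,
    Rule,
    link,
)

__all__ = ["parse_model", "parse_complex_pattern", "parse_reaction_side"]

_IDENT = r"[A-Za-z_][A-Za-z0-9_]*"
_BLOCK_ALIASES = {
    "parameters": "parameters",
    "molecule types": "molecule types",
    "seed species": "seed species",
    "species": "seed species",
    "reaction rules": "reaction rules",
    "observables": "observables",
    "functions": "functions",
    "compartments": "compartments",
}
_UNSUPPORTED_KEYWORDS = ("DeleteMolecules", "include_reactants", "exclude_reactants")


def _logical_lines(text: str):
    """Strip comments, join ``\\`` continuations; yield (line_number, content)."""
    pending = ""
    pending_start = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if pending:
            line = pending + " " + line.strip()
            start = pending_start
        else:
            start = lineno
        if line.endswith("\\"):
            pending = line[:-1].rstrip()
            pending_start = start
            continue
        pending = ""
        if line.strip():
            yield start, line.strip()
    if pending.strip():
        yield pending_start, pending.strip()


class _PatternScanner:
    """Character-level scanner for molecule/complex pattern expressions."""

    def __init__(self, text: str, lineno: int, offset: int = 0):
        self.text = text
        self.pos = 0
        self.lineno = lineno
        self.offset = offset

    def error(self, message: str) -> BnglSyntaxError:
        return BnglSyntaxError(message, line=self.lineno, column=self.offset + self.pos + 1)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def ident(self) -> str:
        m = re.match(_IDENT, self.text[self.pos :])
        if not m:
            raise self.error(f"expected identifier, found {self.peek()!r}")
        self.pos += m.end()
        return m.group(0)

    def component(self) -> ComponentPattern:
        name = self.ident()
        state: str | None = None
        bond = None
        while self.peek() in "~!%":
            ch = self.take()
            if ch == "~":
                if self.peek() == "?":
                    self.take()
                    state = "?"
                else:
                    state = self.ident()
            elif ch == "%":
                raise UnsupportedConstructError("component label '%'", line=self.lineno)
            else:  # '!'
                nxt = self.peek()
                if nxt == "?":
                    self.take()
                    bond = ANY_BOND
                elif nxt == "+":
                    self.take()
                    bond = BOUND_ANY
                elif nxt.isdigit():
                    digits = ""
                    while self.peek().isdigit():
                        digits += self.take()
                    bond = link(int(digits))
                else:
                    raise self.error("expected bond index, '+' or '?' after '!'")
        from mpdiag.bngl.model import UNBOUND

        return ComponentPattern(name=name, state=state, bond=bond if bond is not None else UNBOUND)

    def molecule(self) -> MoleculePattern:
        compartment = None
        if self.peek() == "@":
            self.take()
            compartment = self.ident()
            if self.peek() != ":":
                raise self.error("expected ':' after compartment prefix")
            self.take()
        if self.peek() == "$":
            raise UnsupportedConstructError("fixed species '$'", line=self.lineno)
        type_name = self.ident()
        components: list[ComponentPattern] = []
        if self.peek() == "(":
            self.take()
            if self.peek() != ")":
                components.append(self.component())
                while self.peek() == ",":
                    self.take()
                    components.append(self.component())
            if self.peek() != ")":
                raise self.error("expected ')' closing component list")
            self.take()
        return MoleculePattern(type_name=type_name, components=tuple(components), compartment=compartment)

    def complex_pattern(self) -> ComplexPattern:
        mols = [self.molecule()]
        while self.peek() == ".":
            self.take()
            mols.append(self.molecule())
        return ComplexPattern(molecules=tuple(mols))


def parse_complex_pattern(text: str, lineno: int = 0, offset: int = 0) -> ComplexPattern:
    sc = _PatternScanner(text.strip(), lineno, offset)
    cp = sc.complex_pattern()
    if sc.pos != len(sc.text):
        raise sc.error(f"unexpected trailing text {sc.text[sc.pos:]!r} in pattern")
    return cp


def parse_reaction_side(text: str, lineno: int = 0) -> tuple[ComplexPattern, ...]:
    """Parse a ``+``-separated list of complex patterns; ``0`` is the empty side."""
    text = text.strip()
    if text == "0":
        return ()
    parts: list[str] = []
    depth = 0
    cur = ""
    prev = ""
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "+" and depth == 0 and prev != "!":
            parts.append(cur)
            cur = ""
            prev = ch
            continue
        cur += ch
        if not ch.isspace():
            prev = ch
    parts.append(cur)
    patterns = []
    for part in parts:
        if not part.strip():
            raise BnglSyntaxError("empty reactant/product between '+' separators", line=lineno)
        patterns.append(parse_complex_pattern(part, lineno))
    return tuple(patterns)


def _parse_molecule_type(line: str, lineno: int) -> MoleculeTypeDef:
    m = re.match(rf"({_IDENT})(\((.*)\))?\s*$", line)
    if not m:
        raise BnglSyntaxError(f"malformed molecule type declaration {line!r}", line=lineno)
    name = m.group(1)
    comps: list[ComponentDef] = []
    body = m.group(3)
    if body:
        for piece in body.split(","):
            piece = piece.strip()
            if not piece:
                raise BnglSyntaxError("empty component in molecule type", line=lineno)
            fields = piece.split("~")
            cname = fields[0].strip()
            if not re.fullmatch(_IDENT, cname):
                raise BnglSyntaxError(f"bad component name {cname!r}", line=lineno)
            states = tuple(s.strip() for s in fields[1:])
            for s in states:
                if not s:
                    raise BnglSyntaxError(f"empty state in component {cname!r}", line=lineno)
            comps.append(ComponentDef(name=cname, states=states))
    return MoleculeTypeDef(name=name, components=tuple(comps))


_ARROW_RE = re.compile(r"<->|->")


def _split_rule_line(line: str, lineno: int):
    """Split a rule line into (name, lhs, arrow, rhs-with-rates)."""
    name = None
    m = re.match(rf"({_IDENT})\s*:\s*(.*)$", line)
    if m:
        name, line = m.group(1), m.group(2)
    arrow_match = _ARROW_RE.search(line)
    if not arrow_match:
        raise BnglSyntaxError("reaction rule without '->' or '<->'", line=lineno)
    arrow = arrow_match.group(0)
    lhs = line[: arrow_match.start()].strip()
    rhs = line[arrow_match.end() :].strip()
    return name, lhs, arrow, rhs


def _split_products_and_rates(rhs: str, lineno: int) -> tuple[str, str]:
    """Separate the product expression from the trailing rate expression(s).

    Product patterns alternate pattern tokens and standalone ``+`` separators;
    the first token that breaks the alternation starts the (opaque) rates.
    """
    tokens = rhs.split()
    if not tokens:
        raise BnglSyntaxError("missing products and rate", line=lineno)
    # re-split tokens so that 'A(x)+B(y)' counts as pattern,sep,pattern
    units: list[str] = []
    for tok in tokens:
        pieces: list[str] = []
        cur = ""
        prev = ""
        depth = 0
        for ch in tok:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            if ch == "+" and depth == 0 and prev != "!":
                pieces.append(cur)
                pieces.append("+")
                cur = ""
                prev = ch
                continue
            cur += ch
            prev = ch
        pieces.append(cur)
        units.extend(p for p in pieces if p != "")
        units.append(" ")  # token boundary marker
    expect_pattern = True
    consumed: list[str] = []
    i = 0
    while i < len(units):
        u = units[i]
        if u == " ":
            i += 1
            continue
        if expect_pattern:
            consumed.append(u)
            expect_pattern = False
        elif u == "+":
            consumed.append("+")
            expect_pattern = True
        else:
            break
        i += 1
    if expect_pattern and consumed:
        raise BnglSyntaxError("product list ends with '+'", line=lineno)
    rate_text = " ".join("".join(units[i:]).split())
    product_text = ""
    for u in consumed:
        product_text += " + " if u == "+" else u
    return product_text, rate_text


def _check_unsupported(line: str, lineno: int) -> None:
    for kw in _UNSUPPORTED_KEYWORDS:
        if re.search(rf"\b{kw}\b", line):
            raise UnsupportedConstructError(kw, line=lineno)


def parse_model(text: str, name: str = "model") -> Model:
    """Parse a BNGL document into a validated :class:`Model`.

    Raises :class:`BnglSyntaxError` on malformed text,
    :class:`UnsupportedConstructError` on constructs outside the dialect, and
    :class:`ModelValidationError` when the document violates model invariants
    (dangling bonds, undeclared types, illegal states, ...).
    """
    molecule_types: list[MoleculeTypeDef] = []
    parameters: list[tuple[str, str]] = []
    rules: list[Rule] = []
    seeds: list[tuple[ComplexPattern, str]] = []
    compartments: list[tuple[str, int, str]] = []
    observables: list[str] = []
    functions: list[str] = []
    seen_blocks: set[str] = set()

    block: str | None = None
    rule_counter = 0
    for lineno, line in _logical_lines(text):
        low = line.lower()
        if low.startswith("begin "):
            if block is not None:
                raise BnglSyntaxError(f"'begin' inside block {block!r}", line=lineno)
            key = low[6:].strip()
            if key == "model":
                continue
            if key not in _BLOCK_ALIASES:
                raise UnsupportedConstructError(f"block '{key}'", line=lineno)
            block = _BLOCK_ALIASES[key]
            seen_blocks.add(block)
            continue
        if low.startswith("end "):
            key = low[4:].strip()
            if key == "model":
                continue
            if block is None or _BLOCK_ALIASES.get(key) != block:
                raise BnglSyntaxError(f"'end {key}' without matching 'begin'", line=lineno)
            block = None
            continue
        if block is None:
            # action commands (generate_network, simulate, ...) are ignored
            continue
        _check_unsupported(line, lineno)
        if block == "parameters":
            m = re.match(rf"({_IDENT})\s*=?\s*(\S.*)$", line)
            if not m:
                raise BnglSyntaxError(f"malformed parameter line {line!r}", line=lineno)
            parameters.append((m.group(1), m.group(2).strip()))
        elif block == "molecule types":
            body = re.sub(r"^\d+\s+", "", line)  # optional leading index
            molecule_types.append(_parse_molecule_type(body, lineno))
        elif block == "seed species":
            body = re.sub(r"^\d+\s+", "", line)
            m = re.match(r"(\S+)\s+(\S.*)$", body)
            if not m:
                raise BnglSyntaxError("seed species line needs a pattern and an amount", line=lineno)
            seeds.append((parse_complex_pattern(m.group(1), lineno), m.group(2).strip()))
        elif block == "reaction rules":
            # optional leading rule index; '0 ->' is an empty reactant side, not an index
            body = re.sub(r"^\d+\s+(?!->|<->)", "", line)
            rname, lhs, arrow, rhs = _split_rule_line(body, lineno)
            product_text, rate_text = _split_products_and_rates(rhs, lineno)
            if not product_text and not rhs.startswith("0"):
                raise BnglSyntaxError("missing product side", line=lineno)
            reactants = parse_reaction_side(lhs, lineno)
            products = parse_reaction_side(product_text, lineno)
            rates = [r.strip() for r in rate_text.split(",") if r.strip()]
            reversible = arrow == "<->"
            if reversible and len(rates) != 2:
                raise BnglSyntaxError(
                    "reversible rule requires two comma-separated rate expressions", line=lineno
                )
            if not reversible and len(rates) != 1:
                raise BnglSyntaxError(
                    f"expected one rate expression, found {len(rates)}", line=lineno
                )
            rule_counter += 1
            rules.append(
                Rule(
                    id=rname or f"R{rule_counter}",
                    name=rname,
                    reactants=reactants,
                    products=products,
                    reversible=reversible,
                    rate_forward=rates[0],
                    rate_reverse=rates[1] if reversible else None,
                )
            )
        elif block == "compartments":
            m = re.match(rf"({_IDENT})\s+(\d+)\s*(.*)$", line)
            if not m:
                raise BnglSyntaxError(f"malformed compartment line {line!r}", line=lineno)
            compartments.append((m.group(1), int(m.group(2)), m.group(3).strip()))
        elif block == "observables":
            observables.append(line)
        elif block == "functions":
            functions.append(line)
    if block is not None:
        raise BnglSyntaxError(f"unterminated block {block!r}")
    if "molecule types" not in seen_blocks or "reaction rules" not in seen_blocks:
        raise BnglSyntaxError(
            "document must contain 'molecule types' and 'reaction rules' blocks"
        )
    model = Model(
        molecule_types=tuple(molecule_types),
        rules=tuple(rules),
        parameters=tuple(parameters),
        seed_species=tuple(seeds),
        compartments=tuple(compartments),
        observables_raw=tuple(observables),
        functions_raw=tuple(functions),
        name=name,
    )
    model.validate()
    return model
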