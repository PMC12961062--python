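"""Minimal grammar-level DOT reader, used as an independent check on the
renderer's output (tokenize + recursive descent; no layout semantics)."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_TOKEN = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<arrow>->)
  | (?P<punct>[{}\[\];=,])
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<number>-?(?:\.\d+|\d+(?:\.\d*)?))
    """,
    re.X,
)


class DotSyntaxError(Exception):
    pass


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise DotSyntaxError(f"unexpected character at offset {pos}: {text[pos:pos+20]!r}")
        pos = m.end()
        if m.lastgroup != "ws":
            tokens.append(m.group())
    return tokens


def _unquote(tok: str) -> str:
    if tok.startswith('"'):
        return tok[1:-1].replace('\\"', '"').replace("\\\\", "\\")
    return tok


@dataclass
class DotGraph:
    name: str
    nodes: dict[str, dict] = field(default_factory=dict)
    edges: list[tuple[str, str, dict]] = field(default_factory=list)
    subgraph_nodes: dict[str, list[str]] = field(default_factory=dict)


class _Parser:
    def __init__(self, tokens: list[str]):
        self.toks = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def take(self, expected: str | None = None) -> str:
        tok = self.peek()
        if tok is None:
            raise DotSyntaxError("unexpected end of input")
        if expected is not None and tok != expected:
            raise DotSyntaxError(f"expected {expected!r}, got {tok!r} at token {self.i}")
        self.i += 1
        return tok

    def take_id(self) -> str:
        tok = self.take()
        if tok in ("{", "}", "[", "]", ";", "=", ",", "->"):
            raise DotSyntaxError(f"expected an identifier, got {tok!r}")
        return _unquote(tok)

    def parse(self) -> DotGraph:
        self.take("digraph")
        name = ""
        if self.peek() != "{":
            name = _unquote(self.take())
        g = DotGraph(name=name)
        self.take("{")
        self.stmt_list(g, subgraph=None)
        self.take("}")
        if self.peek() is not None:
            raise DotSyntaxError(f"trailing tokens after graph: {self.peek()!r}")
        return g

    def stmt_list(self, g: DotGraph, subgraph: str | None) -> None:
        while self.peek() not in (None, "}"):
            self.stmt(g, subgraph)

    def attr_block(self) -> dict:
        attrs: dict[str, str] = {}
        self.take("[")
        while self.peek() != "]":
            key = self.take_id()
            self.take("=")
            attrs[key] = self.take_id()
            if self.peek() == ",":
                self.take(",")
        self.take("]")
        return attrs

    def stmt(self, g: DotGraph, subgraph: str | None) -> None:
        tok = self.peek()
        if tok == "subgraph":
            self.take("subgraph")
            name = self.take_id() if self.peek() != "{" else ""
            g.subgraph_nodes.setdefault(name, [])
            self.take("{")
            self.stmt_list(g, name)
            self.take("}")
            return
        ident = self.take_id()
        nxt = self.peek()
        if nxt == "->":
            self.take("->")
            dest = self.take_id()
            attrs = self.attr_block() if self.peek() == "[" else {}
            g.edges.append((ident, dest, attrs))
        elif nxt == "=":
            self.take("=")
            self.take()  # graph-level attribute value
        elif nxt == "[":
            attrs = self.attr_block()
            if ident in ("graph", "node", "edge"):
                pass  # default-attribute statement
            else:
                if ident in g.nodes:
                    raise DotSyntaxError(f"node {ident!r} defined twice")
                g.nodes[ident] = attrs
                if subgraph is not None:
                    g.subgraph_nodes[subgraph].append(ident)
        else:
            raise DotSyntaxError(f"cannot parse statement starting at {ident!r}")
        if self.peek() == ";":
            self.take(";")


def parse_dot(text: str) -> DotGraph:
    """Parse DOT text; raises DotSyntaxError on any grammar violation."""
    return _Parser(_tokenize(text)).parse()
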