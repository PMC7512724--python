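"""Readers and writers: BIF and XMLBIF networks, panel JSON, covariate CSV.

The BIF dialect is the classic Interchange-Format grammar with one
extension: identifiers (node and state names) containing characters
outside ``[A-Za-z0-9_.+-]`` are written in double quotes, so node names
with spaces survive round-trips.  Probability rows are listed in canonical
parent-tuple order (last parent fastest), matching the in-memory layout.

All writers are bit-stable: fixed ordering (node declaration order, parent
order as declared), floats at 17 significant digits, ``\\n`` newlines.
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .bn_core import CPT, DiscreteBayesNet, StateSpace, require_valid
from .errors import InputError, ParseError
from .panel import ExpertAssessment, ExpertPanel, require_valid_panel

PANEL_SCHEMA_VERSION = 1

_WORD = re.compile(r"[A-Za-z0-9_.+-]+")


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _quote(name: str) -> str:
    return name if _WORD.fullmatch(name) else '"' + name.replace('"', '\\"') + '"'


# ---------------------------------------------------------------------------
# BIF
# ---------------------------------------------------------------------------

_TOKEN = re.compile(
    r"""\s*(?:
        (?P<comment>//[^\n]*|/\*.*?\*/)
      | (?P<string>"(?:[^"\\]|\\.)*")
      | (?P<word>[A-Za-z0-9_.+-]+)
      | (?P<punct>[{}()\[\]|,;=])
    )""",
    re.VERBOSE | re.DOTALL,
)


def _tokenize_bif(text: str, path: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos, line = 0, 1
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"{path}:{line}: unexpected character {text[pos]!r}")
        line += text[pos : m.end()].count("\n")
        pos = m.end()
        if m.lastgroup == "comment":
            continue
        tok = m.group()
        if m.lastgroup == "string":
            tok = tok.strip()[1:-1].replace('\\"', '"')
        else:
            tok = tok.strip()
        tokens.append((tok, line))
    return tokens


class _BifReader:
    def __init__(self, tokens, path):
        self.tokens = tokens
        self.path = path
        self.i = 0

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def next(self):
        if self.i >= len(self.tokens):
            raise ParseError(f"{self.path}: unexpected end of file")
        tok, _ = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, tok):
        got = self.next()
        if got != tok:
            line = self.tokens[self.i - 1][1]
            raise ParseError(f"{self.path}:{line}: expected {tok!r}, got {got!r}")
        return got

    def skip_block(self):
        self.expect("{")
        depth = 1
        while depth:
            tok = self.next()
            depth += {"{": 1, "}": -1}.get(tok, 0)


def read_bif(path) -> DiscreteBayesNet:
    path = Path(path)
    r = _BifReader(_tokenize_bif(path.read_text(), str(path)), str(path))
    nodes: dict[str, StateSpace] = {}
    cpts: list[CPT] = []

    while r.peek() is not None:
        kw = r.next()
        if kw == "network":
            r.next()  # name
            r.skip_block()
        elif kw == "variable":
            name = r.next()
            r.expect("{")
            states: tuple[str, ...] | None = None
            while r.peek() != "}":
                inner = r.next()
                if inner == "type":
                    r.expect("discrete")
                    r.expect("[")
                    n = int(r.next())
                    r.expect("]")
                    r.expect("{")
                    states = []
                    while r.peek() != "}":
                        tok = r.next()
                        if tok != ",":
                            states.append(tok)
                    r.expect("}")
                    r.expect(";")
                    states = tuple(states)
                    if len(states) != n:
                        raise ParseError(
                            f"{path}: variable {name!r} declares {n} states, lists {len(states)}"
                        )
                elif inner == "property":
                    while r.next() != ";":
                        pass
                else:
                    raise ParseError(f"{path}: unexpected {inner!r} in variable {name!r}")
            r.expect("}")
            if states is None:
                raise ParseError(f"{path}: variable {name!r} has no type declaration")
            nodes[name] = StateSpace(name, states)
        elif kw == "probability":
            r.expect("(")
            child = r.next()
            parents: list[str] = []
            if r.peek() == "|":
                r.next()
                while r.peek() != ")":
                    tok = r.next()
                    if tok != ",":
                        parents.append(tok)
            r.expect(")")
            if child not in nodes:
                raise ParseError(f"{path}: probability block for undeclared variable {child!r}")
            for p in parents:
                if p not in nodes:
                    raise ParseError(f"{path}: undeclared parent {p!r} of {child!r}")
            child_states = nodes[child].states
            parent_states = [nodes[p].states for p in parents]
            n_rows = int(np.prod([len(s) for s in parent_states])) if parents else 1
            table = np.full((n_rows, len(child_states)), np.nan)
            template = CPT(
                child, child_states, parents, parent_states,
                np.full((n_rows, len(child_states)), 1.0 / len(child_states)),
            )
            r.expect("{")
            while r.peek() != "}":
                tok = r.next()
                if tok == "table":
                    vals = []
                    while r.peek() != ";":
                        t = r.next()
                        if t != ",":
                            vals.append(float(t))
                    r.expect(";")
                    if len(vals) != table.size:
                        raise ParseError(
                            f"{path}: table for {child!r} has {len(vals)} values, needs {table.size}"
                        )
                    table = np.asarray(vals).reshape(table.shape)
                elif tok == "(":
                    combo = []
                    while r.peek() != ")":
                        t = r.next()
                        if t != ",":
                            combo.append(t)
                    r.expect(")")
                    vals = []
                    while r.peek() != ";":
                        t = r.next()
                        if t != ",":
                            vals.append(float(t))
                    r.expect(";")
                    if len(vals) != len(child_states):
                        raise ParseError(
                            f"{path}: row {tuple(combo)} of {child!r} has {len(vals)} values"
                        )
                    table[template.row_index(combo)] = vals
                else:
                    raise ParseError(f"{path}: unexpected {tok!r} in probability block of {child!r}")
            r.expect("}")
            if np.isnan(table).any():
                raise ParseError(f"{path}: probability block of {child!r} leaves rows undefined")
            cpts.append(CPT(child, child_states, parents, parent_states, table))
        else:
            raise ParseError(f"{path}: unexpected top-level token {kw!r}")

    edges = {(p, c.child) for c in cpts for p in c.parents}
    net = DiscreteBayesNet(nodes, edges, cpts)
    require_valid(net)
    return net


def write_bif(net: DiscreteBayesNet, path, name: str = "network") -> None:
    require_valid(net)
    lines = [f"network {_quote(name)} {{", "}"]
    for node, space in net.nodes.items():
        lines.append(f"variable {_quote(node)} {{")
        lines.append(
            f"  type discrete [ {len(space.states)} ] {{ "
            + ", ".join(_quote(s) for s in space.states)
            + " };"
        )
        lines.append("}")
    for node in net.nodes:
        cpt = net.cpts[node]
        if cpt.parents:
            header = (
                f"probability ( {_quote(node)} | "
                + ", ".join(_quote(p) for p in cpt.parents)
                + " ) {"
            )
            lines.append(header)
            for i, combo in enumerate(cpt.parent_combinations()):
                lines.append(
                    "  ( " + ", ".join(_quote(s) for s in combo) + " ) "
                    + ", ".join(_fmt(v) for v in cpt.table[i]) + ";"
                )
        else:
            lines.append(f"probability ( {_quote(node)} ) {{")
            lines.append("  table " + ", ".join(_fmt(v) for v in cpt.table[0]) + ";")
        lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XMLBIF
# ---------------------------------------------------------------------------

def write_xmlbif(net: DiscreteBayesNet, path, name: str = "network") -> None:
    require_valid(net)

    def esc(s):
        return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")

    lines = ['<?xml version="1.0" encoding="UTF-8"?>', '<BIF VERSION="0.3">', "<NETWORK>"]
    lines.append(f"<NAME>{esc(name)}</NAME>")
    for node, space in net.nodes.items():
        lines.append('<VARIABLE TYPE="nature">')
        lines.append(f"  <NAME>{esc(node)}</NAME>")
        for s in space.states:
            lines.append(f"  <OUTCOME>{esc(s)}</OUTCOME>")
        lines.append("</VARIABLE>")
    for node in net.nodes:
        cpt = net.cpts[node]
        lines.append("<DEFINITION>")
        lines.append(f"  <FOR>{esc(node)}</FOR>")
        for p in cpt.parents:
            lines.append(f"  <GIVEN>{esc(p)}</GIVEN>")
        lines.append("  <TABLE>" + " ".join(_fmt(v) for v in cpt.table.ravel()) + "</TABLE>")
        lines.append("</DEFINITION>")
    lines += ["</NETWORK>", "</BIF>"]
    Path(path).write_text("\n".join(lines) + "\n")


def read_xmlbif(path) -> DiscreteBayesNet:
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"{path}: not well-formed XML ({exc})") from None
    network = root.find("NETWORK")
    if network is None:
        raise ParseError(f"{path}: no <NETWORK> element")
    nodes: dict[str, StateSpace] = {}
    for var in network.findall("VARIABLE"):
        name_el = var.find("NAME")
        if name_el is None or not name_el.text:
            raise ParseError(f"{path}: <VARIABLE> without <NAME>")
        name = name_el.text
        states = tuple(o.text for o in var.findall("OUTCOME"))
        if any(s is None for s in states):
            raise ParseError(f"{path}: empty <OUTCOME> in variable {name!r}")
        nodes[name] = StateSpace(name, states)
    cpts = []
    for definition in network.findall("DEFINITION"):
        child = definition.findtext("FOR")
        if child not in nodes:
            raise ParseError(f"{path}: <DEFINITION> for undeclared variable {child!r}")
        parents = [g.text for g in definition.findall("GIVEN")]
        for p in parents:
            if p not in nodes:
                raise ParseError(f"{path}: undeclared parent {p!r} of {child!r}")
        table_text = definition.findtext("TABLE") or ""
        vals = np.array([float(v) for v in table_text.split()])
        child_states = nodes[child].states
        parent_states = [nodes[p].states for p in parents]
        n_rows = int(np.prod([len(s) for s in parent_states])) if parents else 1
        if vals.size != n_rows * len(child_states):
            raise ParseError(
                f"{path}: <TABLE> for {child!r} has {vals.size} values, "
                f"needs {n_rows * len(child_states)}"
            )
        cpts.append(
            CPT(child, child_states, parents, parent_states, vals.reshape(n_rows, len(child_states)))
        )
    edges = {(p, c.child) for c in cpts for p in c.parents}
    net = DiscreteBayesNet(nodes, edges, cpts)
    require_valid(net)
    return net


# ---------------------------------------------------------------------------
# Format dispatch
# ---------------------------------------------------------------------------

def _infer_format(path, fmt: str | None) -> str:
    if fmt:
        fmt = fmt.lower()
        if fmt not in ("bif", "xmlbif"):
            raise InputError(f"unknown network format {fmt!r} (use 'bif' or 'xmlbif')")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".bif":
        return "bif"
    if suffix in (".xml", ".xmlbif"):
        return "xmlbif"
    raise InputError(f"cannot infer format from {path!r}; pass format='bif' or 'xmlbif'")


def read_network(path, format: str | None = None) -> DiscreteBayesNet:
    """Read a validated network from BIF or XMLBIF (inferred from suffix)."""
    fmt = _infer_format(path, format)
    return read_bif(path) if fmt == "bif" else read_xmlbif(path)


def write_network(net: DiscreteBayesNet, path, format: str | None = None, name: str = "network") -> None:
    fmt = _infer_format(path, format)
    (write_bif if fmt == "bif" else write_xmlbif)(net, path, name=name)


# ---------------------------------------------------------------------------
# Panel JSON
# ---------------------------------------------------------------------------

def panel_to_dict(panel: ExpertPanel) -> dict:
    structure = panel.structure
    return {
        "version": PANEL_SCHEMA_VERSION,
        "structure": {
            "nodes": [
                {"name": n, "states": list(s.states)} for n, s in structure.nodes.items()
            ],
            "parents": {
                node: list(panel.experts[0].cpts[node].parents) for node in structure.nodes
            }
            if panel.experts
            else {node: [] for node in structure.nodes},
        },
        "experts": [
            {
                "id": e.expert_id,
                "cpts": {node: e.cpts[node].table.tolist() for node in structure.nodes},
            }
            for e in panel.experts
        ],
        "covariates": {e.expert_id: dict(panel.covariates[e.expert_id]) for e in panel.experts},
        "weights": {e.expert_id: panel.weights[e.expert_id] for e in panel.experts},
    }


def panel_from_dict(data: Mapping, source: str = "<panel>") -> ExpertPanel:
    try:
        version = data["version"]
        if version != PANEL_SCHEMA_VERSION:
            raise ParseError(f"{source}: unsupported panel schema version {version!r}")
        nodes = {
            item["name"]: StateSpace(item["name"], tuple(item["states"]))
            for item in data["structure"]["nodes"]
        }
        parents = {node: list(ps) for node, ps in data["structure"]["parents"].items()}
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{source}: malformed panel file ({exc!r})") from None
    unknown = set(parents) - set(nodes)
    if unknown:
        raise ParseError(f"{source}: parents declared for unknown node(s) {sorted(unknown)}")
    edges = {(p, child) for child, ps in parents.items() for p in ps}
    structure = DiscreteBayesNet(nodes, edges, {})

    experts = []
    for item in data.get("experts", []):
        eid = str(item["id"])
        cpts = {}
        for node, space in nodes.items():
            if node not in item.get("cpts", {}):
                raise ParseError(f"{source}: expert {eid!r} has no CPT for node {node!r}")
            ps = parents.get(node, [])
            cpts[node] = CPT(
                node,
                space.states,
                ps,
                [nodes[p].states for p in ps],
                np.asarray(item["cpts"][node], dtype=float),
            )
        experts.append(ExpertAssessment(eid, cpts))

    covariates = {str(k): dict(v) for k, v in data.get("covariates", {}).items()}
    weights = data.get("weights") or None  # missing block -> equal weights
    if weights is not None:
        weights = {str(k): float(v) for k, v in weights.items()}
    return ExpertPanel(structure, experts, covariates, weights)


def write_panel(panel: ExpertPanel, path) -> None:
    require_valid_panel(panel)
    Path(path).write_text(json.dumps(panel_to_dict(panel), indent=1) + "\n")


def read_panel(path) -> ExpertPanel:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from None
    panel = panel_from_dict(data, source=str(path))
    require_valid_panel(panel)
    return panel


# ---------------------------------------------------------------------------
# Covariate CSV
# ---------------------------------------------------------------------------

def read_covariates_csv(path) -> dict[str, dict[str, str]]:
    """CSV with an ``expert_id`` first column; remaining columns are covariates."""
    df = pd.read_csv(path, dtype=str).fillna("missing")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: covariate CSV needs expert_id plus >= 1 covariate column")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate expert_id {dup!r}")
    return {
        row[id_col]: {c: row[c] for c in df.columns[1:]} for _, row in df.iterrows()
    }


def write_covariates_csv(covariates: Mapping[str, Mapping[str, str]], path) -> None:
    names: dict[str, None] = {}
    for row in covariates.values():
        for k in row:
            names.setdefault(k)
    df = pd.DataFrame(
        [
            {"expert_id": eid, **{k: row.get(k, "missing") for k in names}}
            for eid, row in covariates.items()
        ]
    )
    df.to_csv(path, index=False)
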