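"""File formats: set-system text/JSON, Newick trees, triple lists.

Set-system text format: UTF-8, one block per line with comma-separated
taxon labels; ``#`` starts a comment, blank lines are ignored.  An
optional ``taxa:`` header line declares the universe when it exceeds
the leaf union.  The canonical writer sorts taxa within each line and
lines lexicographically, so write-then-read is the identity on
canonical form.

JSON dialect: ``{"taxa": [...], "blocks": [[...], ...]}`` with the
same invariants.  Extension selects the dialect (.json versus
anything else).

Newick reading is delegated to dendropy and converted to the package's
RootedTree (leaf labels only; internal labels and branch lengths are
tolerated and dropped); writing uses the canonical writer that orders
children by smallest descendant leaf.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import dendropy

from .set_systems import SetSystem, SetSystemError
from .trees import RootedTree, RootedTriple, TreeNode, TripleSet

__all__ = [
    "read_set_system",
    "write_set_system",
    "parse_set_system_text",
    "format_set_system_text",
    "read_newick",
    "write_newick",
    "parse_newick",
    "read_triples",
    "write_triples",
    "ParseError",
]


class ParseError(SetSystemError):
    """Malformed input file; carries a line number where applicable."""


# ---------------------------------------------------------------------------
# Set systems
# ---------------------------------------------------------------------------

def parse_set_system_text(text: str) -> SetSystem:
    blocks: list[list[str]] = []
    universe: list[str] | None = None
    seen: set[frozenset] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("taxa:"):
            universe = [t.strip() for t in line[5:].split(",") if t.strip()]
            continue
        members = [t.strip() for t in line.split(",")]
        if any(not m for m in members):
            raise ParseError(f"line {lineno}: empty taxon label in {raw!r}")
        key = frozenset(members)
        if key in seen:
            raise ParseError(f"line {lineno}: duplicate block {sorted(key)}")
        seen.add(key)
        blocks.append(members)
    try:
        return SetSystem(blocks, universe=universe)
    except SetSystemError as e:
        raise ParseError(str(e)) from e


def format_set_system_text(system: SetSystem) -> str:
    lines = sorted(",".join(sorted(b)) for b in system.blocks)
    out = []
    if system.universe != system.leaves:
        out.append("taxa: " + ",".join(sorted(system.universe)))
    out.extend(lines)
    return "\n".join(out) + "\n"


def read_set_system(path: str | Path) -> SetSystem:
    """Read a set system from text or JSON (detected by extension)."""
    path = Path(path)
    data = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        try:
            obj = json.loads(data)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: invalid JSON: {e}") from e
        if not isinstance(obj, dict) or "blocks" not in obj:
            raise ParseError(f"{path}: JSON dialect requires a 'blocks' key")
        blocks = obj["blocks"]
        seen: set[frozenset] = set()
        for b in blocks:
            key = frozenset(b)
            if key in seen:
                raise ParseError(f"{path}: duplicate block {sorted(key)}")
            seen.add(key)
        try:
            return SetSystem(blocks, universe=obj.get("taxa"))
        except SetSystemError as e:
            raise ParseError(f"{path}: {e}") from e
    return parse_set_system_text(data)


def write_set_system(system: SetSystem, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = {
            "taxa": sorted(system.universe),
            "blocks": [sorted(b) for b in sorted(system.blocks, key=sorted)],
        }
        path.write_text(json.dumps(obj, indent=1) + "\n", encoding="utf-8")
    else:
        path.write_text(format_set_system_text(system), encoding="utf-8")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string into a RootedTree.

    Branch lengths and internal labels are dropped; unary vertices are
    suppressed; duplicate leaf labels are an error.
    """
    text = text.strip()
    if text.startswith("[&U]"):
        text = text[4:].strip()
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as e:  # dendropy raises several error types
        raise ParseError(f"invalid Newick: {e}") from e

    def conv(dnode) -> TreeNode:
        kids = dnode.child_nodes()
        if not kids:
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is None:
                raise ParseError("Newick leaf without a label")
            return TreeNode(label.replace(" ", "_"))
        if len(kids) == 1:
            return conv(kids[0])
        node = TreeNode()
        for k in kids:
            node.add(conv(k))
        return node

    root = conv(dtree.seed_node)
    if root.is_leaf:
        raise ParseError("tree must have at least 2 leaves")
    try:
        return RootedTree(root)
    except SetSystemError as e:
        raise ParseError(str(e)) from e


def read_newick(path: str | Path) -> RootedTree:
    return parse_newick(Path(path).read_text(encoding="utf-8"))


def write_newick(tree, path: str | Path) -> None:
    """Write a RootedTree or UnrootedTree in canonical Newick form."""
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Triple lists
# ---------------------------------------------------------------------------

def read_triples(path: str | Path) -> TripleSet:
    """One triple per line in 'a,b|c' form; comments and blanks ignored."""
    out: list[RootedTriple] = []
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            out.append(RootedTriple.parse(line))
        except SetSystemError as e:
            raise ParseError(f"line {lineno}: {e}") from e
    return TripleSet(out)


def write_triples(triples: Iterable[RootedTriple], path: str | Path) -> None:
    lines = sorted(str(t) for t in triples)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
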