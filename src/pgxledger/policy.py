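"""Patient permission policies as decision trees.

A patient's consent is an allow-set of (drug, role, purpose) triples. The
set is compiled into a three-level decision tree — drug nodes, then role
nodes, then purpose leaves — whose equivalent Boolean formula is the OR
over allowed triples of AND(drug=d, role=r, purpose=p). A request is
granted iff walking the tree reaches a leaf; an empty tree denies
everything (default deny). Triples match exactly: no wildcards.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import Revert
from . import vocab

# tree shape: {drug: {role: [purpose, ...]}} with sorted keys/lists so the
# compiled form is canonical and replay-stable
Tree = dict[str, dict[str, list[str]]]
TripleTuple = tuple[str, str, str]


@dataclass(frozen=True, order=True)
class PermissionTriple:
    drug: str
    role: str
    purpose: str

    def as_tuple(self) -> TripleTuple:
        return (self.drug, self.role, self.purpose)

    def as_dict(self) -> dict[str, str]:
        return {"drug": self.drug, "role": self.role, "purpose": self.purpose}


def validate_triple(triple: TripleTuple | PermissionTriple) -> PermissionTriple:
    """Check each element against its closed vocabulary."""
    if isinstance(triple, PermissionTriple):
        d, r, p = triple.as_tuple()
    else:
        try:
            d, r, p = triple
        except (TypeError, ValueError):
            raise Revert("BAD_TRIPLE", f"not a triple: {triple!r}") from None
    if d not in vocab.drugs():
        raise Revert("BAD_TRIPLE", f"unknown drug {d!r}")
    if r not in vocab.roles():
        raise Revert("BAD_TRIPLE", f"unknown role {r!r}")
    if p not in vocab.purposes():
        raise Revert("BAD_TRIPLE", f"unknown purpose {p!r}")
    return PermissionTriple(d, r, p)


def compile_tree(triples) -> Tree:
    """Compile an allow-set into its canonical decision tree."""
    staged: dict[str, dict[str, set[str]]] = {}
    for t in triples:
        d, r, p = t.as_tuple() if isinstance(t, PermissionTriple) else tuple(t)
        staged.setdefault(d, {}).setdefault(r, set()).add(p)
    return {
        d: {r: sorted(ps) for r, ps in sorted(role_map.items())}
        for d, role_map in sorted(staged.items())
    }


def evaluate_tree(tree: Tree, drug: str, role: str, purpose: str) -> bool:
    """Walk drug → role → purpose; True iff the walk reaches a leaf."""
    role_map = tree.get(drug)
    if role_map is None:
        return False
    leaves = role_map.get(role)
    if leaves is None:
        return False
    return purpose in leaves


def tree_triples(tree: Tree) -> list[TripleTuple]:
    return [
        (d, r, p)
        for d, role_map in tree.items()
        for r, leaves in role_map.items()
        for p in leaves
    ]


def boolean_formula(tree: Tree) -> str:
    """Human-readable Boolean form of the tree (OR of AND-clauses)."""
    clauses = [
        f"(drug={d} AND role={r} AND purpose={p})"
        for d, r, p in tree_triples(tree)
    ]
    return " OR ".join(clauses) if clauses else "FALSE"
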