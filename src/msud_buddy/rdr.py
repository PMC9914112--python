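"""Single-classification ripple-down-rules (RDR) engine.

An RDR tree encodes expert knowledge as a binary tree of rules.  Each node
holds a condition, a conclusion, and the *cornerstone case* that motivated
the rule.  Inference walks the tree: when a node's condition holds the walk
descends into the exception child (``except_child``), otherwise into the
alternative child (``alt_child``); the conclusion of the last node whose
condition held is returned.  The root carries the always-true condition, so
a conclusion always exists.

Knowledge acquisition is incremental and conservative: a new rule is
attached exactly where inference ended for the misclassified case, and the
addition is rejected outright if it would change the conclusion of any
previously registered cornerstone case.  Past behaviour is therefore never
silently altered — the property that makes RDR suitable for clinical
knowledge bases maintained by a domain expert rather than a programmer.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping

from .errors import ConfigurationError, RuleRejectedError, SchemaError

#: Value types a case attribute may take.
AttrValue = float | int | str | bool

#: Comparison operators of the condition language.  ``present``/``absent``
#: test attribute existence and ignore the literal.
OPERATORS = ("==", "!=", "<", "<=", ">", ">=", "present", "absent")


# ---------------------------------------------------------------------------
# Cases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Case:
    """A flat attribute -> value record fed to the engine.

    Absent attributes are simply missing keys: absence is distinguishable
    from ``0`` and from ``""``.
    """

    attributes: Mapping[str, AttrValue]

    def __post_init__(self) -> None:
        for name in self.attributes:
            if not isinstance(name, str) or not name:
                raise ConfigurationError(f"Case attribute names must be non-empty strings, got {name!r}")
        object.__setattr__(self, "attributes", dict(self.attributes))

    def get(self, name: str) -> AttrValue | None:
        return self.attributes.get(name)

    def __contains__(self, name: str) -> bool:
        return name in self.attributes

    def to_dict(self) -> dict[str, AttrValue]:
        return dict(self.attributes)


# ---------------------------------------------------------------------------
# Conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A single comparison ``attr op value``."""

    attr: str
    op: str
    value: AttrValue | None = None

    def __post_init__(self) -> None:
        if self.op not in OPERATORS:
            raise ConfigurationError(
                f"Unknown operator {self.op!r} in comparison on {self.attr!r}; "
                f"supported operators: {', '.join(OPERATORS)}"
            )

    def holds(self, case: Case) -> bool:
        if self.op == "present":
            return self.attr in case
        if self.op == "absent":
            return self.attr not in case
        if self.attr not in case:
            # Comparisons on absent attributes are false, letting partial
            # cases fall through to the default conclusion.
            return False
        actual = case.get(self.attr)
        if self.op == "==":
            return actual == self.value
        if self.op == "!=":
            return actual != self.value
        try:
            if self.op == "<":
                return actual < self.value  # type: ignore[operator]
            if self.op == "<=":
                return actual <= self.value  # type: ignore[operator]
            if self.op == ">":
                return actual > self.value  # type: ignore[operator]
            if self.op == ">=":
                return actual >= self.value  # type: ignore[operator]
        except TypeError:
            return False
        raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class Condition:
    """A conjunction of atoms; the empty conjunction is always true."""

    atoms: tuple[Atom, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def is_always_true(self) -> bool:
        return not self.atoms

    def describe(self) -> str:
        if not self.atoms:
            return "TRUE"
        parts = []
        for a in self.atoms:
            if a.op in ("present", "absent"):
                parts.append(f"{a.attr} {a.op}")
            else:
                parts.append(f"{a.attr} {a.op} {a.value!r}")
        return " AND ".join(parts)


ALWAYS_TRUE = Condition()


def evaluate_condition(condition: Condition, case: Case) -> bool:
    """True iff every atomic comparison of ``condition`` holds on ``case``.

    Total and side-effect free: a comparison against an absent attribute is
    false (the ``absent`` operator being the one exception).
    """
    return all(atom.holds(case) for atom in condition.atoms)


# ---------------------------------------------------------------------------
# Conclusions and nodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Conclusion:
    label: str
    payload: Mapping[str, AttrValue] = field(default_factory=dict)
    explanation: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            raise ConfigurationError("Conclusion label must be non-empty")
        object.__setattr__(self, "payload", dict(self.payload))


@dataclass
class RDRNode:
    id: str
    condition: Condition
    conclusion: Conclusion
    cornerstone: Case
    except_child: "RDRNode | None" = None
    alt_child: "RDRNode | None" = None


class RDRTree:
    """An exception/alternative rule tree with its cornerstone registry."""

    def __init__(self, root: RDRNode):
        if not root.condition.is_always_true:
            raise ConfigurationError("Root condition must be the always-true condition")
        self.root = root
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.nodes():
            if node.id in seen:
                raise ConfigurationError(f"Duplicate node id {node.id!r} in RDR tree")
            seen.add(node.id)

    def nodes(self) -> Iterator[RDRNode]:
        """Pre-order traversal (except child before alt child)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if node.alt_child is not None:
                stack.append(node.alt_child)
            if node.except_child is not None:
                stack.append(node.except_child)

    def node_count(self) -> int:
        return sum(1 for _ in self.nodes())

    @property
    def cornerstones(self) -> list[tuple[str, Case]]:
        """All registered cornerstone cases as (node id, case) pairs."""
        return [(n.id, n.cornerstone) for n in self.nodes()]

    def _next_id(self) -> str:
        existing = {n.id for n in self.nodes()}
        for i in itertools.count(1):
            cand = f"n{i}"
            if cand not in existing:
                return cand
        raise AssertionError("unreachable")  # pragma: no cover

    # -- inference ---------------------------------------------------------

    def infer(self, case: Case) -> tuple[Conclusion, list[str]]:
        """Classify ``case``; returns (conclusion, fired node-id path).

        Deterministic and total: the walk visits each node at most once, so
        the fired path is bounded by the node count, and the root's
        always-true condition guarantees a conclusion.
        """
        fired_path: list[str] = []
        last_satisfied = self.root
        node: RDRNode | None = self.root
        while node is not None:
            fired_path.append(node.id)
            if evaluate_condition(node.condition, case):
                last_satisfied = node
                node = node.except_child
            else:
                node = node.alt_child
        return last_satisfied.conclusion, fired_path

    # -- acquisition -------------------------------------------------------

    def add_rule(
        self,
        misclassified: Case,
        new_condition: Condition,
        new_conclusion: Conclusion,
        node_id: str | None = None,
    ) -> "RDRTree":
        """Attach a new rule at the point where inference ended for
        ``misclassified`` and return ``self``.

        The new node's cornerstone is ``misclassified``.  The addition is
        rejected (tree unchanged) if ``new_condition`` is false on the case
        or if re-inference on any stored cornerstone would change its
        conclusion.
        """
        if not evaluate_condition(new_condition, misclassified):
            raise RuleRejectedError(
                "New rule rejected: its condition "
                f"({new_condition.describe()}) is false on its own cornerstone case"
            )

        # Replay the walk to find the attachment point.
        last_visited = self.root
        last_satisfied_was_last_visited = True
        node: RDRNode | None = self.root
        while node is not None:
            last_visited = node
            if evaluate_condition(node.condition, misclassified):
                last_satisfied_was_last_visited = True
                node = node.except_child
            else:
                last_satisfied_was_last_visited = False
                node = node.alt_child

        new_node = RDRNode(
            id=node_id if node_id is not None else self._next_id(),
            condition=new_condition,
            conclusion=new_conclusion,
            cornerstone=misclassified,
        )
        if new_node.id in {n.id for n in self.nodes()}:
            raise ConfigurationError(f"Node id {new_node.id!r} already exists in tree")

        before = {nid: self.infer(c)[0].label for nid, c in self.cornerstones}
        if last_satisfied_was_last_visited:
            last_visited.except_child = new_node
            attached = ("except", last_visited)
        else:
            last_visited.alt_child = new_node
            attached = ("alt", last_visited)

        # Cornerstone preservation check; roll back on conflict.
        for nid, cornerstone in before.items():
            conclusion, _ = self.infer(
                next(c for i, c in self.cornerstones if i == nid)
            )
            if conclusion.label != cornerstone:
                slot, parent = attached
                if slot == "except":
                    parent.except_child = None
                else:
                    parent.alt_child = None
                raise RuleRejectedError(
                    f"New rule rejected: it would change the conclusion of "
                    f"cornerstone case registered at node {nid!r} "
                    f"(was {cornerstone!r})",
                    conflicting_cornerstone=nid,
                )

        conclusion, _ = self.infer(misclassified)
        if conclusion.label != new_conclusion.label:  # pragma: no cover - by construction
            slot, parent = attached
            if slot == "except":
                parent.except_child = None
            else:
                parent.alt_child = None
            raise RuleRejectedError(
                "New rule rejected: after attachment the misclassified case "
                f"still concludes {conclusion.label!r}"
            )
        return self


def new_tree(default_conclusion: Conclusion, root_id: str = "root", cornerstone: Case | None = None) -> RDRTree:
    """A fresh single-node tree whose root always fires ``default_conclusion``."""
    root = RDRNode(
        id=root_id,
        condition=ALWAYS_TRUE,
        conclusion=default_conclusion,
        cornerstone=cornerstone if cornerstone is not None else Case({}),
    )
    return RDRTree(root)


# ---------------------------------------------------------------------------
# Persistence (JSON dialect, version 1)
# ---------------------------------------------------------------------------
#
# {"version": 1,
#  "nodes": [{"id": ..., "condition": [{"attr","op","value"}],
#             "conclusion": {"label","payload","explanation"},
#             "cornerstone": {...}, "except": id|null, "alt": id|null}],
#  "root": id}

_NODE_KEYS = {"id", "condition", "conclusion", "cornerstone", "except", "alt"}
_ATOM_KEYS = {"attr", "op", "value"}
_CONCLUSION_KEYS = {"label", "payload", "explanation"}


def save_tree(tree: RDRTree) -> dict[str, Any]:
    """Serialize to the version-1 JSON document (as a plain dict)."""
    nodes = []
    for node in tree.nodes():
        nodes.append(
            {
                "id": node.id,
                "condition": [
                    {"attr": a.attr, "op": a.op, "value": a.value}
                    for a in node.condition.atoms
                ],
                "conclusion": {
                    "label": node.conclusion.label,
                    "payload": dict(node.conclusion.payload),
                    "explanation": node.conclusion.explanation,
                },
                "cornerstone": node.cornerstone.to_dict(),
                "except": node.except_child.id if node.except_child else None,
                "alt": node.alt_child.id if node.alt_child else None,
            }
        )
    return {"version": 1, "nodes": nodes, "root": tree.root.id}


def _require_keys(obj: Any, keys: set[str], path: str) -> None:
    if not isinstance(obj, dict):
        raise SchemaError(path, f"expected an object, got {type(obj).__name__}")
    unknown = set(obj) - keys
    if unknown:
        raise SchemaError(f"{path}.{sorted(unknown)[0]}", "unknown key")
    missing = keys - set(obj)
    if missing:
        raise SchemaError(f"{path}.{sorted(missing)[0]}", "missing required key")


def load_tree(document: dict[str, Any]) -> RDRTree:
    """Rebuild a tree from its JSON document; rejects unknown keys and
    dangling child references, naming the first invalid path."""
    _require_keys(document, {"version", "nodes", "root"}, "$")
    if document["version"] != 1:
        raise SchemaError("$.version", f"unsupported version {document['version']!r}")
    raw_nodes = document["nodes"]
    if not isinstance(raw_nodes, list) or not raw_nodes:
        raise SchemaError("$.nodes", "expected a non-empty array")

    nodes: dict[str, RDRNode] = {}
    children: dict[str, tuple[Any, Any]] = {}
    for i, raw in enumerate(raw_nodes):
        path = f"$.nodes[{i}]"
        _require_keys(raw, _NODE_KEYS, path)
        if not isinstance(raw["id"], str) or not raw["id"]:
            raise SchemaError(f"{path}.id", "expected a non-empty string")
        if raw["id"] in nodes:
            raise SchemaError(f"{path}.id", f"duplicate node id {raw['id']!r}")
        if not isinstance(raw["condition"], list):
            raise SchemaError(f"{path}.condition", "expected an array of comparisons")
        atoms = []
        for j, raw_atom in enumerate(raw["condition"]):
            apath = f"{path}.condition[{j}]"
            _require_keys(raw_atom, _ATOM_KEYS, apath)
            try:
                atoms.append(Atom(raw_atom["attr"], raw_atom["op"], raw_atom["value"]))
            except ConfigurationError as exc:
                raise SchemaError(f"{apath}.op", str(exc)) from exc
        cpath = f"{path}.conclusion"
        _require_keys(raw["conclusion"], _CONCLUSION_KEYS, cpath)
        try:
            conclusion = Conclusion(
                label=raw["conclusion"]["label"],
                payload=raw["conclusion"]["payload"],
                explanation=raw["conclusion"]["explanation"],
            )
        except (ConfigurationError, TypeError) as exc:
            raise SchemaError(cpath, str(exc)) from exc
        if not isinstance(raw["cornerstone"], dict):
            raise SchemaError(f"{path}.cornerstone", "expected an object")
        nodes[raw["id"]] = RDRNode(
            id=raw["id"],
            condition=Condition(tuple(atoms)),
            conclusion=conclusion,
            cornerstone=Case(raw["cornerstone"]),
        )
        children[raw["id"]] = (raw["except"], raw["alt"])

    for i, (nid, (exc_id, alt_id)) in enumerate(children.items()):
        for slot, child_id in (("except", exc_id), ("alt", alt_id)):
            if child_id is None:
                continue
            if child_id not in nodes:
                raise SchemaError(
                    f"$.nodes[{i}].{slot}", f"references nonexistent node id {child_id!r}"
                )
            child = nodes[child_id]
            if slot == "except":
                nodes[nid].except_child = child
            else:
                nodes[nid].alt_child = child

    root_id = document["root"]
    if root_id not in nodes:
        raise SchemaError("$.root", f"references nonexistent node id {root_id!r}")

    tree = RDRTree(nodes[root_id])
    # Every node must be reachable from the root exactly once (acyclicity
    # plus single-parent structure).
    reachable = [n.id for n in tree.nodes()]
    if len(reachable) != len(set(reachable)):
        raise SchemaError("$.nodes", "a node is reachable more than once (not a tree)")
    if set(reachable) != set(nodes):
        orphan = sorted(set(nodes) - set(reachable))[0]
        raise SchemaError("$.nodes", f"node {orphan!r} is not reachable from the root")
    return tree


def save_tree_file(tree: RDRTree, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(save_tree(tree), fh, indent=2)
        fh.write("\n")


def load_tree_file(path: str) -> RDRTree:
    with open(path) as fh:
        try:
            document = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError("$", f"not valid JSON: {exc}") from exc
    return load_tree(document)
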