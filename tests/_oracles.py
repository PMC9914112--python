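"""Independent oracles for property tests.

Each oracle is written deliberately differently from the implementation it
checks: the RDR oracle is a plain recursive evaluator, and the scoop
oracle is an exhaustive grid search over integer scoop pairs.
"""

from __future__ import annotations

import math
import random

import numpy as np

from msud_buddy import BCAAS, Atom, Case, Conclusion, Condition, RDRNode, RDRTree, evaluate_condition


# ---------------------------------------------------------------------------
# RDR inference oracle: recursive, no explicit path bookkeeping
# ---------------------------------------------------------------------------

def _recursive_infer(node, case, inherited):
    """Conclusion of an RDR (sub)tree by direct recursion; ``inherited`` is
    the conclusion in force if no condition below holds."""
    if evaluate_condition(node.condition, case):
        if node.except_child is None:
            return node.conclusion
        return _recursive_infer(node.except_child, case, node.conclusion)
    if node.alt_child is None:
        return inherited
    return _recursive_infer(node.alt_child, case, inherited)


def oracle_infer(tree: RDRTree, case: Case) -> Conclusion:
    return _recursive_infer(tree.root, case, tree.root.conclusion)


# ---------------------------------------------------------------------------
# Random tree / case generators (seeded by the caller)
# ---------------------------------------------------------------------------

ATTRS = ["a", "b", "c"]


def random_case(rng: random.Random) -> Case:
    attrs = {}
    for name in ATTRS:
        if rng.random() < 0.7:
            attrs[name] = rng.randint(0, 10)
    return Case(attrs)


def random_condition(rng: random.Random) -> Condition:
    atoms = []
    for _ in range(rng.randint(1, 2)):
        op = rng.choice(["==", "!=", "<", "<=", ">", ">=", "present", "absent"])
        attr = rng.choice(ATTRS)
        value = rng.randint(0, 10) if op not in ("present", "absent") else None
        atoms.append(Atom(attr, op, value))
    return Condition(tuple(atoms))


def random_tree(rng: random.Random, max_nodes: int = 10) -> RDRTree:
    """A structurally random valid tree (always-true root, unique ids)."""
    root = RDRNode("n0", Condition(), Conclusion("c0"), random_case(rng))
    nodes = [root]
    for i in range(1, rng.randint(1, max_nodes)):
        node = RDRNode(f"n{i}", random_condition(rng), Conclusion(f"c{i}"), random_case(rng))
        free = [
            (parent, slot)
            for parent in nodes
            for slot in ("except_child", "alt_child")
            if getattr(parent, slot) is None
        ]
        parent, slot = rng.choice(free)
        setattr(parent, slot, node)
        nodes.append(node)
    return RDRTree(root)


# ---------------------------------------------------------------------------
# Scoop-allocation oracle: exhaustive grid search
# ---------------------------------------------------------------------------

def grid_search_scoops(allowance, commercial, medical, scoop_grams, min_grid=60):
    """Best (commercial, medical) whole-scoop pair by exhaustive search.

    Selection is lexicographic over all feasible commercial counts:
    maximal commercial scoops — the commercial formula is the sole BCAA
    source and is dosed up to, never over, its limits (a BCAA-free
    commercial formula is bounded by the protein target instead) — then
    the medical count minimizing |delivered protein - target|, with exact
    half-scoop ties resolved to the larger count.  The grid extends past
    ``min_grid`` when a low-BCAA formula admits more scoops than that.
    """
    s = scoop_grams
    if commercial is None:
        best_c = 0
    else:
        caps = [
            allowance.bcaa(b) / (s * commercial.bcaa(b) / 100.0)
            for b in BCAAS
            if commercial.bcaa(b) > 0
        ]
        if not caps:
            caps = [allowance.protein / (s * commercial.protein / 100.0)]
        hi = max(min_grid, int(math.ceil(min(caps))) + 2)
        c = np.arange(hi + 1)
        ok = np.ones(hi + 1, dtype=bool)
        has_bcaa = any(commercial.bcaa(b) > 0 for b in BCAAS)
        for b in BCAAS:
            ok &= c * s * commercial.bcaa(b) / 100.0 <= allowance.bcaa(b)
        if not has_bcaa:
            ok &= c * s * commercial.protein / 100.0 <= allowance.protein
        best_c = int(c[ok].max()) if ok.any() else 0

    cp = (commercial.protein if commercial is not None else 0.0) / 100.0
    residual = allowance.protein - best_c * s * cp
    if medical is None:
        best_m = 0
    else:
        mp = s * medical.protein / 100.0
        hi_m = int(max(min_grid, math.ceil(max(residual, 0.0) / mp) + 2))
        m = np.arange(hi_m + 1)
        err = np.abs(residual - m * mp)
        # minimal protein error; half-scoop ties go to the larger count
        best_m = int(m[np.lexsort((-m, np.round(err, 9)))][0])
    return best_c, best_m
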