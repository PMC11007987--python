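"""Rooted binary phylogenies over isolates.

Only the branching pattern matters for the contrasting-pairs statistic, so
branch lengths are parsed and discarded.  Trees are stored as flat postorder
arrays (children indices, leaf positions) and every algorithm — parsing,
serialization, pruning, UPGMA inference — uses explicit stacks instead of
call-stack recursion, so arbitrarily unbalanced trees (tens of thousands of
leaves) are handled without touching the interpreter recursion limit.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Phylogeny", "parse_newick", "infer_tree", "NewickError"]


class NewickError(ValueError):
    """Malformed newick input (position-annotated where possible)."""


class Phylogeny:
    """Rooted strictly binary tree, nodes indexed in postorder (root last).

    Attributes
    ----------
    left, right : int32 arrays, child node index or -1 for leaves.
    leaf_pos : int32 array, for leaf nodes the index into ``leaf_names``.
    leaf_names : tuple of str, labels in order of postorder appearance.
    """

    __slots__ = ("left", "right", "leaf_pos", "leaf_names")

    def __init__(self, left, right, leaf_pos, leaf_names):
        self.left = np.asarray(left, dtype=np.int32)
        self.right = np.asarray(right, dtype=np.int32)
        self.leaf_pos = np.asarray(leaf_pos, dtype=np.int32)
        self.leaf_names = tuple(leaf_names)

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return len(self.left)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def leaf_index(self) -> dict:
        return {name: i for i, name in enumerate(self.leaf_names)}

    # ------------------------------------------------------------ construction
    @classmethod
    def from_nested(cls, nested) -> "Phylogeny":
        """Build from nested tuples/strings, e.g. ``(("A","B"),("C","D"))``.

        Polytomies (tuples with >2 children) are resolved to binary by a
        left-fold in input order.
        """
        left, right, leaf_pos, leaf_names = [], [], [], []
        seen = set()

        # iterative postorder over the nested structure
        stack = [(nested, False)]
        out = []  # node index stack mirroring construction

        def _new_leaf(name: str) -> int:
            if name in seen:
                raise NewickError(f"duplicate leaf label: {name!r}")
            seen.add(name)
            left.append(-1)
            right.append(-1)
            leaf_pos.append(len(leaf_names))
            leaf_names.append(name)
            return len(left) - 1

        def _new_internal(a: int, b: int) -> int:
            left.append(a)
            right.append(b)
            leaf_pos.append(-1)
            return len(left) - 1

        while stack:
            obj, expanded = stack.pop()
            if isinstance(obj, str):
                out.append(_new_leaf(obj))
            elif not expanded:
                if len(obj) < 2:
                    if len(obj) == 1:  # unary wrapper: collapse
                        stack.append((obj[0], False))
                        continue
                    raise NewickError("empty clade")
                stack.append(((len(obj),), True))
                for child in reversed(obj):
                    stack.append((child, False))
            else:
                k = obj[0]
                kids = out[-k:]
                del out[-k:]
                node = kids[0]
                for nxt in kids[1:]:  # left-fold resolves polytomies
                    node = _new_internal(node, nxt)
                if k > 2:
                    warnings.warn(
                        "polytomy resolved arbitrarily to binary; "
                        "contrasting-pair counts can depend on the resolution",
                        stacklevel=2,
                    )
                out.append(node)
        assert len(out) == 1
        return cls(left, right, leaf_pos, leaf_names)

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return cls.from_nested(_parse_newick_nested(text))

    # ----------------------------------------------------------- serialization
    def to_newick(self) -> str:
        """Serialize topology (no branch lengths) as a newick string."""
        parts = [None] * self.n_nodes
        for i in range(self.n_nodes):
            if self.left[i] < 0:
                parts[i] = _quote_label(self.leaf_names[self.leaf_pos[i]])
            else:
                parts[i] = "(" + parts[self.left[i]] + "," + parts[self.right[i]] + ")"
        return parts[self.root] + ";"

    # ---------------------------------------------------------------- pruning
    def prune(self, keep: Iterable[str]) -> "Phylogeny":
        """Restrict to ``keep`` leaves, collapsing unary internal nodes."""
        keep = set(keep)
        missing = keep - set(self.leaf_names)
        if missing:
            raise ValueError(f"cannot prune: labels not in tree: {sorted(missing)[:5]}")
        if len(keep) < 2:
            raise ValueError("pruning must retain at least 2 leaves")
        nleft, nright, nleaf_pos, nnames = [], [], [], []
        new_id = np.full(self.n_nodes, -1, dtype=np.int64)
        for i in range(self.n_nodes):
            if self.left[i] < 0:
                name = self.leaf_names[self.leaf_pos[i]]
                if name in keep:
                    nleft.append(-1)
                    nright.append(-1)
                    nleaf_pos.append(len(nnames))
                    nnames.append(name)
                    new_id[i] = len(nleft) - 1
            else:
                kids = [new_id[self.left[i]], new_id[self.right[i]]]
                kids = [k for k in kids if k >= 0]
                if len(kids) == 1:
                    new_id[i] = kids[0]  # collapse unary node
                elif len(kids) == 2:
                    nleft.append(kids[0])
                    nright.append(kids[1])
                    nleaf_pos.append(-1)
                    new_id[i] = len(nleft) - 1
        return Phylogeny(nleft, nright, nleaf_pos, nnames)

    # ------------------------------------------------------------- invariants
    def validate(self) -> None:
        n_int = int(np.sum(self.left >= 0))
        if n_int != self.n_leaves - 1:
            raise AssertionError("not a rooted binary tree")
        if len(set(self.leaf_names)) != self.n_leaves:
            raise AssertionError("duplicate leaf labels")

    def canonical_signature(self) -> str:
        """Label-aware canonical form, invariant to child-order swaps.

        Intended for isomorphism checks on small trees (quadratic in size).
        """
        parts = [None] * self.n_nodes
        for i in range(self.n_nodes):
            if self.left[i] < 0:
                parts[i] = self.leaf_names[self.leaf_pos[i]]
            else:
                a, b = parts[self.left[i]], parts[self.right[i]]
                if b < a:
                    a, b = b, a
                parts[i] = "(" + a + "," + b + ")"
        return parts[self.root]


# ---------------------------------------------------------------------- parse
def _tokenize_newick(text: str):
    """Yield (position, token) pairs; comments ``[...]`` are stripped."""
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c == "[":  # comment
            j = text.find("]", i)
            if j < 0:
                raise NewickError(f"unterminated comment at position {i}")
            i = j + 1
        elif c in "(),;:":
            yield i, c
            i += 1
        elif c == "'":
            j = i + 1
            buf = []
            while True:
                if j >= n:
                    raise NewickError(f"unterminated quoted label at position {i}")
                if text[j] == "'":
                    if j + 1 < n and text[j + 1] == "'":  # escaped quote
                        buf.append("'")
                        j += 2
                        continue
                    break
                buf.append(text[j])
                j += 1
            yield i, ("label", "".join(buf))
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in "(),;:[" and not text[j].isspace():
                j += 1
            yield i, ("label", text[i:j])
            i = j


def _parse_newick_nested(text: str):
    """Parse newick into nested tuples/strings; branch lengths discarded."""
    stack = []  # list of child-lists for open clades
    current = []  # children collected at the top level
    just_closed = False  # a ')' was seen; next label is an internal name

    for pos, tok in _tokenize_newick(text):
        if tok == "(":
            stack.append(current)
            current = []
            just_closed = False
        elif tok == ",":
            just_closed = False
        elif tok == ")":
            if not stack:
                raise NewickError(f"unbalanced ')' at position {pos}")
            clade = tuple(current)
            if len(clade) == 0:
                raise NewickError(f"empty clade at position {pos}")
            current = stack.pop()
            current.append(clade if len(clade) > 1 else clade[0])
            just_closed = True
        elif tok == ";":
            break
        elif tok == ":":
            just_closed = "length"  # the next label token is a branch length
        elif isinstance(tok, tuple):
            if just_closed == "length" or just_closed is True:
                just_closed = False  # internal node label or branch length: ignore
            else:
                current.append(tok[1])
    if stack:
        raise NewickError("unbalanced '(': missing closing parenthesis")
    if len(current) != 1:
        raise NewickError("newick must describe exactly one tree")
    node = current[0]
    if isinstance(node, str):
        raise NewickError("a tree needs at least 2 leaves")
    return node


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny` (topology only)."""
    return Phylogeny.from_newick(text)


def _quote_label(name: str) -> str:
    if any(c in name for c in "(),;:[] '\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


# ------------------------------------------------------------------ inference
def infer_tree(genotype) -> Phylogeny:
    """UPGMA fallback tree from the binarized genotype matrix.

    Hamming distances between isolate presence/absence profiles, average
    linkage, ties broken by the lexicographically smallest member id so the
    result is invariant to input ordering.  Intended for runs without a
    user-supplied phylogeny; quality is whatever a pan-genome distance tree
    gives, which is adequate because only topology feeds the statistic.
    """
    present = np.asarray(genotype.present, dtype=bool)
    ids = list(genotype.isolate_ids)
    n = len(ids)
    if n < 4:
        raise ValueError("tree inference needs at least 4 isolates")

    # distance between clusters, keyed by frozen cluster key
    active = {}
    for i in range(n):
        active[i] = (1, ids[i], ids[i])  # (size, min member id, nested repr)
    nested = {i: ids[i] for i in range(n)}
    dist = {}
    X = present.astype(np.int32)
    D = np.zeros((n, n))
    for i in range(n):
        D[i] = np.abs(X - X[i]).sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])

    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), d in dist.items():
            if i not in active or j not in active:
                continue
            mi, mj = active[i][1], active[j][1]
            lo, hi = (mi, mj) if mi < mj else (mj, mi)
            key = (d, lo, hi)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        si, sj = active[i][0], active[j][0]
        mi, mj = active[i][1], active[j][1]
        a, b = (i, j) if mi <= mj else (j, i)
        nested[next_id] = (nested[a], nested[b])
        new_min = min(mi, mj)
        # average-linkage update
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(next_id, k), max(next_id, k))] = (si * dik + sj * djk) / (si + sj)
        dist.pop((min(i, j), max(i, j)))
        del active[i], active[j]
        active[next_id] = (si + sj, new_min, None)
        next_id += 1

    root = next(iter(active))
    return Phylogeny.from_nested(nested[root])
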