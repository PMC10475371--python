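"""Neighbor-joining trees and kinship-threshold family construction.

Trees: classical Saitou–Nei neighbor joining on the IBS distance
matrix, with deterministic tie-breaking (lexicographically smallest
leaf-label pair) and the standard limb-length formulas; the unrooted
tree is returned with a trifurcating root.

Families: boars are grouped into families as the connected components
of the graph whose edges join boars with kinship ≥ a threshold
(default 0.1, single linkage); sows are then attached to the family
whose boars they are closest to on average, provided they reach the
threshold with at least one boar, and otherwise left unassigned
(a separate family of genetically distant dams).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .relatedness import DistanceMatrix, KinshipMatrix


@dataclass
class TreeNode:
    """A node of an (un)rooted phylogeny; leaves carry sample labels."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf():
            return [self.label] if self.label is not None else []
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out


def neighbor_joining(distances: DistanceMatrix) -> TreeNode:
    """Build an unrooted NJ tree (trifurcating root) from a distance matrix.

    At each step the pair minimizing the Q-criterion
    Q_ij = (m−2)·d_ij − r_i − r_j is joined; exact ties are broken by
    the lexicographically smallest pair of subtree labels (a subtree is
    labelled by its smallest leaf). Negative limb lengths are retained.
    """
    D0 = np.asarray(distances.values, dtype=float)
    labels = list(distances.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least three taxa")
    if D0.shape != (n, n):
        raise ValueError("distance matrix shape does not match label count")
    if not np.allclose(D0, D0.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D0), 0.0, atol=1e-9):
        raise ValueError("distance matrix diagonal is not zero")

    # Growing working matrix: joined nodes get appended rows/columns.
    cap = 2 * n
    D = np.zeros((cap, cap))
    D[:n, :n] = D0
    nodes: dict[int, TreeNode] = {i: TreeNode(label=labels[i]) for i in range(n)}
    minlab: dict[int, str] = {i: labels[i] for i in range(n)}
    active = list(range(n))
    nxt = n

    while len(active) > 3:
        idx = np.asarray(active)
        sub = D[np.ix_(idx, idx)]
        m = len(active)
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - (r[:, None] + r[None, :])
        # search the upper triangle only (Q is symmetric up to rounding)
        Q[np.tril_indices(m)] = np.inf
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin)
        best = min(
            (tuple(sorted((minlab[idx[a]], minlab[idx[b]]))), a, b) for a, b in cand
        )
        _, a, b = best
        i, j = idx[a], idx[b]
        dij = sub[a, b]
        limb_i = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        limb_j = dij - limb_i
        new = TreeNode(children=[(nodes[i], limb_i), (nodes[j], limb_j)])
        nodes[nxt] = new
        minlab[nxt] = min(minlab[i], minlab[j])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[nxt, k] = D[k, nxt] = dk
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    i, j, k = active
    la = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lb = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lc = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    return TreeNode(children=[(nodes[i], la), (nodes[j], lb), (nodes[k], lc)])


_NEWICK_RESERVED = set("();:,[]' \t\n")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_RESERVED for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree: TreeNode, clamp_negative: bool = True) -> str:
    """Serialize a tree to Newick with branch lengths.

    Negative branch lengths (possible in NJ) are written as 0.0 when
    ``clamp_negative`` is set, mirroring common tree-viewer behaviour.
    """

    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            return _quote(node.label or "")
        parts = []
        for child, length in node.children:
            if clamp_negative and length < 0:
                length = 0.0
            parts.append(f"{fmt(child)}:{length:.10g}")
        inner = ",".join(parts)
        return f"({inner})" + (_quote(node.label) if node.label else "")

    return fmt(tree) + ";"


def write_newick(tree: TreeNode, path: str | Path, clamp_negative: bool = True) -> Path:
    path = Path(path)
    path.write_text(newick_string(tree, clamp_negative=clamp_negative) + "\n")
    return path


# ---------------------------------------------------------------------------
# family construction
# ---------------------------------------------------------------------------


@dataclass
class FamilyAssignment:
    """Boar families plus per-sow family assignment ('unassigned' allowed)."""

    families: dict[str, list[str]]
    sow_assignments: dict[str, str] = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return len(self.families)


def _family_labels(count: int) -> list[str]:
    labels = []
    for i in range(count):
        s = ""
        k = i
        while True:
            s = chr(ord("A") + k % 26) + s
            k = k // 26 - 1
            if k < 0:
                break
        labels.append(s)
    return labels


def build_boar_families(
    ks: KinshipMatrix, boar_ids: list[str], threshold: float = 0.1
) -> FamilyAssignment:
    """Group boars into families by single-linkage at ``threshold``.

    Families are the connected components of the graph on boars with an
    edge wherever KS ≥ threshold; labels A, B, C… are assigned in
    decreasing component size, ties by smallest member id.
    """
    if not boar_ids:
        raise ValueError("empty boar list")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    pos = {lab: i for i, lab in enumerate(ks.labels)}
    missing = [b for b in boar_ids if b not in pos]
    if missing:
        raise KeyError(f"boar ids not in kinship matrix: {missing}")

    parent = {b: b for b in boar_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a_i, a in enumerate(boar_ids):
        for b in boar_ids[a_i + 1 :]:
            v = ks.values[pos[a], pos[b]]
            if np.isfinite(v) and v >= threshold:
                parent[find(a)] = find(b)

    comps: dict[str, list[str]] = {}
    for b in boar_ids:
        comps.setdefault(find(b), []).append(b)
    groups = sorted(comps.values(), key=lambda g: (-len(g), min(g)))
    labels = _family_labels(len(groups))
    return FamilyAssignment(families={lab: sorted(g) for lab, g in zip(labels, groups)})


def assign_sows(
    ks: KinshipMatrix,
    families: FamilyAssignment,
    sow_ids: list[str],
    threshold: float = 0.1,
) -> FamilyAssignment:
    """Attach each sow to a boar family, or leave her unassigned.

    A sow qualifies if her kinship with at least one boar reaches
    ``threshold``; she then joins the family whose boars have the
    highest mean kinship with her (ties broken by family label order).
    Sows below threshold with every boar form the separate, unassigned
    group.
    """
    pos = {lab: i for i, lab in enumerate(ks.labels)}
    assignments: dict[str, str] = {}
    fam_labels = sorted(families.families)
    for sow in sow_ids:
        if sow not in pos:
            raise KeyError(f"sow id {sow!r} not in kinship matrix")
        si = pos[sow]
        best_single = -np.inf
        means = {}
        for lab in fam_labels:
            vals = np.array([ks.values[si, pos[b]] for b in families.families[lab]])
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            means[lab] = float(vals.mean())
            best_single = max(best_single, float(vals.max()))
        if best_single >= threshold and means:
            best = max(means.values())
            assignments[sow] = min(lab for lab, m in means.items() if m == best)
        else:
            assignments[sow] = "unassigned"
    return FamilyAssignment(families=dict(families.families), sow_assignments=assignments)


def family_table(ks: KinshipMatrix, assignment: FamilyAssignment) -> pd.DataFrame:
    """Tidy per-animal table: sample_id, role, family, mean_ks_to_family."""
    pos = {lab: i for i, lab in enumerate(ks.labels)}
    rows = []
    for fam, boars in sorted(assignment.families.items()):
        for b in boars:
            others = [x for x in boars if x != b]
            mean = (
                float(np.nanmean([ks.values[pos[b], pos[o]] for o in others]))
                if others
                else np.nan
            )
            rows.append((b, "boar", fam, mean))
    for sow, fam in sorted(assignment.sow_assignments.items()):
        if fam == "unassigned":
            rows.append((sow, "sow", "unassigned", np.nan))
        else:
            boars = assignment.families[fam]
            mean = float(np.nanmean([ks.values[pos[sow], pos[b]] for b in boars]))
            rows.append((sow, "sow", fam, mean))
    return pd.DataFrame(rows, columns=["sample_id", "role", "family", "mean_ks_to_family"])
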