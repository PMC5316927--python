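"""Branch-length solving and dating on species/duplication trees.

A rooted tree describes the history of a set of genomes: internal nodes are
speciations or whole-genome duplications/triplications (WGD/WGT), and
duplication nodes are unary -- they sit on a lineage branch without
bifurcating the species tree.  Branch lengths are unknown synonymous
distances (Ks units).  Each observed modal Ks value constrains a path sum:

* ortholog(X, Y): the sum of branch lengths along both tip-to-MRCA paths;
* paralog(tip, E): twice the tip-to-event path (both post-duplication
  paralog lineages are approximated by the same genome's branches).

Stacking observations gives a linear system A b = d solved by least squares;
node ages follow by proportional scaling against a root calibration age.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import nnls

NODE_TYPES = ("speciation", "wgd", "wgt", "tip")
DUPLICATION_TYPES = ("wgd", "wgt")


class TopologyError(ValueError):
    """An observation references a node not ancestral to its tip."""


class UnderDeterminedError(ValueError):
    """The observation set does not determine every branch length."""


@dataclass
class EventNode:
    name: str
    node_type: str  # speciation | wgd | wgt | tip
    children: list["EventNode"] = field(default_factory=list)
    parent: "EventNode | None" = None
    length: float | None = None  # Ks of the branch above this node

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"EventNode({self.name}, {self.node_type})"


class EventTree:
    """Rooted species/duplication tree with named nodes.

    Duplication nodes must be unary; every node name must be unique.  One
    unknown branch length is attached to every non-root node (the edge above
    it); the root carries no branch.
    """

    def __init__(self, root: EventNode):
        self.root = root
        self._index: dict[str, EventNode] = {}
        for node in self.preorder():
            if node.name in self._index:
                raise ValueError(f"duplicate node name {node.name!r}")
            self._index[node.name] = node
        for node in self.preorder():
            if node.node_type in DUPLICATION_TYPES and len(node.children) > 1:
                if node is not self.root:
                    raise ValueError(
                        f"duplication node {node.name!r} must be unary"
                    )
            if not node.children and node.node_type != "tip":
                raise ValueError(f"leaf {node.name!r} must have type 'tip'")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "EventTree":
        """Parse a newick string whose node labels may carry a type suffix.

        Labels follow ``name:type=speciation|wgd|wgt`` (quoted or not; a
        pre-quoting pass protects the colon from being read as a branch
        length).  Unlabelled internal nodes default to speciation; leaves
        are tips.
        """
        protected = re.sub(
            r"([A-Za-z0-9_.\-]+:type=(?:speciation|wgd|wgt))", r"'\1'", newick
        )
        tree = dendropy.Tree.get(
            data=protected,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
        counter = [0]

        def convert(dnode) -> EventNode:
            label = dnode.label or ""
            if ":type=" in label:
                name, _, ntype = label.partition(":type=")
            else:
                name, ntype = label, ""
            if not dnode.child_nodes():
                ntype = "tip"
            elif not ntype:
                ntype = "speciation"
            if not name:
                counter[0] += 1
                name = f"node{counter[0]}"
            node = EventNode(name, ntype)
            for child in dnode.child_nodes():
                cnode = convert(child)
                cnode.parent = node
                node.children.append(cnode)
            return node

        return cls(convert(tree.seed_node))

    # -- traversal ---------------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def __getitem__(self, name: str) -> EventNode:
        return self._index[name]

    @property
    def tips(self) -> list[EventNode]:
        return [n for n in self.preorder() if not n.children]

    @property
    def branch_nodes(self) -> list[EventNode]:
        """Non-root nodes in preorder; the unknown vector is ordered this way."""
        return [n for n in self.preorder() if n is not self.root]

    def ancestors(self, node: EventNode) -> list[EventNode]:
        out = []
        cur = node.parent
        while cur is not None:
            out.append(cur)
            cur = cur.parent
        return out

    def path_up(self, tip_name: str, ancestor_name: str) -> list[EventNode]:
        """Nodes whose branches lie on the path tip -> ancestor (tip included)."""
        tip = self[tip_name]
        anc = self[ancestor_name]
        path = []
        cur = tip
        while cur is not anc:
            path.append(cur)
            cur = cur.parent
            if cur is None:
                raise TopologyError(
                    f"{ancestor_name!r} is not ancestral to tip {tip_name!r}"
                )
        return path

    def mrca(self, name_x: str, name_y: str) -> EventNode:
        anc_x = {id(n) for n in [self[name_x]] + self.ancestors(self[name_x])}
        cur = self[name_y]
        while cur is not None:
            if id(cur) in anc_x:
                return cur
            cur = cur.parent
        raise TopologyError(f"no common ancestor of {name_x!r} and {name_y!r}")

    def set_lengths(self, lengths: dict[str, float]) -> None:
        for node in self.branch_nodes:
            node.length = float(lengths[node.name])

    def lengths(self) -> dict[str, float]:
        return {n.name: n.length for n in self.branch_nodes}

    def ks_to_ancestor(self, tip_name: str, ancestor_name: str) -> float:
        return sum(n.length for n in self.path_up(tip_name, ancestor_name))

    def descendant_tips(self, node: EventNode) -> list[EventNode]:
        if not node.children:
            return [node]
        out = []
        stack = [node]
        while stack:
            cur = stack.pop()
            if not cur.children:
                out.append(cur)
            stack.extend(cur.children)
        return out


@dataclass
class ModalObservation:
    """One observed modal Ks value.

    kind "ortholog": node_a and node_b are two tips (MRCA path sum); the
    MRCA may be forced to the root for WGD-derived "old ortholog" peaks.
    kind "paralog": node_a is a tip, node_b an ancestral duplication node.
    """

    kind: str  # ortholog | paralog
    node_a: str
    node_b: str
    modal_ks: float
    through_root: bool = False

    def __post_init__(self):
        if self.kind not in ("ortholog", "paralog"):
            raise ValueError(f"unknown observation kind {self.kind!r}")
        if self.modal_ks < 0:
            raise ValueError("observed modal Ks must be >= 0")


def build_system(
    tree: EventTree, observations: list[ModalObservation]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix A (rows = observations, cols = branches) and vector d."""
    if not observations:
        raise ValueError("no observations")
    branch_names = [n.name for n in tree.branch_nodes]
    col = {name: j for j, name in enumerate(branch_names)}
    A = np.zeros((len(observations), len(branch_names)))
    d = np.zeros(len(observations))
    for i, obs in enumerate(observations):
        if obs.kind == "ortholog":
            anc = tree.root if obs.through_root else tree.mrca(obs.node_a, obs.node_b)
            for node in tree.path_up(obs.node_a, anc.name):
                A[i, col[node.name]] += 1
            for node in tree.path_up(obs.node_b, anc.name):
                A[i, col[node.name]] += 1
        else:
            event = tree[obs.node_b]
            if event.node_type not in DUPLICATION_TYPES and event is not tree.root:
                raise TopologyError(
                    f"paralog observation targets non-duplication node {obs.node_b!r}"
                )
            for node in tree.path_up(obs.node_a, obs.node_b):
                A[i, col[node.name]] += 2
        d[i] = obs.modal_ks
    return A, d, branch_names


@dataclass
class SolveResult:
    lengths: dict[str, float]
    residual: float
    refit: bool  # True when negatives were clipped and a nonnegative refit ran


def solve_branch_lengths(A: np.ndarray, d: np.ndarray, branch_names=None) -> SolveResult:
    """Least-squares solve of A b = d; exact when the system is consistent.

    Requires full column rank.  Negative solved lengths are clipped to zero
    via a nonnegative least-squares refit, flagged in the result.
    """
    A = np.asarray(A, dtype=float)
    d = np.asarray(d, dtype=float)
    if A.shape[0] != d.shape[0]:
        raise ValueError("incompatible dimensions")
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        unresolved = _unresolved_branches(A, branch_names)
        raise UnderDeterminedError(
            f"system rank {rank} < {A.shape[1]} unknowns; "
            f"unresolved branches: {unresolved}"
        )
    b, _, _, _ = np.linalg.lstsq(A, d, rcond=None)
    refit = False
    if np.any(b < -1e-12):
        warnings.warn("negative branch lengths clipped; nonnegative refit", stacklevel=2)
        b, _ = nnls(A, d)
        refit = True
    b = np.clip(b, 0.0, None)
    residual = float(np.linalg.norm(A @ b - d))
    names = branch_names or [f"b{j}" for j in range(A.shape[1])]
    return SolveResult(dict(zip(names, b)), residual, refit)


def _unresolved_branches(A: np.ndarray, branch_names) -> list[str]:
    """Branches whose column lies in the null-space support of A."""
    _, s, vt = np.linalg.svd(A)
    null = vt[np.sum(s > 1e-10) :]
    names = branch_names or [f"b{j}" for j in range(A.shape[1])]
    mask = np.any(np.abs(null) > 1e-8, axis=0) if len(null) else np.zeros(len(names), bool)
    return [n for n, m in zip(names, mask) if m]


@dataclass
class ChronologyResult:
    """Solved chronology: branch Ks, node ages (Mya) and per-branch rates."""

    branch_ks: dict[str, float]
    node_ages: dict[str, float]
    branch_rates: dict[str, float]  # Ks per My on the branch above each node
    residual: float
    calibration_age: float

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        branches = pd.DataFrame(
            {
                "branch": list(self.branch_ks),
                "ks": list(self.branch_ks.values()),
                "rate_ks_per_my": [self.branch_rates[b] for b in self.branch_ks],
            }
        )
        nodes = pd.DataFrame(
            {"node": list(self.node_ages), "age_mya": list(self.node_ages.values())}
        )
        return branches, nodes


def assign_dates(
    tree: EventTree, calibration_age: float, residual: float = 0.0
) -> ChronologyResult:
    """Convert solved branch Ks to ages against a root calibration.

    age(n) = calibration * mean over descendant tips t of Ks(t->n)/Ks(t->root)
    (tips at age 0); each branch's rate is its Ks divided by its duration.
    """
    root = tree.root
    for tip in tree.tips:
        if tree.ks_to_ancestor(tip.name, root.name) <= 0:
            raise ValueError(
                f"zero-length root-to-tip path for {tip.name!r}: rates degenerate"
            )
    ages: dict[str, float] = {}
    for node in tree.preorder():
        if not node.children:
            ages[node.name] = 0.0
        elif node is root:
            ages[node.name] = float(calibration_age)
        else:
            ratios = [
                tree.ks_to_ancestor(t.name, node.name)
                / tree.ks_to_ancestor(t.name, root.name)
                for t in tree.descendant_tips(node)
            ]
            ages[node.name] = calibration_age * float(np.mean(ratios))
    rates = {}
    for node in tree.branch_nodes:
        duration = ages[node.parent.name] - ages[node.name]
        rates[node.name] = node.length / duration if duration > 0 else float("nan")
    return ChronologyResult(
        tree.lengths(), ages, rates, residual, float(calibration_age)
    )


def solve_chronology(
    tree: EventTree,
    observations: list[ModalObservation],
    calibration_age: float,
) -> ChronologyResult:
    """build_system -> solve_branch_lengths -> assign_dates in one call."""
    A, d, names = build_system(tree, observations)
    res = solve_branch_lengths(A, d, names)
    tree.set_lengths(res.lengths)
    return assign_dates(tree, calibration_age, res.residual)


# ---------------------------------------------------------------------------
# Observation table I/O and a demo topology
# ---------------------------------------------------------------------------


def read_observations(path) -> list[ModalObservation]:
    df = pd.read_csv(path, sep="\t")
    needed = {"kind", "node_a", "node_b", "modal_ks"}
    if not needed.issubset(df.columns):
        raise ValueError(f"observation table needs columns {sorted(needed)}")
    return [
        ModalObservation(
            str(r.kind),
            str(r.node_a),
            str(r.node_b),
            float(r.modal_ks),
            bool(getattr(r, "through_root", False)),
        )
        for r in df.itertuples()
    ]


def observations_to_frame(obs: list[ModalObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kind": [o.kind for o in obs],
            "node_a": [o.node_a for o in obs],
            "node_b": [o.node_b for o in obs],
            "modal_ks": [o.modal_ks for o in obs],
            "through_root": [o.through_root for o in obs],
        }
    )


LEGUME_NEWICK = (
    "(((((Glycine)glycine_wgd:type=wgd,Phaseolus)millettioid,"
    "(Medicago,Lotus)galegoid)hologalegina,"
    "(Lupinus)genistoid_wgt:type=wgt)radiation)"
    "papilionoid_wgd:type=wgd;"
)
# Branch Ks chosen so tip-to-event half-distances echo the observed paralog
# peaks (~0.37 Lupinus, ~0.34 Glycine to the root; WGT/WGD peaks 0.30, 0.12).
LEGUME_BRANCH_KS = {
    "radiation": 0.01,
    "hologalegina": 0.10,
    "millettioid": 0.08,
    "glycine_wgd": 0.09,
    "Glycine": 0.06,
    "Phaseolus": 0.25,
    "galegoid": 0.07,
    "Medicago": 0.28,
    "Lotus": 0.20,
    "genistoid_wgt": 0.21,
    "Lupinus": 0.15,
}


def legume_demo_tree() -> EventTree:
    """Five-taxon legume topology with three duplication nodes (11 branches).

    Rooted at the papilionoid WGD (a unary node above the papilionoid
    radiation); the genistoid WGT sits on the Lupinus lineage and an
    independent WGD on the Glycine lineage.  Lengths are illustrative
    defaults in Ks units.
    """
    tree = EventTree.from_newick(LEGUME_NEWICK)
    tree.set_lengths(dict(LEGUME_BRANCH_KS))
    return tree
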