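"""Signed dependency network and feedback-loop taxonomy.

An edge ``D -> M`` means "protein D regulates the polar recruitment of
marker M", read off the dependency matrix: if M's polar signal
*decreases* in the D-deletion the edge is positive (D is required for
M's recruitment); if it *increases* the edge is negative (D limits M's
accumulation). Edges can additionally carry a NETO flag when the
deletion shifts M's monopolar/bipolar distribution.

Two-protein loops fall into three classes —

* ``unidirectional_2``: one + and one - edge (A recruits B, B trims A);
* ``positive_2``: mutual + (amplification);
* ``negative_2``: mutual - (mutual reduction);

and simple cycles of length >= 3 are enumerated with their overall sign
(the product of edge signs; negative iff the number of - edges is odd).
The cycles reported in the source study are all-positive, so an
``all_positive`` flag is carried alongside the product sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .design import deletion_protein

POS, NEG = 1, -1
_SIGN_STR = {POS: "+", NEG: "-"}
_STR_SIGN = {"+": POS, "-": NEG}

UNIDIRECTIONAL_2 = "unidirectional_2"
POSITIVE_2 = "positive_2"
NEGATIVE_2 = "negative_2"
CYCLE_N = "cycle_n"


@dataclass(frozen=True)
class SignedEdge:
    """Directed signed regulation: deleting ``source`` changes the polar
    signal of ``target`` (sign +1 = decrease = requirement)."""

    source: str
    target: str
    sign: int
    basis: str = ""        # compartment(s) driving the call
    neto: bool = False
    groups: str = ""       # reference-set membership labels
    provenance: str = ""

    def __post_init__(self):
        if self.sign not in (POS, NEG):
            raise ValueError("sign must be +1 or -1")
        if self.source == self.target:
            raise ValueError("self-edges are not allowed")

    @property
    def sign_str(self) -> str:
        return _SIGN_STR[self.sign]


@dataclass(frozen=True)
class FeedbackLoop:
    """A classified cycle; ``nodes`` is the canonical rotation starting at
    the lexicographically smallest protein."""

    nodes: tuple[str, ...]
    signs: tuple[int, ...]     # sign of edge nodes[i] -> nodes[i+1]
    loop_class: str

    @property
    def length(self) -> int:
        return len(self.nodes)

    @property
    def overall_sign(self) -> int:
        s = 1
        for x in self.signs:
            s *= x
        return s

    @property
    def all_positive(self) -> bool:
        return all(s == POS for s in self.signs)

    def __str__(self):
        return "-".join(self.nodes) + f" ({self.loop_class}, "\
            f"{_SIGN_STR[self.overall_sign]})"


def _canonical_rotation(nodes: tuple[str, ...], signs: tuple[int, ...]):
    k = nodes.index(min(nodes))
    return (nodes[k:] + nodes[:k], signs[k:] + signs[:k])


# ---------------------------------------------------------------------------
# matrix -> edges

def matrix_to_edges(matrix: pd.DataFrame,
                    neto: pd.DataFrame | None = None,
                    edge_rule: str = "either") -> list[SignedEdge]:
    """Signed edges from the called matrix.

    ``edge_rule`` selects which polar compartments drive an edge:
    ``"either"`` (default; conflicting end calls resolved by the larger
    |rel_diff|), ``"end1"`` or ``"end2"``. Cytosol calls never create
    edges. The NETO flag comes from ``neto.shifted``.
    """
    if edge_rule not in ("either", "end1", "end2"):
        raise ValueError(f"unknown edge_rule {edge_rule!r}")
    compartments = ("end1", "end2") if edge_rule == "either" else (edge_rule,)
    shifted = set()
    if neto is not None:
        for _, row in neto[neto["shifted"]].iterrows():
            shifted.add((row["marker"], row["deletion"]))
    edges = []
    for (marker, deletion), grp in matrix.groupby(["marker", "deletion"],
                                                  sort=True):
        polar = grp[grp["compartment"].isin(compartments)]
        called = polar[polar["call"] != "ns"]
        is_neto = (marker, deletion) in shifted
        if called.empty:
            if is_neto:  # NETO-only dependence still draws an edge
                edges.append(SignedEdge(deletion_protein(deletion), marker,
                                        POS, basis="neto", neto=True))
            continue
        best = called.loc[called["rel_diff"].abs().idxmax()]
        sign = POS if best["call"] == "decrease" else NEG
        edges.append(SignedEdge(deletion_protein(deletion), marker, sign,
                                basis=str(best["compartment"]),
                                neto=is_neto))
    return edges


# ---------------------------------------------------------------------------
# loop taxonomy

_TWO_NODE_CLASS = {
    (POS, POS): POSITIVE_2,
    (NEG, NEG): NEGATIVE_2,
    (POS, NEG): UNIDIRECTIONAL_2,
    (NEG, POS): UNIDIRECTIONAL_2,
}


def classify_two_node_loops(edges: list[SignedEdge]) -> list[FeedbackLoop]:
    """One loop per unordered pair with edges in both directions."""
    lookup = {}
    for e in edges:
        key = (e.source, e.target)
        if key in lookup and lookup[key].sign != e.sign:
            raise ValueError(f"conflicting duplicate edge {key}")
        lookup[key] = e
    loops = []
    seen = set()
    for e in edges:
        pair = frozenset((e.source, e.target))
        if pair in seen:
            continue
        back = lookup.get((e.target, e.source))
        if back is None:
            continue
        seen.add(pair)
        a, b = sorted((e.source, e.target))
        s_ab = lookup[(a, b)].sign
        s_ba = lookup[(b, a)].sign
        loops.append(FeedbackLoop(
            nodes=(a, b), signs=(s_ab, s_ba),
            loop_class=_TWO_NODE_CLASS[(s_ab, s_ba)]))
    return sorted(loops, key=lambda l: l.nodes)


def enumerate_cycles(edges: list[SignedEdge], min_len: int = 3,
                     max_len: int | None = None) -> list[FeedbackLoop]:
    """All simple directed cycles with ``min_len <= length <= max_len``,
    each in canonical rotation, classified ``cycle_n``."""
    g = nx.DiGraph()
    sign = {}
    for e in edges:
        if (e.source, e.target) in sign and sign[(e.source,
                                                  e.target)] != e.sign:
            raise ValueError(
                f"conflicting duplicate edge {(e.source, e.target)}")
        sign[(e.source, e.target)] = e.sign
        g.add_edge(e.source, e.target)
    if max_len is None:
        max_len = g.number_of_nodes()
    loops = []
    for cyc in nx.simple_cycles(g, length_bound=max_len):
        if len(cyc) < min_len:
            continue
        nodes = tuple(cyc)
        signs = tuple(sign[(nodes[i], nodes[(i + 1) % len(nodes)])]
                      for i in range(len(nodes)))
        nodes, signs = _canonical_rotation(nodes, signs)
        loops.append(FeedbackLoop(nodes=nodes, signs=signs,
                                  loop_class=CYCLE_N))
    return sorted(loops, key=lambda l: (l.length, l.nodes))


def find_loops(edges: list[SignedEdge],
               max_len: int | None = None) -> list[FeedbackLoop]:
    """Two-node loop classes plus all larger cycles."""
    return classify_two_node_loops(edges) + enumerate_cycles(
        edges, max_len=max_len)


# ---------------------------------------------------------------------------
# serialisation

_TSV_COLUMNS = ["source", "target", "sign", "basis", "neto", "groups",
                "provenance", "loops"]


def _loop_membership(edges: list[SignedEdge],
                     loops: list[FeedbackLoop]) -> dict:
    member: dict[tuple[str, str], list[str]] = {}
    for li, loop in enumerate(loops):
        label = "-".join(loop.nodes)
        for i in range(loop.length):
            key = (loop.nodes[i], loop.nodes[(i + 1) % loop.length])
            member.setdefault(key, []).append(label)
    return member


def edges_to_frame(edges: list[SignedEdge],
                   loops: list[FeedbackLoop] | None = None) -> pd.DataFrame:
    member = _loop_membership(edges, loops or [])
    rows = []
    for e in sorted(edges, key=lambda e: (e.source, e.target)):
        rows.append({
            "source": e.source, "target": e.target, "sign": e.sign_str,
            "basis": e.basis, "neto": int(e.neto), "groups": e.groups,
            "provenance": e.provenance,
            "loops": ";".join(member.get((e.source, e.target), [])),
        })
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_network_tsv(edges, loops, path) -> None:
    edges_to_frame(edges, loops).to_csv(path, sep="\t", index=False,
                                        lineterminator="\n")


def read_network_tsv(path) -> list[SignedEdge]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"provenance": str, "groups": str, "basis": str})
    edges = []
    for _, row in df.iterrows():
        edges.append(SignedEdge(
            source=row["source"], target=row["target"],
            sign=_STR_SIGN[row["sign"]], basis=row["basis"],
            neto=bool(int(row["neto"])), groups=row["groups"],
            provenance=row["provenance"]))
    return edges


def write_dot(edges, loops, path) -> None:
    """Graphviz DOT with the study's colour scheme: positive = green,
    negative = red, NETO-flagged = blue."""
    lines = ["digraph dependency {", "  rankdir=LR;"]
    for e in sorted(edges, key=lambda e: (e.source, e.target)):
        color = "blue" if e.neto else ("green" if e.sign == POS else "red")
        lines.append(f'  "{e.source}" -> "{e.target}" '
                     f'[color={color}, sign="{e.sign_str}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(edges, loops, path) -> None:
    g = nx.DiGraph()
    member = _loop_membership(edges, loops or [])
    for e in edges:
        g.add_edge(e.source, e.target, sign=e.sign, neto=int(e.neto),
                   basis=e.basis,
                   loops=";".join(member.get((e.source, e.target), [])))
    nx.write_graphml(g, path)


def export_network(edges: list[SignedEdge],
                   loops: list[FeedbackLoop] | None,
                   path: str | Path, fmt: str = "tsv") -> None:
    """Write the network as edge-list TSV, GraphML or DOT."""
    writers = {"tsv": write_network_tsv, "graphml": write_graphml,
               "dot": write_dot}
    if fmt not in writers:
        raise ValueError(f"unsupported format {fmt!r}")
    writers[fmt](edges, loops or [], path)


# ---------------------------------------------------------------------------
# reference edge set (transcribed findings; see fixtures/ for the TSV copy)

def _ref(src, dst, sign, groups, prov):
    return SignedEdge(src, dst, sign, groups=groups, provenance=prov)


#: Signed edges stated by the source study's results narrative. Groups:
#: pair_* = two-protein loop examples; loop_positive = the nine edges of
#: the three listed positive cycles; loop_negative = the five-protein
#: negative cycle; matrix_example = worked single-edge examples.
REFERENCE_EDGES: tuple[SignedEdge, ...] = (
    # unidirectional pairs: first protein recruits the second, which in
    # turn trims the first
    _ref("Bud6", "For3", POS, "pair_unidirectional,loop_positive",
         "unidirectional pair (Bud6, For3)"),
    _ref("For3", "Bud6", NEG, "pair_unidirectional,loop_negative",
         "unidirectional pair (Bud6, For3)"),
    _ref("Tip1", "Tea1", POS, "pair_unidirectional,loop_positive",
         "unidirectional pair (Tip1, Tea1)"),
    _ref("Tea1", "Tip1", NEG, "pair_unidirectional",
         "unidirectional pair (Tip1, Tea1)"),
    _ref("For3", "Myo52", POS, "pair_unidirectional,loop_positive",
         "unidirectional pair (For3, Myo52)"),
    _ref("Myo52", "For3", NEG, "pair_unidirectional,loop_negative",
         "unidirectional pair (For3, Myo52)"),
    _ref("Tea3", "Tea1", POS, "pair_unidirectional",
         "unidirectional pair (Tea3, Tea1)"),
    _ref("Tea1", "Tea3", NEG, "pair_unidirectional",
         "unidirectional pair (Tea3, Tea1)"),
    _ref("Mod5", "Tea3", POS, "pair_unidirectional",
         "unidirectional pair (Mod5, Tea3)"),
    _ref("Tea3", "Mod5", NEG, "pair_unidirectional",
         "unidirectional pair (Mod5, Tea3)"),
    # positive amplification pairs
    _ref("Tea1", "Tea4", POS, "pair_positive",
         "positive pair (Tea1, Tea4)"),
    _ref("Tea4", "Tea1", POS, "pair_positive",
         "positive pair (Tea1, Tea4)"),
    _ref("Tea1", "Tea2", POS, "pair_positive,loop_positive",
         "positive pair (Tea1, Tea2)"),
    _ref("Tea2", "Tea1", POS, "pair_positive,matrix_example",
         "positive pair (Tea1, Tea2); Tea1 needs the Tea2 kinesin"),
    _ref("Tea1", "Mod5", POS, "pair_positive",
         "positive pair (Tea1, Mod5)"),
    _ref("Mod5", "Tea1", POS, "pair_positive,loop_positive",
         "positive pair (Tea1, Mod5)"),
    _ref("Bud6", "Myo52", POS, "pair_positive",
         "positive pair (Bud6, Myo52)"),
    _ref("Myo52", "Bud6", POS, "pair_positive",
         "positive pair (Bud6, Myo52)"),
    # negative reduction pair
    _ref("Myo52", "Tea2", NEG, "pair_negative",
         "negative pair (Myo52, Tea2)"),
    _ref("Tea2", "Myo52", NEG, "pair_negative,loop_negative",
         "negative pair (Myo52, Tea2)"),
    # remaining edges of the three positive >=3-cycles
    _ref("Tea1", "Bud6", POS, "loop_positive",
         "positive cycle Tea1-Bud6-For3-Myo52 / -Tip1"),
    _ref("Myo52", "Tea1", POS, "loop_positive",
         "positive cycle Tea1-Bud6-For3-Myo52"),
    _ref("For3", "Tip1", POS, "loop_positive",
         "positive cycle Tea1-Bud6-For3-Tip1"),
    _ref("Tea2", "Mod5", POS, "loop_positive",
         "positive cycle Tea1-Tea2-Mod5"),
    # remaining edges of the five-protein negative cycle; only the pair
    # product of these two signs is constrained by the stated overall
    # negative sign, encoded here as +/+
    _ref("Bud6", "Tea3", POS, "loop_negative",
         "negative cycle Myo52-For3-Bud6-Tea3-Tea2 (sign inferred)"),
    _ref("Tea3", "Tea2", POS, "loop_negative",
         "negative cycle Myo52-For3-Bud6-Tea3-Tea2 (sign inferred)"),
    # worked matrix example: more Tip1 at poles without Myo52
    _ref("Myo52", "Tip1", NEG, "matrix_example",
         "polar Tip1 increases in the Myo52 deletion"),
)


def reference_edges(group: str | None = None) -> list[SignedEdge]:
    """The transcribed reference edges, optionally filtered by group
    label (e.g. ``"loop_positive"``)."""
    if group is None:
        return list(REFERENCE_EDGES)
    return [e for e in REFERENCE_EDGES if group in e.groups.split(",")]
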