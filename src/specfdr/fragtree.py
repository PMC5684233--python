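"""Fragmentation trees: molecular-formula arithmetic, DOT I/O, noise filtering.

A fragmentation tree explains an MS/MS spectrum: nodes are molecular
formulas of (hypothetical) fragment ions, edges carry the neutral loss
between a fragment and its parent.  Trees drive two things downstream:

* noise filtering — only spectrum peaks annotated by some tree node are
  kept, with their original intensities; and
* the tree-based decoy construction — the tree is re-rooted and fragment
  formulas recomputed along the (kept) losses.

Trees are consumed as input (computed elsewhere); a deliberately simple
greedy annotator is included so synthetic fixtures can be built without an
external tree-computation tool.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
from pyteomics import mass as _pmass

from .spectra import (
    DEFAULT_ABS_DA,
    DEFAULT_PPM,
    PROTON_MASS,
    Spectrum,
    mass_tolerance_da,
)

#: Elements allowed in formulas: CHNOPS plus the halogens.
ELEMENTS = ("C", "H", "N", "O", "P", "S", "F", "Cl", "Br", "I")

_MONO = {e: _pmass.nist_mass[e][0][0] for e in ELEMENTS}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class TreeError(ValueError):
    """Raised for structurally or chemically inconsistent fragmentation trees."""


# ---------------------------------------------------------------------------
# Molecular formulas
# ---------------------------------------------------------------------------

class MolecularFormula:
    """An element→count map with arithmetic.

    Subtraction of a loss may produce negative counts; such a formula is
    *invalid* (chemically impossible) but is kept as a value — invalidity
    drives the re-grafting step of the tree-based decoy, so it must be
    representable, not an exception.
    """

    __slots__ = ("_counts",)

    def __init__(self, formula: "str | Mapping[str, int] | MolecularFormula" = ""):
        counts: dict[str, int] = {}
        if isinstance(formula, MolecularFormula):
            counts = dict(formula._counts)
        elif isinstance(formula, str):
            pos = 0
            for m in _FORMULA_TOKEN.finditer(formula):
                if m.start() != pos:
                    raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
                pos = m.end()
                elem, num = m.group(1), m.group(2)
                counts[elem] = counts.get(elem, 0) + (int(num) if num not in ("", "-") else 1)
            if pos != len(formula):
                raise ValueError(f"cannot parse formula {formula!r}")
        else:
            for elem, n in formula.items():
                counts[elem] = counts.get(elem, 0) + int(n)
        for elem in counts:
            if elem not in _MONO:
                raise ValueError(f"unsupported element {elem!r} (allowed: {ELEMENTS})")
        self._counts = {e: c for e, c in counts.items() if c != 0}

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._counts)

    def valid(self) -> bool:
        """True iff every element count is non-negative."""
        return all(c >= 0 for c in self._counts.values())

    def __getitem__(self, elem: str) -> int:
        return self._counts.get(elem, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = dict(self._counts)
        for e, c in other._counts.items():
            out[e] = out.get(e, 0) + c
        return MolecularFormula(out)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = dict(self._counts)
        for e, c in other._counts.items():
            out[e] = out.get(e, 0) - c
        return MolecularFormula(out)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MolecularFormula) and self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __bool__(self) -> bool:
        return bool(self._counts)

    @property
    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass in Da (linear in counts; defined for invalid formulas too)."""
        return sum(c * _MONO[e] for e, c in self._counts.items())

    @property
    def ion_mass(self) -> float:
        """[M+H]+ ion mass: monoisotopic + proton (library is positive-mode)."""
        return self.monoisotopic_mass + PROTON_MASS

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        elems = sorted(self._counts, key=lambda e: (e != "C", e != "H", e))
        parts = []
        for e in elems:
            c = self._counts[e]
            parts.append(e if c == 1 else f"{e}{c}")
        return "".join(parts) or "empty"

    def __repr__(self) -> str:
        return f"MolecularFormula({str(self)!r})"


def formula_subtract(a: MolecularFormula, b: MolecularFormula) -> MolecularFormula:
    """Element-wise difference ``a − b``; may be invalid (check ``.valid()``)."""
    return a - b


# ---------------------------------------------------------------------------
# Tree data model
# ---------------------------------------------------------------------------

@dataclass
class FragTreeNode:
    """A fragment ion: its formula, theoretical [M+H]+ mass, and the matched peak intensity."""

    formula: MolecularFormula
    mass: float = 0.0
    peak_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.mass == 0.0:
            self.mass = self.formula.ion_mass


@dataclass
class FragmentationTree:
    """A rooted tree of fragment formulas joined by neutral-loss edges.

    Internally a :class:`networkx.DiGraph` over integer node ids; node
    attribute ``node`` holds the :class:`FragTreeNode`, edge attribute
    ``loss`` the :class:`MolecularFormula` of the neutral loss.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    root: int = 0
    spectrum_id: str = ""

    def node(self, i: int) -> FragTreeNode:
        return self.graph.nodes[i]["node"]

    def loss(self, parent: int, child: int) -> MolecularFormula:
        return self.graph.edges[parent, child]["loss"]

    def node_ids(self) -> list[int]:
        return list(self.graph.nodes)

    def node_masses(self) -> list[float]:
        return [self.node(i).mass for i in self.graph.nodes]

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_root(cls, root_formula: MolecularFormula, spectrum_id: str = "",
                  peak_intensity: float | None = None) -> "FragmentationTree":
        t = cls(spectrum_id=spectrum_id)
        t.graph.add_node(0, node=FragTreeNode(root_formula, peak_intensity=peak_intensity))
        t.root = 0
        return t

    def add_child(self, parent: int, loss: MolecularFormula,
                  peak_intensity: float | None = None) -> int:
        child_formula = self.node(parent).formula - loss
        if not child_formula.valid():
            raise TreeError(
                f"loss {loss} from node {parent} ({self.node(parent).formula}) "
                f"gives invalid formula {child_formula}"
            )
        i = max(self.graph.nodes) + 1
        self.graph.add_node(i, node=FragTreeNode(child_formula, peak_intensity=peak_intensity))
        self.graph.add_edge(parent, i, loss=loss)
        return i

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check the tree invariants; raise :class:`TreeError` on violation."""
        g = self.graph
        if g.number_of_nodes() == 0:
            raise TreeError("empty tree")
        roots = [n for n in g.nodes if g.in_degree(n) == 0]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        if roots[0] != self.root:
            raise TreeError(f"declared root {self.root} has incoming edges")
        if not nx.is_weakly_connected(g):
            raise TreeError("tree is not connected")
        if g.number_of_edges() != g.number_of_nodes() - 1:
            raise TreeError("node/edge count inconsistent with a tree (cycle or multi-parent)")
        for parent, child, data in g.edges(data=True):
            loss = data["loss"]
            expect = self.node(parent).formula - loss
            if expect != self.node(child).formula:
                raise TreeError(
                    f"edge {self.node(parent).formula} -[{loss}]-> "
                    f"{self.node(child).formula}: child + loss != parent"
                )
            if not self.node(child).formula.valid():
                raise TreeError(f"invalid formula at node {child}")


# ---------------------------------------------------------------------------
# DOT dialect I/O
# ---------------------------------------------------------------------------
#
# Dialect: a digraph whose node labels are "FORMULA\nMASS" and whose edge
# labels are loss formulas; an optional node attribute ``intensity`` carries
# the matched peak intensity.  Unknown attributes are ignored on read.

_DOT_NODE_RE = re.compile(r'^\s*(\w+)\s*\[(.*)\]\s*;?\s*$')
_DOT_EDGE_RE = re.compile(r'^\s*(\w+)\s*->\s*(\w+)\s*\[(.*)\]\s*;?\s*$')
_DOT_ATTR_RE = re.compile(r'(\w+)\s*=\s*"([^"]*)"')
_DOT_HEADER_RE = re.compile(r'^\s*(?:strict\s+)?digraph\s*(?:"([^"]*)"|(\w+))?\s*\{')


def write_dot_tree(tree: FragmentationTree, path: str | Path) -> None:
    lines = [f'digraph "{tree.spectrum_id}" {{']
    for i in tree.graph.nodes:
        n = tree.node(i)
        attrs = [f'label="{n.formula}\\n{n.mass:.6f}"']
        if n.peak_intensity is not None:
            attrs.append(f'intensity="{n.peak_intensity:.6f}"')
        lines.append(f'  v{i} [{", ".join(attrs)}];')
    for parent, child, data in tree.graph.edges(data=True):
        lines.append(f'  v{parent} -> v{child} [label="{data["loss"]}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_dot_tree(path: str | Path) -> FragmentationTree:
    """Parse and validate a fragmentation tree from the DOT dialect."""
    text = Path(path).read_text()
    spectrum_id = ""
    nodes: dict[str, FragTreeNode] = {}
    edges: list[tuple[str, str, MolecularFormula]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line == "}":
            continue
        m = _DOT_HEADER_RE.match(line)
        if m:
            spectrum_id = m.group(1) or m.group(2) or ""
            continue
        m = _DOT_EDGE_RE.match(line)
        if m:
            attrs = dict(_DOT_ATTR_RE.findall(m.group(3)))
            if "label" not in attrs:
                raise TreeError(f"edge without loss label: {line!r}")
            edges.append((m.group(1), m.group(2), MolecularFormula(attrs["label"])))
            continue
        m = _DOT_NODE_RE.match(line)
        if m:
            attrs = dict(_DOT_ATTR_RE.findall(m.group(2)))
            label = attrs.get("label", "")
            parts = label.split("\\n")
            formula = MolecularFormula(parts[0])
            node_mass = float(parts[1]) if len(parts) > 1 else formula.ion_mass
            intensity = float(attrs["intensity"]) if "intensity" in attrs else None
            nodes[m.group(1)] = FragTreeNode(formula, node_mass, intensity)
            continue
        raise TreeError(f"unparseable DOT line: {line!r}")
    if not nodes:
        raise TreeError(f"no nodes found in {path}")
    tree = FragmentationTree(spectrum_id=spectrum_id)
    index = {name: i for i, name in enumerate(nodes)}
    for name, node in nodes.items():
        tree.graph.add_node(index[name], node=node)
    for a, b, loss in edges:
        if a not in index or b not in index:
            raise TreeError(f"edge references undeclared node: {a} -> {b}")
        tree.graph.add_edge(index[a], index[b], loss=loss)
    roots = [n for n in tree.graph.nodes if tree.graph.in_degree(n) == 0]
    if len(roots) != 1:
        raise TreeError(f"expected one root, found {len(roots)}")
    tree.root = roots[0]
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Noise filtering
# ---------------------------------------------------------------------------

def noise_filter(
    s: Spectrum,
    tree: FragmentationTree,
    ppm: float = DEFAULT_PPM,
    abs_da: float = DEFAULT_ABS_DA,
) -> Spectrum:
    """Keep only peaks annotated by a tree node, with their original intensities.

    A peak survives when its mass is within ``max(ppm, abs_da)`` of some node
    mass.  The result may be empty or precursor-only; callers that build
    libraries should drop such spectra (see :func:`is_empty_or_precursor_only`).
    """
    if tree.spectrum_id and tree.spectrum_id != s.identifier:
        raise ValueError(
            f"tree annotates spectrum {tree.spectrum_id!r}, not {s.identifier!r}"
        )
    node_masses = sorted(tree.node_masses())
    kept = [
        p
        for p in s.peaks
        if any(abs(p.mass - m) <= mass_tolerance_da(max(p.mass, m), ppm, abs_da) for m in node_masses)
    ]
    return s.with_peaks(kept)


def is_empty_or_precursor_only(s: Spectrum, ppm: float = DEFAULT_PPM,
                               abs_da: float = DEFAULT_ABS_DA) -> bool:
    """True when a (filtered) spectrum carries no fragment information."""
    frag = [p for p in s.peaks
            if abs(p.mass - s.precursor_mass) > mass_tolerance_da(s.precursor_mass, ppm, abs_da)]
    return len(frag) == 0


# ---------------------------------------------------------------------------
# Toy tree annotator (fixture plumbing)
# ---------------------------------------------------------------------------

#: Common small neutral losses used by the greedy annotator and the
#: synthetic-spectrum generator.  All pairwise mass differences are far
#: larger than the matching tolerance at fragment masses, so greedy
#: mass-based assignment is unambiguous.
COMMON_LOSSES = tuple(
    MolecularFormula(f)
    for f in (
        "H2", "CH2", "NH3", "H2O", "C2H2", "HCN", "CO", "CH2O",
        "CH4O", "C2H4", "C2H2O", "CO2", "CH2O2", "C3H6",
    )
)


def toy_tree_annotator(
    s: Spectrum,
    precursor_formula: MolecularFormula,
    losses: Iterable[MolecularFormula] = COMMON_LOSSES,
    ppm: float = DEFAULT_PPM,
    abs_da: float = DEFAULT_ABS_DA,
) -> FragmentationTree:
    """Greedy single-loss formula annotation of a spectrum (fixtures only).

    Starting from the precursor formula as root, peaks are visited in
    descending mass; each peak is attached as a child of the first existing
    node for which subtracting a loss from the small-loss alphabet yields a
    valid formula whose ion mass matches the peak.  Peaks that cannot be
    explained are left out (they are "noise" for this annotator).  This is a
    fixture-side stand-in for real tree computation, which solves a global
    optimization over full fragmentation graphs.
    """
    prec_ion = precursor_formula.ion_mass
    if abs(prec_ion - s.precursor_mass) > max(prec_ion * 10e-6, abs_da):
        raise ValueError(
            f"precursor formula mass {prec_ion:.5f} does not match spectrum "
            f"precursor {s.precursor_mass:.5f} within tolerance"
        )
    root_intensity = None
    for p in s.peaks:
        if abs(p.mass - prec_ion) <= mass_tolerance_da(prec_ion, ppm, abs_da):
            root_intensity = p.intensity
    tree = FragmentationTree.from_root(precursor_formula, s.identifier, root_intensity)
    losses = tuple(losses)
    for p in sorted(s.peaks, key=lambda p: -p.mass):
        if abs(p.mass - prec_ion) <= mass_tolerance_da(prec_ion, ppm, abs_da):
            continue  # the precursor peak is the root
        placed = False
        for node_id in list(tree.graph.nodes):
            if placed:
                break
            parent = tree.node(node_id)
            for loss in losses:
                cand = parent.formula - loss
                if not cand.valid():
                    continue
                if abs(cand.ion_mass - p.mass) <= mass_tolerance_da(max(cand.ion_mass, p.mass), ppm, abs_da):
                    tree.add_child(node_id, loss, peak_intensity=p.intensity)
                    placed = True
                    break
    tree.validate()
    return tree
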