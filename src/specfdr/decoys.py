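"""Decoy spectral-library generation.

A decoy library models the null hypothesis of spectral library search: its
spectra must look like real MS/MS spectra (so decoy hits score like false
target hits) while not corresponding to any compound actually present.
Three constructions are provided, in increasing order of realism:

``naive``
    each decoy peak mass is drawn uniformly from the pool of all fragment
    masses in the reference library (a baseline known to be inadequate);
``spectrum_based``
    peaks are added iteratively, conditioned on co-occurrence: each added
    ion recruits candidate ions from the library spectra that contain it,
    which mimics fragmentation cascades;
``tree_based``
    the target's fragmentation tree is re-rooted — structure and losses are
    kept, a new root receives the precursor-ion formula, fragment formulas
    are recomputed by subtracting losses, and subtrees that would get
    chemically impossible formulas (negative atom counts) are re-grafted
    onto other nodes.

Every decoy keeps its target's precursor mass and peak count, and reuses
the target's intensities, so target and decoy libraries are
indistinguishable in all per-spectrum summary statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .fragtree import FragmentationTree, FragTreeNode, MolecularFormula
from .spectra import Peak, SpectralLibrary, Spectrum

logger = logging.getLogger("specfdr")

Method = Literal["naive", "spectrum_based", "tree_based"]

#: Minimal relative separation between decoy peaks (parts per million).
SEPARATION_PPM = 5.0


class DecoyGenerationError(RuntimeError):
    pass


@dataclass
class DecoyLibrary:
    """A decoy library mirroring a target library entry-for-entry."""

    entries: list[Spectrum] = field(default_factory=list)
    source_library: str = ""
    method: Method = "naive"
    seed: int = 0
    #: identifiers of the target entries actually used (parity with targets)
    used_target_ids: list[str] = field(default_factory=list)
    #: per-spectrum status report ("ok", "skipped-no-tree", "dropped-subtree:<k>", ...)
    report: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def as_spectral_library(self) -> SpectralLibrary:
        return SpectralLibrary(entries=list(self.entries), name=f"decoy-{self.source_library}")


def _too_close(mass: float, accepted: list[float], ppm: float = SEPARATION_PPM) -> bool:
    return any(abs(mass - m) <= max(mass, m) * ppm * 1e-6 for m in accepted)


def _assign_intensities(target: Spectrum, masses: Sequence[float]) -> tuple[Peak, ...]:
    """Pair drawn masses with the target's intensities by mass rank.

    The smallest decoy mass receives the intensity of the target's smallest
    peak mass, and so on — this reuses the original intensities (multiset
    conservation) while preserving the intensity-vs-mass-rank profile.
    """
    srt = sorted(masses)
    intens = [p.intensity for p in target.peaks]  # peaks are stored mass-ascending
    return tuple(Peak(m, i) for m, i in zip(srt, intens[: len(srt)]))


def _decoy_id(target: Spectrum) -> str:
    return f"DECOY_{target.identifier}"


# ---------------------------------------------------------------------------
# Naive method
# ---------------------------------------------------------------------------

def naive_decoy(
    target: Spectrum,
    pool: SpectralLibrary | Sequence[Spectrum],
    rng: np.random.Generator,
    _pool_masses: np.ndarray | None = None,
) -> Spectrum:
    """Decoy with the target's peak count, masses drawn uniformly from the library pool.

    Masses above the target's precursor, or within 5 p.p.m. of an already
    drawn mass, are rejected and redrawn (the same hygiene rules as the
    spectrum-based method, so the three constructions stay comparable).
    """
    masses_pool = (
        _pool_masses
        if _pool_masses is not None
        else np.array([p.mass for s in pool for p in s.peaks])
    )
    if masses_pool.size == 0:
        raise DecoyGenerationError("empty fragment-mass pool")
    k = len(target.peaks)
    accepted: list[float] = []
    attempts = 0
    max_attempts = 200 * max(k, 1)
    while len(accepted) < k:
        if attempts >= max_attempts:
            raise DecoyGenerationError(
                f"pool exhausted generating naive decoy for {target.identifier!r} "
                f"({len(accepted)}/{k} peaks)"
            )
        attempts += 1
        m = float(masses_pool[rng.integers(masses_pool.size)])
        if m > target.precursor_mass or _too_close(m, accepted):
            continue
        accepted.append(m)
    return Spectrum(
        identifier=_decoy_id(target),
        precursor_mass=target.precursor_mass,
        ion_mode=target.ion_mode,
        peaks=_assign_intensities(target, accepted),
    )


# ---------------------------------------------------------------------------
# Spectrum-based method
# ---------------------------------------------------------------------------

def spectrum_based_decoy(
    target: Spectrum,
    pool: SpectralLibrary | Sequence[Spectrum],
    rng: np.random.Generator,
    _pool_sorted: tuple[np.ndarray, np.ndarray] | None = None,
) -> Spectrum:
    """Decoy built by conditional, co-occurrence-driven fragment drawing.

    The target's precursor ion seeds the decoy.  Each ion added to the decoy
    recruits candidates: all library spectra containing that ion within
    5 p.p.m. contribute their fragment ions, from which five are drawn
    uniformly (all, if fewer) into a persistent candidate set.  Ions are then
    drawn from the candidate set one at a time; an ion lands in the decoy
    unless it lies above the precursor mass or within 5 p.p.m. of a previous
    decoy ion.  The two-stage draw mimics fragmentation cascades and keeps
    fragment-rich spectra from dominating.  If the candidate set runs dry,
    the remaining slots fall back to naive draws (logged).
    """
    entries = list(pool)
    if _pool_sorted is None:
        all_masses = np.array([p.mass for s in entries for p in s.peaks])
        spec_index = np.array([si for si, s in enumerate(entries) for _ in s.peaks])
        order = np.argsort(all_masses)
        _pool_sorted = (all_masses[order], spec_index[order])
    pool_masses_sorted, pool_spec_idx = _pool_sorted
    if pool_masses_sorted.size == 0:
        raise DecoyGenerationError("empty fragment-mass pool")

    k = len(target.peaks)
    decoy_masses: list[float] = []
    candidates: list[float] = []

    def recruit(mass: float) -> None:
        tol = mass * SEPARATION_PPM * 1e-6
        a = np.searchsorted(pool_masses_sorted, mass - tol, side="left")
        b = np.searchsorted(pool_masses_sorted, mass + tol, side="right")
        specs = np.unique(pool_spec_idx[a:b])
        frag: list[float] = [p.mass for si in specs for p in entries[si].peaks]
        if not frag:
            return
        n_draw = min(5, len(frag))
        drawn = rng.choice(len(frag), size=n_draw, replace=False)
        candidates.extend(frag[i] for i in drawn)

    # seed: the precursor fragment ion of the target spectrum (the precursor
    # m/z header doubles as the selected-ion mass when no precursor peak exists)
    seed_mass = target.precursor_mass
    decoy_masses.append(seed_mass)
    recruit(seed_mass)

    fallback = 0
    while len(decoy_masses) < k:
        if not candidates:
            # no conditional candidates left: naive draw for the remaining slots
            fallback += 1
            if fallback > 200 * k:
                raise DecoyGenerationError(
                    f"cannot complete spectrum-based decoy for {target.identifier!r}"
                )
            m = float(pool_masses_sorted[rng.integers(pool_masses_sorted.size)])
            if m > target.precursor_mass or _too_close(m, decoy_masses):
                continue
            logger.debug("spectrum_based_decoy %s: naive fallback draw", target.identifier)
            decoy_masses.append(m)
            recruit(m)
            continue
        i = int(rng.integers(len(candidates)))
        m = candidates.pop(i)
        if m > target.precursor_mass or _too_close(m, decoy_masses):
            continue
        decoy_masses.append(m)
        recruit(m)

    return Spectrum(
        identifier=_decoy_id(target),
        precursor_mass=target.precursor_mass,
        ion_mode=target.ion_mode,
        peaks=_assign_intensities(target, decoy_masses),
    )


# ---------------------------------------------------------------------------
# Tree-based method (fragmentation-tree re-rooting)
# ---------------------------------------------------------------------------

def _undirected_edges(tree: FragmentationTree) -> dict[int, list[tuple[int, MolecularFormula]]]:
    """Adjacency of the tree skeleton; each incident edge carries its loss."""
    adj: dict[int, list[tuple[int, MolecularFormula]]] = {i: [] for i in tree.graph.nodes}
    for a, b, data in tree.graph.edges(data=True):
        adj[a].append((b, data["loss"]))
        adj[b].append((a, data["loss"]))
    return adj


def _propagate_count_invalid(
    tree: FragmentationTree, new_root: int, root_formula: MolecularFormula
) -> int:
    """Number of edges needing re-grafting were ``new_root`` made the root.

    The re-rooting is simulated once: formulas are propagated outward from
    the new root by subtracting each edge's loss; an edge whose child
    formula goes invalid is counted and its subtree not descended (it would
    be re-grafted, so its formulas are unknown at this point).
    """
    adj = _undirected_edges(tree)
    n_invalid = 0
    stack = [(new_root, -1, root_formula)]
    while stack:
        node, parent, formula = stack.pop()
        for nbr, loss in adj[node]:
            if nbr == parent:
                continue
            child = formula - loss
            if child.valid():
                stack.append((nbr, node, child))
            else:
                n_invalid += 1
    return n_invalid


def reroot_choices(tree: FragmentationTree) -> list[tuple[int, int, float]]:
    """Per node: (node id, n edges to re-graft, selection weight 1/(n+1))."""
    root_formula = tree.node(tree.root).formula
    out = []
    for v in tree.graph.nodes:
        n = _propagate_count_invalid(tree, v, root_formula)
        out.append((v, n, 1.0 / (n + 1)))
    return out


def sample_new_root(tree: FragmentationTree, rng: np.random.Generator) -> int:
    """Draw the new root with probability proportional to 1/(n+1).

    n is the number of edges that would need re-grafting were that node made
    the root, so roots requiring little surgery are preferred while every
    node keeps a positive selection probability.
    """
    choices = reroot_choices(tree)
    weights = np.array([w for _, _, w in choices])
    idx = rng.choice(len(choices), p=weights / weights.sum())
    return choices[idx][0]


def tree_based_decoy(
    target: Spectrum,
    tree: FragmentationTree,
    rng: np.random.Generator,
    max_regraft_attempts: int = 100,
) -> tuple[Spectrum, str]:
    """Decoy from a re-rooted fragmentation tree.

    A new root is sampled with probability proportional to 1/(n+1), where n
    is the number of edges whose subtrees would need re-grafting; the new
    root receives the precursor-ion formula, fragment formulas are
    recomputed along the losses, and invalid subtrees are re-grafted onto
    uniformly chosen valid nodes.  Decoy peak masses are the resulting ion
    masses; intensities are the original peaks' (carried on the tree nodes).

    Returns the decoy spectrum and a status string ("ok", or
    "dropped-subtree:<k>" when some subtree admitted no valid attachment and
    its peaks were dropped).
    """
    tree.validate()
    root_formula = tree.node(tree.root).formula
    new_root = sample_new_root(tree, rng)

    adj = _undirected_edges(tree)
    formulas: dict[int, MolecularFormula] = {new_root: root_formula}
    pending: list[tuple[int, int, MolecularFormula]] = []  # (parent, child-root, loss)

    def propagate(node: int, parent: int) -> None:
        for nbr, loss in adj[node]:
            if nbr == parent or nbr in formulas:
                continue
            child = formulas[node] - loss
            if child.valid():
                formulas[nbr] = child
                propagate(nbr, node)
            else:
                pending.append((node, nbr, loss))

    propagate(new_root, -1)

    dropped = 0
    while pending:
        blocked_parent, sub_root, loss = pending.pop(0)
        placed = False
        for _ in range(max_regraft_attempts):
            hosts = [v for v in formulas if v != sub_root]
            host = hosts[int(rng.integers(len(hosts)))]
            cand = formulas[host] - loss
            if cand.valid():
                formulas[sub_root] = cand
                propagate(sub_root, host)
                placed = True
                break
        if not placed:
            # count the whole unreachable subtree as dropped
            def count_subtree(node: int, parent: int) -> int:
                return 1 + sum(
                    count_subtree(nbr, node)
                    for nbr, _ in adj[node]
                    if nbr != parent and nbr not in formulas
                )

            n_sub = count_subtree(sub_root, blocked_parent)
            dropped += n_sub
            logger.warning(
                "tree_based_decoy %s: dropped subtree of %d node(s), no valid re-graft",
                target.identifier, n_sub,
            )

    # distinct re-rooted paths can occasionally sum to the same total formula;
    # such collisions are dropped (logged) rather than silently merged
    by_mass: dict[float, float] = {}
    for v, f in formulas.items():
        intensity = tree.node(v).peak_intensity
        if intensity is None:
            intensity = 1.0
        m = f.ion_mass
        if m in by_mass:
            dropped += 1
            by_mass[m] = max(by_mass[m], intensity)
        else:
            by_mass[m] = intensity
    peaks = [Peak(m, i) for m, i in by_mass.items()]
    status = "ok" if dropped == 0 else f"dropped-subtree:{dropped}"
    decoy = Spectrum(
        identifier=_decoy_id(target),
        precursor_mass=target.precursor_mass,
        ion_mode=target.ion_mode,
        peaks=tuple(peaks),
    )
    return decoy, status


# ---------------------------------------------------------------------------
# Library builder
# ---------------------------------------------------------------------------

def build_decoy_library(
    targets: SpectralLibrary,
    trees: Mapping[str, FragmentationTree] | None = None,
    method: Method = "tree_based",
    seed: int = 0,
) -> DecoyLibrary:
    """One decoy per usable target, from a single seeded generator.

    The generator is consumed in deterministic entry order, so a given seed
    reproduces the library bit-for-bit.  Targets without a fragmentation
    tree are skipped under ``tree_based`` (and recorded in the report) so
    callers can drop them from the target side too, keeping target/decoy
    parity.  Per-spectrum failures are collected, not fatal.
    """
    rng = np.random.default_rng(seed)
    lib = DecoyLibrary(source_library=targets.name, method=method, seed=seed)
    entries = list(targets)
    pool_masses = np.array([p.mass for s in entries for p in s.peaks])
    if method == "spectrum_based":
        spec_index = np.array([si for si, s in enumerate(entries) for _ in s.peaks])
        order = np.argsort(pool_masses)
        pool_sorted = (pool_masses[order], spec_index[order])
    for s in entries:
        try:
            if method == "naive":
                d = naive_decoy(s, entries, rng, _pool_masses=pool_masses)
                status = "ok"
            elif method == "spectrum_based":
                d = spectrum_based_decoy(s, entries, rng, _pool_sorted=pool_sorted)
                status = "ok"
            elif method == "tree_based":
                if trees is None or s.identifier not in trees:
                    lib.report[s.identifier] = "skipped-no-tree"
                    continue
                d, status = tree_based_decoy(s, trees[s.identifier], rng)
            else:
                raise ValueError(f"unknown decoy method {method!r}")
        except DecoyGenerationError as exc:
            lib.report[s.identifier] = f"error: {exc}"
            continue
        lib.entries.append(d)
        lib.used_target_ids.append(s.identifier)
        lib.report[s.identifier] = status
    return lib
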