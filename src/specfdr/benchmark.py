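"""Synthetic benchmark generation and FDR-quality evaluation.

Real evaluation of FDR estimates needs query compounds of known identity.
This module builds a fully synthetic stand-in at desk scale: a reference
library of random (but chemically valid) compounds whose spectra are
generated from random fragmentation trees over a common neutral-loss
alphabet, plus query spectra of three kinds —

* *true* queries: noisy replicates of library spectra (the compound is in
  the library);
* *isomer* queries: compounds absent from the library but sharing the
  precursor mass and most fragments with a library entry (the hard
  near-miss case that inflates scores of wrong hits);
* *null* queries: compounds generated by the same process but absent from
  the library (their best hits are false by construction).

Because all spectra derive from the same loss alphabet, unrelated compounds
still share neutral-loss patterns — the reason false hits attain non-trivial
modified-cosine scores, as they do for real chemistry.

With the ground truth in hand, true FDRs and q-values follow from labeled
correctness, and estimated q-values, decoy p-values and the
empirical-Bayes fit can be checked for calibration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decoys import DecoyLibrary, Method, build_decoy_library
from .fdr import (
    MIN_SCORES_FOR_EB,
    FdrCurve,
    MixtureModel,
    estimate_fdr_tda,
    estimate_p_value,
    estimate_pit,
    fdr_from_pep,
    fit_mixture_em,
    sort_hits,
)
from .fragtree import (
    COMMON_LOSSES,
    FragmentationTree,
    MolecularFormula,
    is_empty_or_precursor_only,
    noise_filter,
    read_dot_tree,
    toy_tree_annotator,
    write_dot_tree,
)
from .scoring import SpectrumMatch, Variant, search_library
from .spectra import (
    Peak,
    SpectralLibrary,
    Spectrum,
    passes_library_filters,
    read_mgf,
    write_mgf,
)

ABSENT = "absent"


# ---------------------------------------------------------------------------
# Benchmark specification and generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticLibrarySpec:
    """Parameters of the synthetic benchmark.

    Defaults describe a desk-scale study: a 200-compound positive-mode
    library with 8–14 fragment peaks per spectrum, queries that are half
    true replicates, 10% near-miss isomers and the rest unrelated nulls,
    5 p.p.m. mass jitter and moderate intensity noise.
    """

    n_compounds: int = 200
    n_queries: int = 200
    element_alphabet: tuple[str, ...] = ("C", "H", "N", "O", "S")
    peaks_per_spectrum: tuple[int, int] = (8, 14)
    isomer_fraction: float = 0.1
    true_fraction: float = 0.5
    noise_peaks: tuple[int, int] = (0, 3)
    query_noise_peaks: tuple[int, int] = (0, 5)
    mass_jitter_ppm: float = 5.0
    intensity_sigma: float = 0.3
    dropout: float = 0.1
    isomer_shift_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 2:
            raise ValueError("n_compounds must be >= 2")
        for rng_field in ("peaks_per_spectrum", "noise_peaks", "query_noise_peaks"):
            lo, hi = getattr(self, rng_field)
            if hi < lo:
                raise ValueError(f"empty range for {rng_field}: ({lo}, {hi})")
        if not 0.0 <= self.isomer_fraction <= 1.0:
            raise ValueError("isomer_fraction must be in [0,1]")
        if not 0.0 <= self.true_fraction <= 1.0 - self.isomer_fraction:
            raise ValueError("true_fraction + isomer_fraction must not exceed 1")


@dataclass
class BenchmarkBundle:
    target: SpectralLibrary
    trees: dict[str, FragmentationTree]
    queries: SpectralLibrary
    truth: dict[str, str]
    spec: SyntheticLibrarySpec


def _random_formula(rng: np.random.Generator, alphabet: Sequence[str]) -> MolecularFormula:
    for _ in range(100):
        counts = {"C": int(rng.integers(10, 31))}
        counts["H"] = int(rng.integers(counts["C"], 2 * counts["C"] + 3))
        if "N" in alphabet:
            counts["N"] = int(rng.integers(0, 4))
        if "O" in alphabet:
            counts["O"] = int(rng.integers(2, 9))
        if "S" in alphabet and rng.random() < 0.15:
            counts["S"] = 1
        f = MolecularFormula(counts)
        if 150.0 < f.monoisotopic_mass < 950.0:
            return f
    raise RuntimeError("could not draw a compound formula in the mass range")


#: minimum separation between generated fragment masses; comfortably above
#: the 10 p.p.m. / 2 mDa matching tolerance so annotation stays unambiguous
_MIN_SEP_PPM = 25.0
_MIN_SEP_DA = 0.006


def _well_separated(mass: float, existing: list[float]) -> bool:
    return all(
        abs(mass - m) > max(max(mass, m) * _MIN_SEP_PPM * 1e-6, _MIN_SEP_DA)
        for m in existing
    )


def _random_tree_masses(
    rng: np.random.Generator, formula: MolecularFormula, n_peaks: int
) -> FragmentationTree:
    """A random fragmentation tree: uniform topology, random losses on edges.

    The unrooted topology is drawn uniformly (random Prüfer sequence) and the
    root placed at a uniformly chosen node, so the rooted-tree distribution
    is invariant under re-rooting.  This matters: the tree-based decoy
    re-roots these trees, and a generator whose trees were grown outward
    from the root would hand the decoy systematically deeper loss paths
    than real spectra have, violating the premise that decoys mimic targets.
    Losses are drawn from the common-loss alphabet, re-drawn until every
    fragment formula is valid and fragment masses stay above 55 Da and
    pairwise separated beyond the matching tolerance.
    """
    import networkx as nx

    for _ in range(40):
        n = max(1, n_peaks)
        if n == 1:
            return FragmentationTree.from_root(formula)
        if n == 2:
            topo = nx.Graph([(0, 1)])
        else:
            topo = nx.from_prufer_sequence([int(x) for x in rng.integers(0, n, size=n - 2)])
        root_label = int(rng.integers(n))
        tree = FragmentationTree.from_root(formula)
        node_of = {root_label: tree.root}
        masses = [formula.ion_mass]
        ok = True
        stack = [root_label]
        seen = {root_label}
        while stack and ok:
            u = stack.pop()
            for v in topo.neighbors(u):
                if v in seen:
                    continue
                seen.add(v)
                placed = False
                for _try in range(40):
                    loss = COMMON_LOSSES[int(rng.integers(len(COMMON_LOSSES)))]
                    cand = tree.node(node_of[u]).formula - loss
                    if not cand.valid():
                        continue
                    m = cand.ion_mass
                    if m < 55.0 or not _well_separated(m, masses):
                        continue
                    node_of[v] = tree.add_child(node_of[u], loss)
                    masses.append(m)
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
                stack.append(v)
        if ok:
            return tree
    raise RuntimeError(f"could not assign valid losses to a {n_peaks}-node tree")


def _make_compound_spectrum(
    rng: np.random.Generator,
    spec: SyntheticLibrarySpec,
    identifier: str,
    compound_id: str,
) -> tuple[Spectrum, MolecularFormula]:
    """One library-grade spectrum: tree-derived peaks + a few noise peaks."""
    formula = _random_formula(rng, spec.element_alphabet)
    lo, hi = spec.peaks_per_spectrum
    tree = _random_tree_masses(rng, formula, int(rng.integers(lo, hi + 1)))
    precursor = formula.ion_mass
    peaks = []
    node_masses = []
    for i in tree.node_ids():
        m = tree.node(i).mass
        node_masses.append(m)
        # log-uniform intensities over ~1.2 decades: skewed but every
        # fragment stays above the 2% informative-peak cutoff
        intensity = 100.0 * 10 ** rng.uniform(-1.2, 0.0)
        if i == tree.root:
            jitter = 0.0  # the precursor peak defines the precursor m/z
        else:
            jitter = rng.uniform(-3e-6, 3e-6) * m
        peaks.append(Peak(m + jitter, intensity))
    n_noise = int(rng.integers(spec.noise_peaks[0], spec.noise_peaks[1] + 1))
    for _ in range(n_noise):
        m = rng.uniform(60.0, precursor - 1.0)
        if _well_separated(m, node_masses):
            peaks.append(Peak(m, 100.0 * 10 ** rng.uniform(-1.7, -1.0)))
    s = Spectrum(
        identifier=identifier,
        precursor_mass=precursor,
        ion_mode="positive",
        peaks=tuple(peaks),
        compound_mass=formula.monoisotopic_mass,
        compound_id=compound_id,
    )
    return s, formula


def _perturb(
    rng: np.random.Generator, spec: SyntheticLibrarySpec, s: Spectrum, identifier: str
) -> Spectrum:
    """Instrument-style noise: peak dropout, mass jitter, intensity noise, noise peaks."""
    kept = [p for p in s.peaks if rng.random() >= spec.dropout]
    if len(kept) < 5:  # never degrade a query below the informative-peak floor
        kept = sorted(s.peaks, key=lambda p: -p.intensity)[:5]
    peaks = [
        Peak(
            p.mass * (1.0 + rng.uniform(-1e-6, 1e-6) * spec.mass_jitter_ppm),
            p.intensity * rng.lognormal(0.0, spec.intensity_sigma),
        )
        for p in kept
    ]
    n_noise = int(rng.integers(spec.query_noise_peaks[0], spec.query_noise_peaks[1] + 1))
    for _ in range(n_noise):
        peaks.append(
            Peak(rng.uniform(60.0, s.precursor_mass - 1.0), 100.0 * 10 ** rng.uniform(-1.7, -1.0))
        )
    return Spectrum(
        identifier=identifier,
        precursor_mass=s.precursor_mass,
        ion_mode="positive",
        peaks=tuple(peaks),
        compound_mass=s.compound_mass,
    )


def _make_isomer(rng: np.random.Generator, spec: SyntheticLibrarySpec, s: Spectrum) -> Spectrum:
    """A compound absent from the library but spectrally similar to entry ``s``.

    The precursor mass is kept and a fraction of the fragment peaks is
    shifted by a random small-loss mass, emulating a structural isomer with
    a partly overlapping fragmentation pattern.
    """
    peaks = []
    for p in s.peaks:
        if abs(p.mass - s.precursor_mass) < 0.01 or rng.random() >= spec.isomer_shift_fraction:
            peaks.append(p)
            continue
        delta = COMMON_LOSSES[int(rng.integers(len(COMMON_LOSSES)))].monoisotopic_mass
        sign = 1.0 if (rng.random() < 0.5 and p.mass + delta < s.precursor_mass - 1) else -1.0
        m = p.mass + sign * delta
        if m < 55.0:
            m = p.mass + delta
        if m >= s.precursor_mass:
            m = p.mass
        peaks.append(Peak(m, p.intensity))
    return Spectrum(
        identifier=s.identifier,
        precursor_mass=s.precursor_mass,
        ion_mode="positive",
        peaks=tuple(peaks),
    )


def generate_benchmark(spec: SyntheticLibrarySpec) -> BenchmarkBundle:
    """Deterministically generate (target library, trees, queries, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    entries = []
    trees: dict[str, FragmentationTree] = {}
    formulas: dict[str, MolecularFormula] = {}
    for i in range(spec.n_compounds):
        ident, cid = f"LIB{i:04d}", f"CPD{i:04d}"
        s, f = _make_compound_spectrum(rng, spec, ident, cid)
        entries.append(s)
        formulas[ident] = f
        trees[ident] = toy_tree_annotator(s, f)
    target = SpectralLibrary(entries=entries, name=f"synthetic-{spec.seed}")

    n_true = int(round(spec.true_fraction * spec.n_queries))
    n_isomer = int(round(spec.isomer_fraction * spec.n_queries))
    n_null = spec.n_queries - n_true - n_isomer
    queries: list[Spectrum] = []
    truth: dict[str, str] = {}
    qn = 0

    def next_id() -> str:
        nonlocal qn
        qn += 1
        return f"Q{qn:04d}"

    for _ in range(n_true):
        src = entries[int(rng.integers(len(entries)))]
        qid = next_id()
        queries.append(_perturb(rng, spec, src, qid))
        truth[qid] = src.compound_id
    for _ in range(n_isomer):
        src = entries[int(rng.integers(len(entries)))]
        qid = next_id()
        queries.append(_perturb(rng, spec, _make_isomer(rng, spec, src), qid))
        truth[qid] = ABSENT
    for _ in range(n_null):
        qid = next_id()
        s, _f = _make_compound_spectrum(rng, spec, qid, f"NULL_{qid}")
        queries.append(_perturb(rng, spec, s, qid))
        truth[qid] = ABSENT

    return BenchmarkBundle(
        target=target,
        trees=trees,
        queries=SpectralLibrary(entries=queries, name=f"queries-{spec.seed}"),
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Bundle I/O (target.mgf, queries.mgf, trees/*.dot, truth.tsv, spec.json)
# ---------------------------------------------------------------------------

def write_bundle(bundle: BenchmarkBundle, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_mgf(bundle.target, d / "target.mgf")
    write_mgf(bundle.queries, d / "queries.mgf")
    (d / "trees").mkdir(exist_ok=True)
    for ident, tree in bundle.trees.items():
        write_dot_tree(tree, d / "trees" / f"{ident}.dot")
    pd.DataFrame(
        sorted(bundle.truth.items()), columns=["query_id", "compound_id"]
    ).to_csv(d / "truth.tsv", sep="\t", index=False)
    (d / "spec.json").write_text(json.dumps(asdict(bundle.spec), indent=2) + "\n")


def read_bundle(directory: str | Path) -> BenchmarkBundle:
    d = Path(directory)
    raw = json.loads((d / "spec.json").read_text())
    for key in ("element_alphabet", "peaks_per_spectrum", "noise_peaks", "query_noise_peaks"):
        raw[key] = tuple(raw[key])
    spec = SyntheticLibrarySpec(**raw)
    target = read_mgf(d / "target.mgf", name="target")
    queries = read_mgf(d / "queries.mgf", name="queries")
    trees = {p.stem: read_dot_tree(p) for p in sorted((d / "trees").glob("*.dot"))}
    truth_df = pd.read_csv(d / "truth.tsv", sep="\t")
    truth = dict(zip(truth_df.query_id.astype(str), truth_df.compound_id.astype(str)))
    return BenchmarkBundle(target=target, trees=trees, queries=queries, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# True q-values and calibration
# ---------------------------------------------------------------------------

def true_q_values(
    hits: Sequence[SpectrumMatch],
    truth: Mapping[str, str],
    reference_compounds: Mapping[str, str],
) -> FdrCurve:
    """True FDR/q-values from known query identities.

    A hit is correct when the reference's compound equals the query's true
    compound; the true FDR at a threshold is the ratio of false hits among
    target hits above it, and the true q-value the smallest FDR at which a
    hit is reported.
    """
    ordered = sort_hits(hits)
    for h in ordered:
        if h.query_id not in truth:
            raise ValueError(f"query {h.query_id!r} missing from ground truth")
    correct = np.array(
        [
            truth[h.query_id] != ABSENT
            and reference_compounds.get(h.reference_id) == truth[h.query_id]
            for h in ordered
        ]
    )
    n = np.arange(1, len(ordered) + 1)
    false = np.cumsum(~correct)
    fdr = false / n
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    return FdrCurve(
        target_hits=ordered,
        thresholds=np.array([h.score for h in ordered]),
        n_target=n,
        n_decoy=false,
        fdr=fdr,
        q=q,
        pit=1.0,
    )


@dataclass
class CalibrationReport:
    """Estimated-vs-true q-values plus decoy p-value uniformity diagnostics."""

    per_hit: pd.DataFrame
    ks_statistic: float
    ks_pvalue: float
    max_abs_dev_band: float
    band: tuple[float, float]
    small_q_bias: bool
    qq_table: pd.DataFrame

    def summary(self) -> dict:
        return {
            "n_hits": int(len(self.per_hit)),
            "ks_statistic": self.ks_statistic,
            "ks_pvalue": self.ks_pvalue,
            "max_abs_dev_band": self.max_abs_dev_band,
            "band": list(self.band),
            "small_q_bias": self.small_q_bias,
        }


def calibration_report(
    estimated: FdrCurve,
    true_curve: FdrCurve,
    p_values: Sequence[float],
    band: tuple[float, float] = (0.05, 0.3),
) -> CalibrationReport:
    """Compare estimated with true q-values and test p-value uniformity.

    ``p_values`` should be the decoy p-values of *false* hits; under an
    adequate decoy model they are uniform, which a Kolmogorov–Smirnov test
    checks.  The report also flags the known bias region: estimates close to
    zero for true q-values below 0.05, driven by high-scoring isomer hits
    that have no decoy counterpart.
    """
    est_ids = [h.query_id for h in estimated.target_hits]
    true_ids = [h.query_id for h in true_curve.target_hits]
    if est_ids != true_ids:
        raise ValueError("estimated and true curves must come from the same hit list")
    per_hit = pd.DataFrame(
        {
            "query_id": est_ids,
            "score": estimated.thresholds,
            "estimated_q": estimated.q,
            "true_q": true_curve.q,
        }
    )
    pv = np.asarray(list(p_values), dtype=float)
    if pv.size:
        ks = stats.kstest(pv, "uniform")
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
        grid = np.linspace(0, 1, 21)
        qq = pd.DataFrame(
            {"uniform_quantile": grid, "p_value_quantile": np.quantile(pv, grid)}
        )
    else:
        ks_stat, ks_p = float("nan"), float("nan")
        qq = pd.DataFrame(columns=["uniform_quantile", "p_value_quantile"])
    in_band = (per_hit.true_q >= band[0]) & (per_hit.true_q <= band[1])
    max_dev = (
        float(np.max(np.abs(per_hit.estimated_q[in_band] - per_hit.true_q[in_band])))
        if in_band.any()
        else 0.0
    )
    below = per_hit.true_q < band[0]
    small_q_bias = bool(
        below.any() and (per_hit.estimated_q[below].mean() < per_hit.true_q[below].mean())
    )
    return CalibrationReport(
        per_hit=per_hit,
        ks_statistic=ks_stat,
        ks_pvalue=ks_p,
        max_abs_dev_band=max_dev,
        band=band,
        small_q_bias=small_q_bias,
        qq_table=qq,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline on a bundle
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    target_hits: list[SpectrumMatch]
    decoy_hits: list[SpectrumMatch]
    decoy_library: DecoyLibrary
    filtered_target: SpectralLibrary
    mixture: MixtureModel | None
    pit: float
    tda_curve: FdrCurve
    eb_curve: FdrCurve | None
    true_curve: FdrCurve
    p_values: np.ndarray  # decoy p-value per target hit, aligned with tda_curve
    false_hit_p_values: np.ndarray


def noise_filter_library(
    library: SpectralLibrary, trees: Mapping[str, FragmentationTree]
) -> SpectralLibrary:
    """Tree-based noise filtering of a whole library; uninformative spectra dropped."""
    kept = []
    for s in library:
        if s.identifier not in trees:
            continue
        f = noise_filter(s, trees[s.identifier])
        if is_empty_or_precursor_only(f):
            continue
        kept.append(f)
    return SpectralLibrary(entries=kept, name=f"{library.name}-filtered")


def run_pipeline(
    bundle: BenchmarkBundle,
    method: Method = "tree_based",
    decoy_seed: int = 0,
    variant: Variant = "gnps",
    min_matched_peaks: int = 3,
    tolerance_ppm: float = 10.0,
    noise_filtered: bool = True,
    use_empirical_bayes_pit: bool = True,
) -> PipelineResult:
    """Generate decoys, search, and estimate FDR/q/p on a benchmark bundle.

    The tree-based decoy applies noise filtering by design, so the target
    side is noise-filtered too whenever ``noise_filtered`` (default).  The
    search runs without a precursor window: synthetic precursor masses are
    continuous, so windowing would leave null queries with no eligible
    references — with real libraries a 10 p.p.m. window is the norm.
    """
    target = (
        noise_filter_library(bundle.target, bundle.trees) if noise_filtered else bundle.target
    )
    decoy_lib = build_decoy_library(target, bundle.trees, method=method, seed=decoy_seed)
    usable = set(decoy_lib.used_target_ids)
    target = SpectralLibrary(
        entries=[s for s in target if s.identifier in usable], name=target.name
    )
    ref_compounds = {s.identifier: s.compound_id for s in bundle.target}
    common = dict(
        min_matched_peaks=min_matched_peaks, tolerance_ppm=tolerance_ppm, variant=variant
    )
    target_hits = search_library(bundle.queries, target, origin="target", **common)
    decoy_hits = search_library(
        bundle.queries, decoy_lib.entries, origin="decoy", **common
    )

    mixture = None
    pit = 1.0
    scores = [h.score for h in target_hits]
    if use_empirical_bayes_pit and len(scores) >= MIN_SCORES_FOR_EB:
        mixture = fit_mixture_em(scores)
        pit = estimate_pit(mixture)

    tda = estimate_fdr_tda(target_hits, decoy_hits, pit=pit)
    eb = fdr_from_pep(mixture, target_hits) if mixture is not None else None
    true_curve = true_q_values(target_hits, bundle.truth, ref_compounds)
    p_values = np.array(
        [estimate_p_value(h.score, decoy_hits) for h in tda.target_hits]
    )
    false_mask = np.array(
        [
            not (
                bundle.truth[h.query_id] != ABSENT
                and ref_compounds.get(h.reference_id) == bundle.truth[h.query_id]
            )
            for h in tda.target_hits
        ]
    )
    return PipelineResult(
        target_hits=target_hits,
        decoy_hits=decoy_hits,
        decoy_library=decoy_lib,
        filtered_target=target,
        mixture=mixture,
        pit=pit,
        tda_curve=tda,
        eb_curve=eb,
        true_curve=true_curve,
        p_values=p_values,
        false_hit_p_values=p_values[false_mask],
    )


# ---------------------------------------------------------------------------
# Scoring-parameter sweep
# ---------------------------------------------------------------------------

def parameter_sweep(
    queries: SpectralLibrary,
    target: SpectralLibrary,
    decoy: Sequence[Spectrum] | DecoyLibrary,
    min_matched_peaks_grid: Sequence[int],
    fdr_level: float = 0.01,
    variant: Variant = "gnps",
    tolerance_ppm: float = 10.0,
    pit: float = 1.0,
) -> pd.DataFrame:
    """Trade-off between the matched-peak gate and the score threshold.

    For each minimum-matched-peaks value, report the smallest score
    threshold whose q-value stays at or below ``fdr_level`` and the number
    of annotations accepted there.  Requiring more matching ions lets the
    score threshold relax — the score needed for a fixed FDR decreases.
    """
    if not list(min_matched_peaks_grid):
        raise ValueError("min_matched_peaks_grid must be non-empty")
    decoy_entries = list(decoy)
    rows = []
    for mmp in min_matched_peaks_grid:
        t_hits = search_library(
            queries, target, origin="target", min_matched_peaks=mmp,
            tolerance_ppm=tolerance_ppm, variant=variant,
        )
        d_hits = search_library(
            queries, decoy_entries, origin="decoy", min_matched_peaks=mmp,
            tolerance_ppm=tolerance_ppm, variant=variant,
        )
        curve = estimate_fdr_tda(t_hits, d_hits, pit=pit)
        threshold, n_annot = curve.q_at_fdr(fdr_level)
        rows.append(
            {
                "min_matched_peaks": mmp,
                "score_threshold": threshold,
                "n_annotations": n_annot,
                "n_target_hits": len(t_hits),
                "n_decoy_hits": len(d_hits),
            }
        )
    return pd.DataFrame(rows)
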