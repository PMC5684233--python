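"""Peak alignment and cosine-family spectrum–spectrum scoring.

Spectral library search scores a query spectrum against reference spectra
with a normalized dot product over tolerance-matched peak pairs.  Three
weightings of the peak vectors are provided:

``cosine``
    plain intensity weights, w = I;
``massbank``
    w = m² · I^0.5, the mass-squared/square-root-intensity convention that
    up-weights heavy, structure-specific fragments;
``gnps``
    w = I^0.5 with *shifted* matching: a reference peak may also match a
    query peak displaced by the precursor-mass difference, so fragments
    sharing the same neutral loss from their precursor align even when a
    modification shifts their absolute mass ("modified cosine").

Alignment is an exact maximum-weight bipartite matching on the candidate
pair graph (each peak used at most once), so scores do not depend on peak
order and can be checked against brute-force enumeration on small spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .spectra import SpectralLibrary, Spectrum

Variant = Literal["cosine", "massbank", "gnps"]


@dataclass(frozen=True)
class PeakAlignment:
    """A one-to-one matching between query and reference peak indices."""

    pairs: tuple[tuple[int, int], ...]
    tolerance_ppm: float
    shifted: bool = False

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SpectrumMatch:
    """One scored query–reference pair; the atom of FDR estimation."""

    query_id: str
    reference_id: str
    score: float
    n_matched: int
    origin: Literal["target", "decoy"] = "target"

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0 + 1e-9):
            raise ValueError(f"score must be in [0,1], got {self.score}")
        if self.n_matched < 0:
            raise ValueError("n_matched must be non-negative")


def _peak_weights(s: Spectrum, variant: Variant) -> np.ndarray:
    m = np.asarray(s.masses, dtype=float)
    i = np.asarray(s.intensities, dtype=float)
    if variant == "cosine":
        return i
    if variant == "massbank":
        return m ** 2 * np.sqrt(i)
    if variant == "gnps":
        return np.sqrt(i)
    raise ValueError(f"unknown scoring variant {variant!r}")


def _candidate_pairs(
    qm: np.ndarray, rm: np.ndarray, tolerance_ppm: float, shift: float | None
) -> list[tuple[int, int]]:
    """All (i, j) with |qm[i] − rm[j]| (or −shift) within the ppm tolerance."""
    pairs: set[tuple[int, int]] = set()
    deltas = [0.0] if shift is None else [0.0, shift]
    order = np.argsort(rm)
    rs = rm[order]
    for d in deltas:
        # query peak i matches reference mass near qm[i] − d
        targets = qm - d
        tol = np.abs(targets) * tolerance_ppm * 1e-6
        lo = np.searchsorted(rs, targets - tol, side="left")
        hi = np.searchsorted(rs, targets + tol, side="right")
        for i, (a, b) in enumerate(zip(lo, hi)):
            for j in order[a:b]:
                pairs.add((i, int(j)))
    return sorted(pairs)


def align_peaks(
    q: Spectrum,
    r: Spectrum,
    tolerance_ppm: float = 10.0,
    shifted: bool = False,
    q_weights: np.ndarray | None = None,
    r_weights: np.ndarray | None = None,
) -> PeakAlignment:
    """Maximum-weight one-to-one matching of tolerance-compatible peaks.

    The matching maximizes Σ w_q[i]·w_r[j] over all candidate pairs (weights
    default to intensities).  With ``shifted``, pairs displaced by the
    precursor-mass difference are also candidates.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if len(q) == 0 or len(r) == 0:
        return PeakAlignment((), tolerance_ppm, shifted)
    qm = np.asarray(q.masses)
    rm = np.asarray(r.masses)
    wq = np.asarray(q.intensities, float) if q_weights is None else np.asarray(q_weights, float)
    wr = np.asarray(r.intensities, float) if r_weights is None else np.asarray(r_weights, float)
    shift = (q.precursor_mass - r.precursor_mass) if shifted else None
    cand = _candidate_pairs(qm, rm, tolerance_ppm, shift)
    if not cand:
        return PeakAlignment((), tolerance_ppm, shifted)
    # fast path: candidate graph already a matching
    qi = [i for i, _ in cand]
    rj = [j for _, j in cand]
    if len(set(qi)) == len(cand) and len(set(rj)) == len(cand):
        pairs = tuple((i, j) for i, j in cand if wq[i] * wr[j] > 0)
        return PeakAlignment(pairs, tolerance_ppm, shifted)
    # exact assignment on the submatrix of involved peaks
    qs = sorted(set(qi))
    rs_ = sorted(set(rj))
    qpos = {i: k for k, i in enumerate(qs)}
    rpos = {j: k for k, j in enumerate(rs_)}
    w = np.zeros((len(qs), len(rs_)))
    for i, j in cand:
        w[qpos[i], rpos[j]] = max(w[qpos[i], rpos[j]], wq[i] * wr[j])
    rows, cols = linear_sum_assignment(w, maximize=True)
    pairs = tuple(
        (qs[a], rs_[b]) for a, b in zip(rows, cols) if w[a, b] > 0
    )
    return PeakAlignment(pairs, tolerance_ppm, shifted)


def cosine_score(
    q: Spectrum,
    r: Spectrum,
    tolerance_ppm: float = 10.0,
    variant: Variant = "cosine",
) -> SpectrumMatch:
    """Normalized dot product over an optimal peak alignment; score ∈ [0, 1].

    Weights are L2-normalized over the *full* peak lists, so a spectrum
    scored against itself gives exactly 1.
    """
    if len(q) == 0 or len(r) == 0:
        raise ValueError("cosine_score requires non-empty spectra")
    wq = _peak_weights(q, variant)
    wr = _peak_weights(r, variant)
    alignment = align_peaks(
        q, r, tolerance_ppm, shifted=(variant == "gnps"), q_weights=wq, r_weights=wr
    )
    nq = float(np.linalg.norm(wq))
    nr = float(np.linalg.norm(wr))
    if nq == 0 or nr == 0:
        return SpectrumMatch(q.identifier, r.identifier, 0.0, 0)
    dot = sum(wq[i] * wr[j] for i, j in alignment.pairs)
    score = min(1.0, dot / (nq * nr))
    return SpectrumMatch(q.identifier, r.identifier, float(score), len(alignment.pairs))


def search_library(
    queries: SpectralLibrary | Sequence[Spectrum],
    library: SpectralLibrary | Sequence[Spectrum],
    origin: Literal["target", "decoy"] = "target",
    min_matched_peaks: int = 6,
    precursor_window_ppm: float | None = None,
    precursor_window_da: float | None = None,
    tolerance_ppm: float = 10.0,
    variant: Variant = "cosine",
) -> list[SpectrumMatch]:
    """Best-scoring library hit per query.

    Only references whose precursor falls inside the window are considered;
    a hit must align at least ``min_matched_peaks`` peak pairs.  Ties are
    broken toward the lexicographically smaller reference identifier so
    results are reproducible.  Queries with no eligible reference produce no
    match.  Using the same window for target and decoy searches guarantees
    that any precursor range admits equally many target and decoy
    references, since decoys mirror target precursors exactly.
    """
    if min_matched_peaks < 0:
        raise ValueError("min_matched_peaks must be >= 0")
    entries = list(library)
    prec = np.array([r.precursor_mass for r in entries])
    order = np.argsort(prec, kind="stable")
    prec_sorted = prec[order]
    hits: list[SpectrumMatch] = []
    for q in queries:
        if len(q) == 0:
            continue
        if precursor_window_ppm is not None or precursor_window_da is not None:
            win = 0.0
            if precursor_window_ppm is not None:
                win = max(win, q.precursor_mass * precursor_window_ppm * 1e-6)
            if precursor_window_da is not None:
                win = max(win, precursor_window_da)
            a = np.searchsorted(prec_sorted, q.precursor_mass - win, side="left")
            b = np.searchsorted(prec_sorted, q.precursor_mass + win, side="right")
            candidates = [entries[i] for i in order[a:b]]
        else:
            candidates = entries
        best: SpectrumMatch | None = None
        for r in candidates:
            if len(r) == 0:
                continue
            m = cosine_score(q, r, tolerance_ppm, variant)
            if m.n_matched < min_matched_peaks:
                continue
            if (
                best is None
                or m.score > best.score
                or (m.score == best.score and m.reference_id < best.reference_id)
            ):
                best = m
        if best is not None:
            hits.append(
                SpectrumMatch(best.query_id, best.reference_id, best.score, best.n_matched, origin)
            )
    return hits


# ---------------------------------------------------------------------------
# TSV serialization of match lists
# ---------------------------------------------------------------------------

def matches_to_tsv(matches: Sequence[SpectrumMatch], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "query_id": m.query_id,
                "reference_id": m.reference_id,
                "score": m.score,
                "n_matched": m.n_matched,
                "origin": m.origin,
            }
            for m in matches
        ],
        columns=["query_id", "reference_id", "score", "n_matched", "origin"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def matches_from_tsv(path: str | Path) -> list[SpectrumMatch]:
    df = pd.read_csv(path, sep="\t")
    return [
        SpectrumMatch(
            str(row.query_id), str(row.reference_id), float(row.score),
            int(row.n_matched), str(row.origin),
        )
        for row in df.itertuples()
    ]
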