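"""Spectrum data model, spectral-library I/O and library-level processing.

The unit of everything downstream (scoring, decoy generation, FDR
estimation) is a centroided MS/MS spectrum: a precursor ion mass, an ion
mode and a peak list.  Libraries are read from MassBank-style text records
or MGF files, passed through the inclusion filters used to assemble a
homogeneous positive-mode reference library, and spectra of the same
compound recorded at different collision energies are merged into one.

All masses are in Da (m/z for singly charged ions); intensities are kept in
their raw, unnormalized units on disk and in memory — normalization happens
only inside the scoring routines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from pyteomics import mgf as _mgf

logger = logging.getLogger("specfdr")

#: Mass of a proton in Da; ion mass of [M+H]+ = neutral monoisotopic + PROTON_MASS.
PROTON_MASS = 1.00727646688

#: Default relative mass accuracy (parts per million).
DEFAULT_PPM = 10.0
#: Default absolute mass accuracy (Da); 2 mDa.
DEFAULT_ABS_DA = 0.002


def mass_tolerance_da(mass: float, ppm: float = DEFAULT_PPM, abs_da: float = DEFAULT_ABS_DA) -> float:
    """Matching window around ``mass``: max of the relative and absolute accuracy.

    The max-combination is the permissive reading for low-mass fragments,
    where a pure p.p.m. window would shrink below instrument accuracy
    (10 p.p.m. of 100 Da is 1 mDa, below the 2 mDa floor).
    """
    return max(mass * ppm * 1e-6, abs_da)


def masses_match(a: float, b: float, ppm: float = DEFAULT_PPM, abs_da: float = DEFAULT_ABS_DA) -> bool:
    """True when two masses agree within ``max(ppm, abs_da)`` of the larger mass."""
    return abs(a - b) <= mass_tolerance_da(max(a, b), ppm=ppm, abs_da=abs_da)


class SpectrumParseError(ValueError):
    """Raised when a spectral-library record cannot be parsed."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Peak:
    """A single fragment-ion signal: observed m/z (Da) and raw intensity."""

    mass: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"peak mass must be positive, got {self.mass}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")


def _normalize_peaks(peaks: Iterable[Peak]) -> tuple[Peak, ...]:
    """Sort ascending by mass and merge exact-duplicate masses (keep max intensity)."""
    out: list[Peak] = []
    for p in sorted(peaks, key=lambda p: (p.mass, -p.intensity)):
        if out and p.mass == out[-1].mass:
            if p.intensity > out[-1].intensity:
                out[-1] = p
        else:
            out.append(p)
    return tuple(out)


@dataclass(frozen=True)
class Spectrum:
    """An MS/MS spectrum with its precursor header.

    Parameters
    ----------
    identifier
        Unique accession within a library.
    precursor_mass
        m/z of the precursor (or selected) ion, Da.
    ion_mode
        ``"positive"`` or ``"negative"``.
    peaks
        Fragment-ion peaks; stored strictly ascending in mass, exact
        duplicate masses merged keeping the larger intensity.
    compound_mass
        Neutral monoisotopic mass of the compound (structure-derived), if known.
    compound_id
        Ground-truth compound identity, used only for evaluation.
    """

    identifier: str
    precursor_mass: float
    ion_mode: str = "positive"
    peaks: tuple[Peak, ...] = ()
    compound_mass: float | None = None
    compound_id: str | None = None

    def __post_init__(self) -> None:
        if not self.precursor_mass > 0:
            raise ValueError("precursor_mass must be positive")
        if self.ion_mode not in ("positive", "negative"):
            raise ValueError(f"ion_mode must be 'positive' or 'negative', got {self.ion_mode!r}")
        object.__setattr__(self, "peaks", _normalize_peaks(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def masses(self) -> tuple[float, ...]:
        return tuple(p.mass for p in self.peaks)

    @property
    def intensities(self) -> tuple[float, ...]:
        return tuple(p.intensity for p in self.peaks)

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        return replace(self, peaks=tuple(peaks))


@dataclass
class SpectralLibrary:
    """An ordered collection of spectra with unique identifiers."""

    entries: list[Spectrum] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [s.identifier for s in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate identifiers in library {self.name!r}: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.entries)

    def __getitem__(self, identifier: str) -> Spectrum:
        for s in self.entries:
            if s.identifier == identifier:
                return s
        raise KeyError(identifier)


# ---------------------------------------------------------------------------
# MassBank record I/O
# ---------------------------------------------------------------------------
#
# The parser reads the minimal field set (ACCESSION, CH$NAME, CH$EXACT_MASS,
# AC$MASS_SPECTROMETRY: ION_MODE, MS$FOCUSED_ION: PRECURSOR_M/Z or BASE_PEAK,
# PK$NUM_PEAK, PK$PEAK) and ignores unknown tags, so records written by other
# tools with extra annotations still load.  Records are separated by "//".

_MB_PEAK_RE = re.compile(r"^\s*([0-9.eE+-]+)\s+([0-9.eE+-]+)(?:\s+[0-9.eE+-]+)?\s*$")


def _parse_massbank_record(lines: list[str], record_no: int) -> Spectrum:
    accession = None
    ion_mode = None
    precursor = None
    selected_ion = None
    compound_mass = None
    compound_id = None
    n_peaks_declared = None
    peaks: list[Peak] = []
    in_peaks = False
    for lineno, raw in lines:
        line = raw.rstrip()
        if in_peaks:
            if not line.strip():
                continue
            m = _MB_PEAK_RE.match(line)
            if m is None:
                if ":" in line:  # a new tag ends the peak table
                    in_peaks = False
                else:
                    raise SpectrumParseError(
                        f"record {accession or record_no}, line {lineno}: malformed peak line {line!r}"
                    )
            else:
                # columns: m/z, intensity[, rel.int.]; raw intensity wins over rel.int.
                peaks.append(Peak(float(m.group(1)), float(m.group(2))))
                continue
        if line.startswith("ACCESSION:"):
            accession = line.split(":", 1)[1].strip()
        elif line.startswith("CH$NAME:") and compound_id is None:
            compound_id = line.split(":", 1)[1].strip()
        elif line.startswith("CH$EXACT_MASS:"):
            compound_mass = float(line.split(":", 1)[1].strip())
        elif line.startswith("AC$MASS_SPECTROMETRY:"):
            body = line.split(":", 1)[1].strip()
            if body.upper().startswith("ION_MODE"):
                ion_mode = body.split(None, 1)[1].strip().lower()
        elif line.startswith("MS$FOCUSED_ION:"):
            body = line.split(":", 1)[1].strip()
            key, _, val = body.partition(" ")
            if key.upper() == "PRECURSOR_M/Z":
                precursor = float(val)
            elif key.upper() == "BASE_PEAK":
                selected_ion = float(val)
        elif line.startswith("PK$NUM_PEAK:"):
            n_peaks_declared = int(line.split(":", 1)[1].strip())
        elif line.startswith("PK$PEAK:"):
            in_peaks = True
    if accession is None:
        raise SpectrumParseError(f"record #{record_no}: missing ACCESSION")
    if precursor is None:
        # absent precursor ion: fall back to the selected (base-peak) ion mass
        precursor = selected_ion
    if precursor is None:
        raise SpectrumParseError(
            f"record {accession}: neither PRECURSOR_M/Z nor BASE_PEAK (selected ion) present"
        )
    if n_peaks_declared is not None and n_peaks_declared != len(peaks):
        raise SpectrumParseError(
            f"record {accession}: PK$NUM_PEAK declares {n_peaks_declared} peaks "
            f"but {len(peaks)} rows found"
        )
    mode = "positive" if (ion_mode or "positive").startswith("pos") else "negative"
    return Spectrum(
        identifier=accession,
        precursor_mass=precursor,
        ion_mode=mode,
        peaks=tuple(peaks),
        compound_mass=compound_mass,
        compound_id=compound_id,
    )


def read_massbank(path: str | Path, name: str | None = None) -> SpectralLibrary:
    """Read a MassBank record file (single record, or records joined by ``//``)."""
    path = Path(path)
    text = path.read_text()
    records: list[list] = [[]]
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if raw.strip() == "//":
            records.append([])
        else:
            records[-1].append((lineno, raw))
    entries = [
        _parse_massbank_record(rec, i)
        for i, rec in enumerate(records, start=1)
        if any(line.strip() for _, line in rec)
    ]
    if not entries:
        logger.warning("no records found in %s", path)
    return SpectralLibrary(entries=entries, name=name or path.stem)


def write_massbank(library: SpectralLibrary | Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as concatenated MassBank records (6-decimal masses)."""
    entries = library.entries if isinstance(library, SpectralLibrary) else list(library)
    lines: list[str] = []
    for s in entries:
        lines.append(f"ACCESSION: {s.identifier}")
        if s.compound_id is not None:
            lines.append(f"CH$NAME: {s.compound_id}")
        if s.compound_mass is not None:
            lines.append(f"CH$EXACT_MASS: {s.compound_mass:.6f}")
        lines.append(f"AC$MASS_SPECTROMETRY: ION_MODE {s.ion_mode.upper()}")
        lines.append(f"MS$FOCUSED_ION: PRECURSOR_M/Z {s.precursor_mass:.6f}")
        lines.append(f"PK$NUM_PEAK: {len(s.peaks)}")
        lines.append("PK$PEAK: m/z int. rel.int.")
        base = s.base_peak_intensity or 1.0
        for p in s.peaks:
            lines.append(f"  {p.mass:.6f} {p.intensity:.6f} {max(1, round(999 * p.intensity / base))}")
        lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MGF I/O (via pyteomics)
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path, name: str | None = None) -> SpectralLibrary:
    """Read an MGF file into a library (one spectrum per BEGIN IONS block)."""
    path = Path(path)
    entries: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
        for i, block in enumerate(reader, start=1):
            params = block.get("params", {})
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise SpectrumParseError(f"MGF block #{i} in {path}: missing PEPMASS")
            pepmass = float(params["pepmass"][0])
            title = str(params.get("title", f"{path.stem}_{i}"))
            charge = params.get("charge")
            mode = "positive"
            if charge:
                mode = "negative" if int(charge[0]) < 0 else "positive"
            compound_mass = params.get("exactmass")
            compound_id = params.get("compound_id")
            peaks = tuple(
                Peak(float(m), float(z))
                for m, z in zip(block["m/z array"], block["intensity array"])
            )
            entries.append(
                Spectrum(
                    identifier=title,
                    precursor_mass=pepmass,
                    ion_mode=mode,
                    peaks=peaks,
                    compound_mass=float(compound_mass) if compound_mass is not None else None,
                    compound_id=str(compound_id) if compound_id is not None else None,
                )
            )
    if not entries:
        logger.warning("empty MGF file: %s", path)
    return SpectralLibrary(entries=entries, name=name or path.stem)


def write_mgf(library: SpectralLibrary | Sequence[Spectrum], path: str | Path) -> None:
    entries = library.entries if isinstance(library, SpectralLibrary) else list(library)
    spectra = []
    for s in entries:
        params = {
            "title": s.identifier,
            "pepmass": s.precursor_mass,
            "charge": "1+" if s.ion_mode == "positive" else "1-",
        }
        if s.compound_mass is not None:
            params["exactmass"] = f"{s.compound_mass:.6f}"
        if s.compound_id is not None:
            params["compound_id"] = s.compound_id
        spectra.append(
            {
                "params": params,
                "m/z array": list(s.masses),
                "intensity array": list(s.intensities),
            }
        )
    _mgf.write(spectra, str(path), write_charges=True)


# ---------------------------------------------------------------------------
# Library inclusion filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.passed


def passes_library_filters(
    s: Spectrum,
    max_compound_mass: float = 1000.0,
    min_informative_peaks: int = 5,
    relative_intensity_threshold: float = 0.02,
) -> FilterResult:
    """Inclusion rules for building a homogeneous reference library.

    A spectrum passes when it is (d) in positive ion mode, (e) of a compound
    strictly below 1000 Da, and (f) has at least five peaks with relative
    intensity above 2% of the base peak.  When a structure-derived
    ``compound_mass`` is present, the precursor mass must additionally agree
    with it to 10 p.p.m. (assuming [M+H]+), which screens out low-resolution
    records.  The ``reason`` names the first failing rule.
    """
    if s.ion_mode != "positive":
        return FilterResult(False, "ion-mode")
    if s.compound_mass is not None:
        expected = s.compound_mass + PROTON_MASS
        if abs(s.precursor_mass - expected) > expected * 10e-6:
            return FilterResult(False, "precursor-structure-mass-mismatch")
        neutral = s.compound_mass
    else:
        neutral = s.precursor_mass - PROTON_MASS
    if not neutral < max_compound_mass:
        return FilterResult(False, "compound-mass")
    base = s.base_peak_intensity
    informative = sum(1 for p in s.peaks if base > 0 and p.intensity > relative_intensity_threshold * base)
    if informative < min_informative_peaks:
        return FilterResult(False, "min-informative-peaks")
    return FilterResult(True, "")


def filter_library(library: SpectralLibrary, **kwargs) -> tuple[SpectralLibrary, dict[str, str]]:
    """Apply :func:`passes_library_filters` to each entry; return kept library + rejection reasons."""
    kept, rejected = [], {}
    for s in library:
        res = passes_library_filters(s, **kwargs)
        if res:
            kept.append(s)
        else:
            rejected[s.identifier] = res.reason
    return SpectralLibrary(entries=kept, name=library.name), rejected


# ---------------------------------------------------------------------------
# Collision-energy merging
# ---------------------------------------------------------------------------

def merge_collision_energies(
    spectra: Sequence[Spectrum],
    ppm: float = DEFAULT_PPM,
    abs_da: float = DEFAULT_ABS_DA,
) -> Spectrum:
    """Merge spectra of one compound recorded at different collision energies.

    All peaks are pooled and clustered within ``max(ppm, abs_da)``; each
    cluster is represented by its most intense member (that member's mass and
    intensity).  Keeping the maximum rather than the sum preserves the
    relative-intensity profile that the informative-peak filter relies on.
    """
    if not spectra:
        raise ValueError("merge_collision_energies requires at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if s.compound_id != first.compound_id:
            raise ValueError(
                f"cannot merge spectra of different compounds: {first.compound_id!r} vs {s.compound_id!r}"
            )
        if abs(s.precursor_mass - first.precursor_mass) > first.precursor_mass * 10e-6:
            raise ValueError(
                f"precursor masses disagree beyond 10 p.p.m.: "
                f"{first.precursor_mass} vs {s.precursor_mass}"
            )
    pooled = sorted((p for s in spectra for p in s.peaks), key=lambda p: -p.intensity)
    accepted: list[Peak] = []
    for p in pooled:
        if not any(masses_match(p.mass, q.mass, ppm=ppm, abs_da=abs_da) for q in accepted):
            accepted.append(p)
    return first.with_peaks(accepted)
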