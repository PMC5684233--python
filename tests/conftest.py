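import numpy as np
import pytest

from specfdr import (
    BenchmarkBundle,
    FragmentationTree,
    MolecularFormula,
    Peak,
    SpectralLibrary,
    Spectrum,
    SyntheticLibrarySpec,
    generate_benchmark,
)


@pytest.fixture
def glucose_spectrum() -> Spectrum:
    """A glucose-like [M+H]+ spectrum whose fragments are water/CO losses."""
    f = MolecularFormula("C6H12O6")
    m = f.ion_mass
    h2o = MolecularFormula("H2O").monoisotopic_mass
    co = MolecularFormula("CO").monoisotopic_mass
    peaks = (
        Peak(m, 55.0),
        Peak(m - h2o, 100.0),
        Peak(m - 2 * h2o, 40.0),
        Peak(m - h2o - co, 30.0),
        Peak(m - 2 * h2o - co, 22.0),
        Peak(97.0, 1.0),  # unexplained noise
    )
    return Spectrum(
        identifier="GLC001",
        precursor_mass=m,
        ion_mode="positive",
        peaks=peaks,
        compound_mass=f.monoisotopic_mass,
        compound_id="glucose",
    )


@pytest.fixture
def chain_tree() -> FragmentationTree:
    """C6H12O6 -(H2O)-> C6H10O5 -(CO)-> C5H10O4 chain."""
    t = FragmentationTree.from_root(MolecularFormula("C6H12O6"), "GLC001")
    a = t.add_child(t.root, MolecularFormula("H2O"), peak_intensity=100.0)
    t.add_child(a, MolecularFormula("CO"), peak_intensity=30.0)
    return t


@pytest.fixture
def star_tree() -> FragmentationTree:
    """Root with four leaf children; every re-rooting is valid (n = 0 everywhere)."""
    t = FragmentationTree.from_root(MolecularFormula("C20H30N2O6"), "STAR")
    for loss in ("H2O", "CO", "NH3", "C2H4"):
        t.add_child(t.root, MolecularFormula(loss), peak_intensity=10.0)
    return t


@pytest.fixture(scope="session")
def small_bundle() -> BenchmarkBundle:
    """A 60-compound / 60-query benchmark shared across tests (seed fixed)."""
    return generate_benchmark(
        SyntheticLibrarySpec(n_compounds=60, n_queries=60, seed=11)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def toy_library(n: int = 6, seed: int = 5) -> SpectralLibrary:
    """Tiny deterministic library of hand-rolled spectra for decoy pool tests."""
    r = np.random.default_rng(seed)
    entries = []
    for i in range(n):
        prec = 200.0 + 50.0 * i
        masses = np.sort(r.uniform(60.0, prec - 5.0, size=7))
        peaks = tuple(Peak(float(m), float(r.uniform(5, 100))) for m in masses) + (
            Peak(prec, 50.0),
        )
        entries.append(
            Spectrum(identifier=f"T{i}", precursor_mass=prec, peaks=peaks,
                     compound_id=f"C{i}")
        )
    return SpectralLibrary(entries=entries, name="toy")


@pytest.fixture
def pool_library() -> SpectralLibrary:
    return toy_library()
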