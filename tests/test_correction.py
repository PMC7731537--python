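"""Natural-abundance correction: matrix construction, deconvolution, MPE."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcatrace import (
    FragmentSpec,
    IsotopeTable,
    MIDVector,
    U13C5_GLUTAMINE,
    build_correction_matrix,
    correct_mid,
    fraction_labeled,
    ideal_mid,
    mole_percent_enrichment,
)

SMALL_FRAG = FragmentSpec("toy", 2, {"C": 3, "H": 4, "O": 2, "Si": 1}, 100.0)


def brute_force_column(frag, isotopes, j, purity, n_rows):
    """Independent oracle: enumerate every isotope placement atom by atom.

    Expands the fragment into individual atoms, assigns each non-tracer
    atom its natural isotope options and each of the j tracer carbons a
    purity-weighted 13C/12C choice, and sums the probability of every
    combination by total mass offset. Exponential; fragments <= 12 atoms.
    """
    atoms = []
    for element, count in frag.composition.items():
        n_atoms = count - j if element == "C" else count
        atoms.extend([isotopes.elements[element]] * n_atoms)
    atoms.extend([[(0, 1.0 - purity), (1, purity)]] * j)
    spectrum = np.zeros(n_rows)
    for combo in itertools.product(*atoms):
        mass = sum(off for off, _ in combo)
        if mass < n_rows:
            spectrum[mass] += math.prod(ab for _, ab in combo)
    return spectrum


def test_no_heavy_isotopes_gives_identity():
    flat = IsotopeTable({el: [(0, 1.0)] for el in ("C", "H", "O", "Si")})
    matrix = build_correction_matrix(SMALL_FRAG, flat, tracer_purity=1.0)
    expected = np.zeros((5, 3))
    expected[:3, :3] = np.eye(3)
    assert np.allclose(matrix.matrix, expected)


def test_single_carbon_binomial_columns():
    p = 0.0107
    frag = FragmentSpec("one_carbon", 1, {"C": 1}, 50.0)
    matrix = build_correction_matrix(frag, tracer_purity=1.0).matrix
    assert matrix[:, 0] == pytest.approx([1 - p, p, 0, 0])
    assert matrix[:, 1] == pytest.approx([0, 1, 0, 0])


@pytest.mark.parametrize("purity", [1.0, 0.95])
def test_matrix_matches_brute_force_enumeration(isotopes, purity):
    """Per-element convolution equals exhaustive isotope-placement
    enumeration for a 10-atom fragment, at both purities."""
    matrix = build_correction_matrix(SMALL_FRAG, isotopes, purity).matrix
    for j in range(SMALL_FRAG.backbone_carbons + 1):
        oracle = brute_force_column(
            SMALL_FRAG, isotopes, j, purity, SMALL_FRAG.n_channels)
        assert np.allclose(matrix[:, j], oracle, atol=1e-12)


def test_pure_column_recovers_unlabeled(catalog):
    matrix = build_correction_matrix(catalog["glutamate"])
    raw = MIDVector("glutamate", matrix.matrix[:, 0])
    corrected = correct_mid(raw, matrix)
    assert corrected.values == pytest.approx([1, 0, 0, 0, 0, 0], abs=1e-10)


@given(f=st.floats(0.0, 1.0), seed=st.integers(0, 2**16))
@settings(deadline=None, max_examples=40)
def test_round_trip_exact_at_zero_noise(f, seed):
    """correct_mid inverts the forward convolution for any valid MID."""
    from tcatrace import load_fragment_catalog

    catalog = load_fragment_catalog()
    rng = np.random.default_rng(seed)
    frag = catalog["succinate"]
    x = rng.dirichlet(np.ones(frag.backbone_carbons + 1))
    matrix = build_correction_matrix(frag)
    corrected = correct_mid(MIDVector("succinate", matrix.matrix @ x), matrix)
    assert np.abs(corrected.values - x).max() < 1e-8


def test_noisy_round_trip_within_half_point(catalog, rng):
    """0.2%-of-total additive noise perturbs each corrected component by
    well under half a percentage point for a 4-carbon fragment."""
    frag = catalog["succinate"]
    matrix = build_correction_matrix(frag)
    x = ideal_mid(U13C5_GLUTAMINE, "succinate", 0.4)
    clean = matrix.matrix @ x
    errors = []
    for _ in range(50):
        noisy = np.clip(clean + rng.normal(0, 0.002, size=clean.shape), 0, None)
        recovered = correct_mid(MIDVector("succinate", noisy), matrix)
        errors.append(np.abs(recovered.values - x).max())
    assert np.median(errors) < 0.005


def test_correction_scale_invariant(catalog, rng):
    frag = catalog["malate"]
    matrix = build_correction_matrix(frag)
    raw = matrix.matrix @ ideal_mid(U13C5_GLUTAMINE, "malate", 0.3) + 1e-4
    a = correct_mid(MIDVector("malate", raw), matrix)
    b = correct_mid(MIDVector("malate", raw * 7.3e5), matrix)
    assert np.allclose(a.values, b.values, atol=1e-12)


def test_mole_percent_enrichment_examples():
    assert mole_percent_enrichment(
        MIDVector("x", [1, 0, 0, 0, 0], kind="corrected")) == 0.0
    assert mole_percent_enrichment(
        MIDVector("x", [0, 0, 0, 0, 1], kind="corrected")) == 1.0
    citrate = np.zeros(7)
    citrate[0], citrate[4] = 0.98, 0.02
    mid = MIDVector("citrate", citrate, kind="corrected")
    assert mole_percent_enrichment(mid) == pytest.approx(0.02 * 4 / 6)
    assert fraction_labeled(mid) == pytest.approx(0.02)


def test_mpe_monotone_in_labeled_channels(rng):
    base = np.array([0.9, 0.04, 0.03, 0.02, 0.01])
    for i in range(1, 5):
        bumped = base.copy()
        bumped[i] += 0.05
        bumped[0] -= 0.05
        assert (
            mole_percent_enrichment(MIDVector("x", bumped, kind="corrected"))
            > mole_percent_enrichment(MIDVector("x", base, kind="corrected"))
        )


def test_error_conditions(catalog, isotopes):
    matrix = build_correction_matrix(catalog["fumarate"])
    with pytest.raises(ValueError, match="all-zero"):
        correct_mid(MIDVector("fumarate", np.zeros(7)), matrix)
    with pytest.raises(ValueError, match="channels"):
        correct_mid(MIDVector("fumarate", np.ones(4)), matrix)
    with pytest.raises(KeyError, match="missing from isotope table"):
        build_correction_matrix(
            FragmentSpec("p_frag", 2, {"C": 2, "P": 1}, 10.0), isotopes)
    with pytest.raises(ValueError, match="backbone"):
        FragmentSpec("bad", 5, {"C": 3}, 10.0)
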