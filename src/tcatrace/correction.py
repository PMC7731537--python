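"""Natural-abundance correction of GC-MS SIM mass isotopomer distributions.

Raw SIM intensities of a derivatized fragment mix tracer-derived labeling
with naturally occurring heavy isotopes of every atom in the fragment —
including the Si-rich TBDMS derivatization groups, whose 29/30Si
contributions are large. SIM monitors channels M0..M(n+2), two mass units
above the backbone carbon count n, so those heavy-atom tails are observed
and can be deconvolved.

The correction solves the linear system  A x = raw,  where column j of A
is the theoretical measured spectrum of a molecule carrying exactly j
tracer 13C atoms on its backbone: the convolution of (a) the
natural-abundance mass distribution of every atom except the j labeled
carbons and (b) the binomial isotopic-purity distribution of those j
carbons, truncated to the monitored channels. x is recovered by
nonnegativity-constrained least squares, truncated to M0..Mn and
renormalized; negative isotopologue fractions on noisy data are thereby
impossible by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import nnls

__all__ = [
    "IsotopeTable",
    "FragmentSpec",
    "MIDVector",
    "CorrectionMatrix",
    "load_fragment_catalog",
    "natural_abundance_distribution",
    "build_correction_matrix",
    "correct_mid",
    "mole_percent_enrichment",
    "fraction_labeled",
]

EXTRA_CHANNELS = 2  # SIM monitors up to m+2 above the backbone carbon count


class IsotopeTable:
    """Per-element natural-abundance mass distributions.

    Each element maps to a list of ``(mass offset, abundance)`` pairs;
    abundances must sum to 1 within 1e-9.
    """

    def __init__(self, elements: dict[str, list[tuple[int, float]]]) -> None:
        self.elements = {
            el: [(int(off), float(ab)) for off, ab in pairs]
            for el, pairs in elements.items()
        }
        for el, pairs in self.elements.items():
            total = sum(ab for _, ab in pairs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"abundances for {el} sum to {total}, expected 1"
                )

    @classmethod
    def default(cls) -> "IsotopeTable":
        source = resources.files("tcatrace.data").joinpath("isotopes.yaml")
        raw = yaml.safe_load(source.read_text())
        return cls(raw["elements"])

    @classmethod
    def from_file(cls, path) -> "IsotopeTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw["elements"])

    def atom_distribution(self, element: str) -> np.ndarray:
        if element not in self.elements:
            raise KeyError(f"element {element!r} missing from isotope table")
        pairs = self.elements[element]
        dist = np.zeros(max(off for off, _ in pairs) + 1)
        for off, ab in pairs:
            dist[off] += ab
        return dist


@dataclass(frozen=True)
class FragmentSpec:
    """A derivatized metabolite fragment monitored in SIM mode."""

    metabolite: str
    backbone_carbons: int
    composition: dict[str, int]
    m0_mz: float

    def __post_init__(self) -> None:
        if self.composition.get("C", 0) < self.backbone_carbons:
            raise ValueError(
                f"{self.metabolite}: fragment carbons "
                f"{self.composition.get('C', 0)} < backbone {self.backbone_carbons}"
            )
        if self.m0_mz <= 0:
            raise ValueError(f"{self.metabolite}: m0_mz must be positive")

    @property
    def n_channels(self) -> int:
        return self.backbone_carbons + EXTRA_CHANNELS + 1


def load_fragment_catalog(path=None) -> dict[str, FragmentSpec]:
    """Load a fragment catalog; defaults to the shipped TBDMS example set."""
    if path is None:
        source = resources.files("tcatrace.data").joinpath("fragments.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {
        name: FragmentSpec(
            metabolite=name,
            backbone_carbons=int(entry["backbone_carbons"]),
            composition={k: int(v) for k, v in entry["composition"].items()},
            m0_mz=float(entry["m0_mz"]),
        )
        for name, entry in raw["fragments"].items()
    }


@dataclass
class MIDVector:
    """A mass isotopomer distribution (raw or corrected) for one fragment."""

    metabolite: str
    values: np.ndarray
    kind: str = "raw"  # "raw" | "corrected"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("MID values must be a 1-D vector")
        if np.any(self.values < -1e-12):
            raise ValueError(f"{self.metabolite}: negative MID entries")
        if self.kind == "corrected":
            total = float(self.values.sum())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.metabolite}: corrected MID sums to {total}"
                )

    @property
    def n_backbone(self) -> int:
        if self.kind == "corrected":
            return len(self.values) - 1
        return len(self.values) - EXTRA_CHANNELS - 1


@dataclass
class CorrectionMatrix:
    """Columns = theoretical measured spectra of j-labeled molecules."""

    fragment: FragmentSpec
    matrix: np.ndarray  # (n+3, n+1)
    tracer_purity: float

    def __post_init__(self) -> None:
        if np.any(self.matrix < 0):
            raise ValueError("correction matrix has negative entries")


def _self_convolve(dist: np.ndarray, count: int, max_len: int) -> np.ndarray:
    out = np.array([1.0])
    for _ in range(count):
        out = np.convolve(out, dist)[:max_len]
    return out


def natural_abundance_distribution(
    composition: dict[str, int],
    isotopes: IsotopeTable,
    max_offset: int,
) -> np.ndarray:
    """Mass distribution (offsets 0..max_offset) of a composition at
    natural abundance, by per-element convolution."""
    out = np.array([1.0])
    max_len = max_offset + 1
    for element, count in composition.items():
        if count < 0:
            raise ValueError(f"negative atom count for {element}")
        if count == 0:
            continue
        out = np.convolve(out, _self_convolve(
            isotopes.atom_distribution(element), count, max_len))[:max_len]
    full = np.zeros(max_len)
    full[: len(out)] = out
    return full


def build_correction_matrix(
    frag: FragmentSpec,
    isotopes: IsotopeTable | None = None,
    tracer_purity: float = 0.99,
) -> CorrectionMatrix:
    """Correction matrix for ``frag`` at the given tracer isotopic purity.

    Column j (j = 0..n backbone carbons) is the spectrum of a molecule
    with exactly j backbone carbons drawn from the tracer: the remaining
    atoms (including the n-j unlabeled backbone carbons and all
    derivatization atoms) contribute natural abundance, and each of the
    j tracer carbons is 13C with probability ``tracer_purity``. Rows are
    the monitored channels M0..M(n+2); column mass beyond M(n+2) is
    truncated, so columns sum to slightly less than 1.
    """
    if not 0.0 < tracer_purity <= 1.0:
        raise ValueError(f"tracer purity {tracer_purity} outside (0, 1]")
    if isotopes is None:
        isotopes = IsotopeTable.default()
    n = frag.backbone_carbons
    n_rows = frag.n_channels
    cols = []
    for j in range(n + 1):
        remaining = dict(frag.composition)
        remaining["C"] = remaining["C"] - j
        na = natural_abundance_distribution(remaining, isotopes, n_rows - 1)
        purity = np.array(
            [math.comb(j, k) * tracer_purity**k * (1 - tracer_purity) ** (j - k)
             for k in range(j + 1)]
        )
        col = np.convolve(na, purity)[:n_rows]
        full = np.zeros(n_rows)
        full[: len(col)] = col
        cols.append(full)
    return CorrectionMatrix(frag, np.column_stack(cols), tracer_purity)


def correct_mid(raw: MIDVector, matrix: CorrectionMatrix) -> MIDVector:
    """Natural-abundance-correct a raw MID (or raw SIM intensities).

    Solves ``matrix @ x ~= raw`` by nonnegative least squares, truncates
    to M0..Mn and renormalizes to sum 1. Invariant to uniform scaling of
    the raw intensities.
    """
    A = matrix.matrix
    b = np.asarray(raw.values, dtype=float)
    if len(b) != A.shape[0]:
        raise ValueError(
            f"{raw.metabolite}: raw MID has {len(b)} channels, "
            f"matrix expects {A.shape[0]}"
        )
    total = b.sum()
    if total <= 0:
        raise ValueError(f"{raw.metabolite}: all-zero raw intensity vector")
    if np.linalg.cond(A) > 1e8:
        raise ValueError(
            f"{raw.metabolite}: ill-conditioned correction matrix "
            "(check the fragment composition)"
        )
    x, _ = nnls(A, b / total)
    s = x.sum()
    if s <= 0:
        raise ValueError(f"{raw.metabolite}: correction yielded a zero MID")
    return MIDVector(raw.metabolite, x / s, kind="corrected")


def mole_percent_enrichment(corrected: MIDVector) -> float:
    """Carbon-weighted average fractional 13C labeling of the backbone.

    MPE = sum_i i * M_i / n, the average fraction of backbone carbons
    carrying tracer 13C; 0 for unlabeled material, 1 when every molecule
    is fully labeled.
    """
    v = np.asarray(corrected.values, dtype=float)
    n = len(v) - 1
    if n < 1:
        raise ValueError("MID needs at least two channels")
    i = np.arange(len(v))
    return float((i * v).sum() / n)


def fraction_labeled(corrected: MIDVector) -> float:
    """Fraction of molecules carrying at least one tracer carbon."""
    v = np.asarray(corrected.values, dtype=float)
    return float(v[1:].sum())
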