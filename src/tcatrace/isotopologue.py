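"""Positional carbon tracking of a glutamine tracer through the first
oxidative turn of the TCA cycle.

The model follows the anaplerotic route glutamine -> glutamate ->
alpha-ketoglutarate -> succinate -> fumarate -> malate -> oxaloacetate,
branching from oxaloacetate to aspartate (transamination) and to citrate
(condensation with acetyl-CoA, treated as unlabeled in the first turn).
Only the first turn, oxidative direction, is modeled: reductive
carboxylation and second-turn isotopomers are out of scope.

Carbon fates are encoded as explicit atom maps (see
``data/atom_maps.yaml``).  Succinate and fumarate are symmetric: the two
molecular orientations cannot be distinguished chemically, so label
states are carried as an equiprobable mixture over both orientations.
The nominal mass shift (number of tracer carbons retained) is invariant
under that flip; positional queries remain well-defined.

A uniformly labeled [13C5]-glutamine tracer yields m+5 glutamate and
alpha-ketoglutarate and m+4 succinate, fumarate, malate, aspartate and
citrate (one carbon is lost as CO2 at the alpha-ketoglutarate
dehydrogenase step); a [5-13C] tracer yields m+1 everywhere because C5
survives the decarboxylation of C1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "TracerSpec",
    "LabelState",
    "AtomMap",
    "PathwayModel",
    "U13C5_GLUTAMINE",
    "C5_GLUTAMINE",
    "propagate_first_turn",
    "positional_states",
    "ideal_mid",
]

GLUTAMINE_CARBONS = 5


@dataclass(frozen=True)
class TracerSpec:
    """A 13C-glutamine tracer.

    Parameters
    ----------
    name:
        Display name, e.g. ``"[U-13C5]glutamine"``.
    labeled_positions:
        1-based glutamine carbon indices carrying 13C (subset of 1..5).
    enrichment:
        Tracer fraction of the plasma glutamine pool (the plateau
        enrichment e, typically 0.03-0.10 in vivo).
    """

    name: str
    labeled_positions: frozenset[int]
    enrichment: float = 0.05

    def __post_init__(self) -> None:
        positions = frozenset(self.labeled_positions)
        object.__setattr__(self, "labeled_positions", positions)
        bad = positions - set(range(1, GLUTAMINE_CARBONS + 1))
        if bad:
            raise ValueError(
                f"tracer positions {sorted(bad)} outside glutamine C1-C5"
            )
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError(f"enrichment {self.enrichment} outside [0, 1]")

    @property
    def n_labels(self) -> int:
        return len(self.labeled_positions)

    def initial_state(self) -> "LabelState":
        positions = tuple(
            i + 1 in self.labeled_positions for i in range(GLUTAMINE_CARBONS)
        )
        return LabelState("glutamine", positions)


U13C5_GLUTAMINE = TracerSpec("[U-13C5]glutamine", frozenset({1, 2, 3, 4, 5}))
C5_GLUTAMINE = TracerSpec("[5-13C]glutamine", frozenset({5}))


@dataclass(frozen=True)
class LabelState:
    """Positional labeling of one molecule: a boolean per backbone carbon."""

    metabolite: str
    positions: tuple[bool, ...]

    @property
    def mass_shift(self) -> int:
        return int(sum(self.positions))

    def reversed_orientation(self) -> "LabelState":
        return LabelState(self.metabolite, self.positions[::-1])


@dataclass(frozen=True)
class AtomMap:
    """Carbon fate map for one reaction.

    ``mapping`` sends 1-based substrate carbon indices to product carbon
    indices; ``lost_carbons`` are substrate carbons released (CO2).
    Product carbons without a source (citrate's acetyl-CoA carbons) are
    unlabeled in the first turn.
    """

    reaction: str
    substrate: str
    product: str
    mapping: Mapping[int, int]
    lost_carbons: frozenset[int] = frozenset()

    def validate(self, n_substrate: int, n_product: int) -> None:
        destinations = list(self.mapping.values())
        if len(destinations) != len(set(destinations)):
            raise ValueError(f"{self.reaction}: duplicate destination carbon")
        if set(self.mapping) & self.lost_carbons:
            raise ValueError(f"{self.reaction}: lost carbon also mapped")
        if any(not 1 <= s <= n_substrate for s in self.mapping):
            raise ValueError(f"{self.reaction}: substrate index out of range")
        if any(not 1 <= d <= n_product for d in destinations):
            raise ValueError(f"{self.reaction}: product index out of range")

    def apply(self, state: LabelState, n_product: int) -> LabelState:
        out = [False] * n_product
        for src, dst in self.mapping.items():
            out[dst - 1] = state.positions[src - 1]
        return LabelState(self.product, tuple(out))


class PathwayModel:
    """First-turn TCA pathway assembled from a plain-text atom-map config."""

    def __init__(
        self,
        metabolites: Mapping[str, dict],
        reactions: list[AtomMap],
    ) -> None:
        self.carbons = {m: int(v["carbons"]) for m, v in metabolites.items()}
        self.symmetric = {
            m for m, v in metabolites.items() if v.get("symmetric", False)
        }
        self.reactions = list(reactions)
        for rxn in self.reactions:
            for side in (rxn.substrate, rxn.product):
                if side not in self.carbons:
                    raise ValueError(f"{rxn.reaction}: unknown metabolite {side!r}")
            rxn.validate(self.carbons[rxn.substrate], self.carbons[rxn.product])

    @classmethod
    def from_config(cls, path=None) -> "PathwayModel":
        if path is None:
            source = resources.files("tcatrace.data").joinpath("atom_maps.yaml")
            raw = yaml.safe_load(source.read_text())
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        reactions = [
            AtomMap(
                reaction=r["name"],
                substrate=r["substrate"],
                product=r["product"],
                mapping={int(k): int(v) for k, v in r["map"].items()},
                lost_carbons=frozenset(r.get("lost_carbons", [])),
            )
            for r in raw["reactions"]
        ]
        return cls(raw["metabolites"], reactions)

    def positional_states(
        self, tracer: TracerSpec
    ) -> dict[str, list[tuple[float, LabelState]]]:
        """Propagate the tracer; return per-metabolite weighted label states.

        Symmetric metabolites (succinate, fumarate) carry both molecular
        orientations at probability 1/2 each; the mixture is propagated
        downstream so malate and beyond inherit the scrambling.
        """
        states: dict[str, list[tuple[float, LabelState]]] = {
            "glutamine": [(1.0, tracer.initial_state())]
        }
        for rxn in self.reactions:
            if rxn.substrate not in states:
                raise ValueError(
                    f"{rxn.reaction}: substrate {rxn.substrate!r} not yet produced; "
                    "reactions must be listed in pathway order"
                )
            n_prod = self.carbons[rxn.product]
            produced = [
                (w, rxn.apply(s, n_prod)) for w, s in states[rxn.substrate]
            ]
            if rxn.product in self.symmetric:
                produced = [
                    half
                    for w, s in produced
                    for half in ((w / 2, s), (w / 2, s.reversed_orientation()))
                ]
            states[rxn.product] = _merge_states(produced)
        return states

    def mass_shifts(self, tracer: TracerSpec) -> dict[str, int]:
        """Nominal first-turn mass shift per metabolite.

        The shift (count of tracer carbons retained) must be identical
        across all positional states of a metabolite — orientation flips
        of symmetric molecules change positions, never mass.
        """
        shifts: dict[str, int] = {}
        for met, weighted in self.positional_states(tracer).items():
            if met == "glutamine":
                continue
            unique = {s.mass_shift for _, s in weighted}
            if len(unique) != 1:  # cannot happen with valid atom maps
                raise RuntimeError(f"ambiguous mass shift for {met}: {unique}")
            shifts[met] = unique.pop()
        return shifts


def _merge_states(
    weighted: list[tuple[float, LabelState]]
) -> list[tuple[float, LabelState]]:
    merged: dict[LabelState, float] = {}
    for w, s in weighted:
        merged[s] = merged.get(s, 0.0) + w
    return [(w, s) for s, w in merged.items()]


_DEFAULT_MODEL: PathwayModel | None = None


def default_pathway() -> PathwayModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = PathwayModel.from_config()
    return _DEFAULT_MODEL


def propagate_first_turn(
    tracer: TracerSpec, pathway: PathwayModel | None = None
) -> dict[str, int]:
    """Expected nominal mass shift of each first-turn TCA intermediate.

    For [U-13C5]glutamine this is 5 for glutamate/alpha-ketoglutarate and
    4 for succinate, fumarate, malate, aspartate and citrate; for
    [5-13C]glutamine it is 1 throughout.
    """
    model = pathway or default_pathway()
    return model.mass_shifts(tracer)


def positional_states(
    tracer: TracerSpec, pathway: PathwayModel | None = None
) -> dict[str, list[tuple[float, LabelState]]]:
    model = pathway or default_pathway()
    return model.positional_states(tracer)


def ideal_mid(
    tracer: TracerSpec,
    metabolite: str,
    anaplerotic_fraction: float,
    pathway: PathwayModel | None = None,
) -> np.ndarray:
    """Idealized first-turn MID of ``metabolite`` (length n_carbons + 1).

    Two-component mixture: a fraction f of the metabolite pool turned
    over from plasma glutamine (of which a fraction e is tracer, fully
    shifted by the first-turn mass shift) and the remainder unlabeled:

        MID = (1 - f*e) * M0  +  f*e * M_shift

    where e is the tracer's plasma enrichment. This is the forward model
    the synthetic cohort generator samples from.
    """
    if not 0.0 <= anaplerotic_fraction <= 1.0:
        raise ValueError(
            f"anaplerotic fraction {anaplerotic_fraction} outside [0, 1]"
        )
    model = pathway or default_pathway()
    if metabolite not in model.carbons:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    shifts = model.mass_shifts(tracer)
    if metabolite == "glutamine":
        shift = tracer.n_labels
    else:
        shift = shifts[metabolite]
    n = model.carbons[metabolite]
    mid = np.zeros(n + 1)
    labeled = anaplerotic_fraction * tracer.enrichment
    mid[0] = 1.0 - labeled
    mid[shift] += labeled
    return mid
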