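"""Marker panel layout: which marker is imaged in which round and channel.

A cyclic-immunofluorescence experiment stains a specimen in successive
rounds; each round contributes a small set of markers imaged in spectrally
distinct fluorophore channels alongside a DAPI nuclear counterstain.  A
"round 0" acquisition taken before any staining records per-cell
autofluorescence.  The :class:`RoundLayout` maps every marker to its
(round, channel) slot, the subcellular compartment used for phenotyping,
and its biological category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import LayoutError

#: Markers whose joint positivity with CD45 defines a hybrid cell.
EPITHELIAL_COCKTAIL = ("ECAD", "EpCAM", "panCK")

#: Pan-leukocyte marker required for a hybrid call.
LEUKOCYTE_MARKER = "CD45"

#: Markers used for co-expression gating.
GATING_MARKERS = (LEUKOCYTE_MARKER,) + EPITHELIAL_COCKTAIL

COMPARTMENTS = ("whole_cell", "nucleus", "cytoplasm")
CATEGORIES = ("tumor", "immune", "stromal", "signaling", "functional")


@dataclass(frozen=True)
class MarkerSpec:
    """Placement and interpretation of a single marker."""

    name: str
    round: int
    channel: str
    compartment: str = "whole_cell"
    category: str = "tumor"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise LayoutError(f"unknown compartment {self.compartment!r}")
        if self.category not in CATEGORIES:
            raise LayoutError(f"unknown category {self.category!r}")
        if self.round < 1:
            raise LayoutError("marker rounds start at 1 (round 0 is background)")


@dataclass
class RoundLayout:
    """Panel layout: marker -> (round, channel, compartment, category).

    Parameters
    ----------
    markers
        Marker specs in panel order.  (round, channel) pairs must be unique.
    nuclear_channel
        Channel name of the nuclear counterstain, present in every round.
    background_round, background_channel
        Round id and channel of the pre-staining autofluorescence scan.
    """

    markers: list[MarkerSpec] = field(default_factory=list)
    nuclear_channel: str = "DAPI"
    background_round: int = 0
    background_channel: str = "background"

    def __post_init__(self) -> None:
        self.validate()

    # -- views -------------------------------------------------------------
    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def rounds(self) -> list[int]:
        return sorted({m.round for m in self.markers})

    def __getitem__(self, name: str) -> MarkerSpec:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(m.name == name for m in self.markers)

    def markers_in_round(self, round_id: int) -> list[MarkerSpec]:
        return [m for m in self.markers if m.round == round_id]

    def channels_in_round(self, round_id: int) -> list[str]:
        """Channel order of the stack for one round (DAPI first)."""
        if round_id == self.background_round:
            return [self.nuclear_channel, self.background_channel]
        return [self.nuclear_channel] + [m.channel for m in self.markers_in_round(round_id)]

    def compartment_of(self, name: str) -> str:
        return self[name].compartment

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        names = self.marker_names
        if len(set(names)) != len(names):
            raise LayoutError("duplicate marker names")
        slots = [(m.round, m.channel) for m in self.markers]
        if len(set(slots)) != len(slots):
            raise LayoutError("duplicate (round, channel) slots")
        for m in self.markers:
            if m.channel == self.nuclear_channel:
                raise LayoutError(f"marker {m.name} collides with the nuclear channel")
        missing = [g for g in GATING_MARKERS if g not in names]
        if missing:
            raise LayoutError(f"gating markers missing from panel: {missing}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nuclear_channel": self.nuclear_channel,
            "background_round": self.background_round,
            "background_channel": self.background_channel,
            "markers": [
                {
                    "name": m.name,
                    "round": m.round,
                    "channel": m.channel,
                    "compartment": m.compartment,
                    "category": m.category,
                }
                for m in self.markers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoundLayout":
        return cls(
            markers=[MarkerSpec(**m) for m in d["markers"]],
            nuclear_channel=d.get("nuclear_channel", "DAPI"),
            background_round=d.get("background_round", 0),
            background_channel=d.get("background_channel", "background"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RoundLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_layout() -> RoundLayout:
    """The 14-marker / 4-round hybrid-cell phenotyping panel.

    Round 1 carries the gating markers (epithelial cocktail + CD45); rounds
    2-4 carry the phenotyping markers.  Compartment is whole-cell for all
    markers except the nuclear proliferation marker Ki67.
    """
    spec = [
        # name,   round, channel, compartment, category
        ("ECAD", 1, "AF488", "whole_cell", "tumor"),
        ("EpCAM", 1, "AF546", "whole_cell", "tumor"),
        ("panCK", 1, "AF647", "whole_cell", "tumor"),
        ("CD45", 1, "AF750", "whole_cell", "immune"),
        ("CK19", 2, "AF488", "whole_cell", "tumor"),
        ("Ki67", 2, "AF546", "nucleus", "functional"),
        ("pAKT", 2, "AF647", "whole_cell", "signaling"),
        ("CD44", 2, "AF750", "whole_cell", "functional"),
        ("CK8", 3, "AF546", "whole_cell", "tumor"),
        ("VIM", 3, "AF647", "whole_cell", "stromal"),
        ("EGFR", 3, "AF750", "whole_cell", "signaling"),
        ("CK7", 4, "AF546", "whole_cell", "tumor"),
        ("aSMA", 4, "AF647", "whole_cell", "stromal"),
        ("VWF", 4, "AF750", "whole_cell", "stromal"),
    ]
    return RoundLayout(markers=[MarkerSpec(*s) for s in spec])
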