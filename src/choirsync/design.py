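"""Study-design model for an ensemble-singing hyperscanning experiment.

The design is a lattice of voices x pieces x recording units x blocks x
spatial conditions.  Pieces are grouped into recording units (a unit is a
>= 6-minute concatenation of pieces, e.g. three repetitions of an Agnus
section); each block is one performance of one recording unit, repeated
under every spatial condition.  All downstream observation counts (how many
audio files, how many piece-level accuracy rows, how many respiration grid
points, ...) are derived from this object, so every analysis table can be
validated against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Piece",
    "StudyDesign",
    "ObservationLevel",
    "DesignValidationError",
    "enumerate_recordings",
    "observation_count",
    "default_design",
    "tiny_design",
]


class DesignValidationError(ValueError):
    """Raised when a study design is internally inconsistent."""


@dataclass(frozen=True)
class Piece:
    """One musical piece, its recording unit, and per-voice repeat counts.

    ``repeats_per_voice[v]`` is the number of repeated audio recordings of
    this piece for voice ``v`` in *each* spatial condition.  A voice that
    does not take part in a piece (e.g. a two-voice section) simply has a
    repeat count of zero; no counting rule special-cases it.
    """

    name: str
    unit: str
    repeats_per_voice: dict[str, int]


class ObservationLevel(str, Enum):
    """Aggregation level of an analysis table, each with a unique counting rule."""

    AUDIO_FILE = "audio_file"
    PIECE = "piece"
    RECORDING_UNIT = "recording_unit"
    BLOCK_VOICE_MEAN = "block_voice_mean"
    RESPIRATION_GRID = "respiration_grid"


@dataclass(frozen=True)
class StudyDesign:
    voices: tuple[str, ...]
    conditions: tuple[str, ...]
    pieces: tuple[Piece, ...]
    blocks: tuple[str, ...]  # ordered recording-unit labels, one per block
    singers_per_voice: int = 2
    n_frequency_components: int = 10

    def __post_init__(self) -> None:
        self.validate()

    # -- basic derived quantities ------------------------------------------
    @property
    def n_singers(self) -> int:
        return len(self.voices) * self.singers_per_voice

    @property
    def singers(self) -> tuple[str, ...]:
        return tuple(
            f"{v}_{i}" for v in self.voices for i in range(1, self.singers_per_voice + 1)
        )

    @property
    def recording_units(self) -> tuple[str, ...]:
        """Distinct unit labels in first-appearance (block) order."""
        seen: list[str] = []
        for u in self.blocks:
            if u not in seen:
                seen.append(u)
        return tuple(seen)

    def unit_repeat_counts(self) -> dict[str, int]:
        """How many blocks perform each recording unit."""
        out: dict[str, int] = {}
        for u in self.blocks:
            out[u] = out.get(u, 0) + 1
        return out

    def voice_repeat_totals(self) -> dict[str, int]:
        """Per-voice repeat sums over pieces (the printed column sums)."""
        return {
            v: sum(p.repeats_per_voice.get(v, 0) for p in self.pieces)
            for v in self.voices
        }

    def blocks_of_unit(self, unit: str) -> list[int]:
        return [i for i, u in enumerate(self.blocks) if u == unit]

    def voice_of(self, singer: str) -> str:
        voice = singer.rsplit("_", 1)[0]
        if voice not in self.voices:
            raise KeyError(f"unknown singer label {singer!r}")
        return voice

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if not self.voices or not self.conditions or not self.pieces or not self.blocks:
            raise DesignValidationError("voices, conditions, pieces, blocks must be non-empty")
        if self.singers_per_voice < 1:
            raise DesignValidationError("singers_per_voice must be >= 1")
        piece_names = [p.name for p in self.pieces]
        if len(set(piece_names)) != len(piece_names):
            raise DesignValidationError("duplicate piece names")
        units_of_pieces = {p.unit for p in self.pieces}
        units_of_blocks = set(self.blocks)
        if units_of_pieces != units_of_blocks:
            raise DesignValidationError(
                f"recording units of pieces {sorted(units_of_pieces)} do not match "
                f"units performed in blocks {sorted(units_of_blocks)}"
            )
        for p in self.pieces:
            unknown = set(p.repeats_per_voice) - set(self.voices)
            if unknown:
                raise DesignValidationError(f"piece {p.name!r} names unknown voices {unknown}")
            if any(r < 0 for r in p.repeats_per_voice.values()):
                raise DesignValidationError(f"piece {p.name!r} has negative repeat counts")
            # each piece's repeats must be coverable by its unit's blocks
            if self.unit_repeat_counts()[p.unit] == 0:
                raise DesignValidationError(f"unit {p.unit!r} never performed")

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        return cls(
            voices=tuple(d["voices"]),
            conditions=tuple(d["conditions"]),
            pieces=tuple(
                Piece(p["name"], p["unit"], dict(p["repeats_per_voice"])) for p in d["pieces"]
            ),
            blocks=tuple(d["blocks"]),
            singers_per_voice=int(d.get("singers_per_voice", 2)),
            n_frequency_components=int(d.get("n_frequency_components", 10)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "voices": list(self.voices),
            "singers_per_voice": self.singers_per_voice,
            "conditions": list(self.conditions),
            "n_frequency_components": self.n_frequency_components,
            "pieces": [
                {"name": p.name, "unit": p.unit, "repeats_per_voice": p.repeats_per_voice}
                for p in self.pieces
            ],
            "blocks": list(self.blocks),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def default_design() -> StudyDesign:
    """The full study layout: 4 voices x 8 pieces x 3 units x 8 blocks x 3 conditions."""
    with resources.files("choirsync.data").joinpath("default_design.json").open() as fh:
        return StudyDesign.from_dict(json.load(fh))


def tiny_design(
    n_voices: int = 4,
    conditions: Sequence[str] = ("touch", "no_touch"),
    blocks_per_unit: int = 1,
) -> StudyDesign:
    """A deliberately small design for fast tests: 2 units, 4 pieces, few repeats."""
    voices = ("soprano", "altus", "tenor", "bassus")[:n_voices]
    pieces = (
        Piece("p1", "u1", {v: 2 for v in voices}),
        Piece("p2", "u1", {v: 1 for v in voices}),
        Piece("p3", "u2", {v: 2 for v in voices}),
        Piece("p4", "u2", {v: 1 for v in voices}),
    )
    blocks = tuple(["u1"] * blocks_per_unit + ["u2"] * blocks_per_unit)
    return StudyDesign(
        voices=voices, conditions=tuple(conditions), pieces=pieces, blocks=blocks
    )


# ---------------------------------------------------------------------------
# enumeration and counting


def _block_assignment(design: StudyDesign, piece: Piece, n_repeats: int) -> list[int]:
    """Assign the repeats of a piece (within one condition) to the blocks of
    its unit, round-robin so uneven counts (e.g. 4 repeats over 3 blocks)
    spread as evenly as possible, earlier blocks taking the extra."""
    blocks = design.blocks_of_unit(piece.unit)
    return [blocks[i % len(blocks)] for i in range(n_repeats)]


def enumerate_recordings(design: StudyDesign) -> pd.DataFrame:
    """One row per audio file: (piece, unit, voice, singer, condition, block, repeat).

    The row count equals sum over voices of total repeats x singers_per_voice
    x number of conditions (672 for the default design).
    """
    design.validate()
    rows = []
    for piece in design.pieces:
        for voice in design.voices:
            n_rep = piece.repeats_per_voice.get(voice, 0)
            block_of_rep = _block_assignment(design, piece, n_rep)
            for rep in range(n_rep):
                for cond in design.conditions:
                    for s in range(1, design.singers_per_voice + 1):
                        rows.append(
                            {
                                "piece": piece.name,
                                "unit": piece.unit,
                                "voice": voice,
                                "singer": f"{voice}_{s}",
                                "condition": cond,
                                "block": block_of_rep[rep],
                                "repeat": rep,
                            }
                        )
    cols = ["piece", "unit", "voice", "singer", "condition", "block", "repeat"]
    return pd.DataFrame(rows, columns=cols)


def observation_count(
    design: StudyDesign,
    level: ObservationLevel | str,
    conditions: Iterable[str] | None = None,
) -> int:
    """Closed-form count of analysis rows at a given aggregation level.

    ``conditions`` restricts to a subset of spatial conditions (default: all).
    ``block_voice_mean`` counts paired block x voice cells and therefore does
    not multiply by the number of conditions (each cell carries one value per
    condition of the contrasted pair).
    """
    level = ObservationLevel(level)
    conds = tuple(conditions) if conditions is not None else design.conditions
    unknown = set(conds) - set(design.conditions)
    if unknown:
        raise DesignValidationError(f"unknown conditions {sorted(unknown)}")
    n_cond = len(conds)
    total_repeats = sum(design.voice_repeat_totals().values())
    n_blocks = len(design.blocks)
    if level is ObservationLevel.AUDIO_FILE:
        return total_repeats * design.singers_per_voice * n_cond
    if level is ObservationLevel.PIECE:
        return total_repeats * n_cond
    if level is ObservationLevel.RECORDING_UNIT:
        return len(design.voices) * n_blocks * n_cond
    if level is ObservationLevel.BLOCK_VOICE_MEAN:
        return n_blocks * len(design.voices)
    if level is ObservationLevel.RESPIRATION_GRID:
        return n_blocks * design.n_singers * design.n_frequency_components
    raise DesignValidationError(f"unsupported level {level!r}")  # pragma: no cover
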