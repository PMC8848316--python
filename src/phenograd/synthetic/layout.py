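"""Experiment layout: species blocks on a room / row / column grid.

Each room holds a grid of cultivation gutters: columns are gutters (12 per
room by default, following the light gradient), rows run across them (10
pots per gutter). A species occupies a block of contiguous rows — 3 rows of
12 (36 pots) for ordinary species, 4 rows (48 pots) for the compact rosette
reference, which needs the extra replication because only its top view is
informative. Within each block, replicate plants are randomized to
positions once at treatment start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LayoutConfig", "Pot", "ExperimentLayout", "build_layout"]


@dataclass(frozen=True)
class Pot:
    uid: str
    species: str
    room: str
    row: int
    column: int
    replicate: int


@dataclass
class LayoutConfig:
    """Species blocks and grid geometry.

    ``species_rows`` maps species name -> number of contiguous rows its
    block occupies (each row spans all columns).
    """

    species_rows: dict[str, int] = field(default_factory=dict)
    columns_per_room: int = 12
    rows_per_room: int = 10
    room_labels: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")


@dataclass
class ExperimentLayout:
    pots: list[Pot]
    config: LayoutConfig

    @property
    def pot_uids(self) -> list[str]:
        return [p.uid for p in self.pots]

    def pots_of(self, species: str) -> list[Pot]:
        return [p for p in self.pots if p.species == species]


def build_layout(config: LayoutConfig, seed: int) -> ExperimentLayout:
    """Place species blocks room by room and randomize within blocks.

    Blocks are contiguous rows; a block never straddles two rooms. Raises
    ``ValueError`` when the configured rooms cannot hold all blocks.
    Deterministic given (config, seed).
    """
    if not config.species_rows:
        raise ValueError("no species blocks configured")
    rng = np.random.default_rng(seed)
    pots: list[Pot] = []
    room_idx, next_row = 0, 0
    for species, n_rows in config.species_rows.items():
        if n_rows > config.rows_per_room:
            raise ValueError(
                f"species {species!r} block of {n_rows} rows exceeds the "
                f"{config.rows_per_room}-row room grid"
            )
        if next_row + n_rows > config.rows_per_room:
            room_idx += 1
            next_row = 0
        if room_idx >= len(config.room_labels):
            raise ValueError(
                "layout capacity exceeded: species blocks do not fit in "
                f"{len(config.room_labels)} room(s)"
            )
        room = config.room_labels[room_idx]
        positions = [
            (next_row + r, c)
            for r in range(n_rows)
            for c in range(config.columns_per_room)
        ]
        # randomization step: replicate identities shuffled within the block
        replicates = rng.permutation(len(positions))
        for (row, col), rep in zip(positions, replicates):
            uid = f"{room}:{row:02d}:{col:02d}"
            pots.append(Pot(uid, species, room, row, col, int(rep)))
        next_row += n_rows
    return ExperimentLayout(pots=pots, config=config)
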