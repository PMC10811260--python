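"""Two-field incomplete block trial design.

The trial layout mirrors a paired field experiment in which a diverse panel of
red clover accessions is sown in two adjacent fields (an irrigated control and
a rain-out-shelter drought field). Each field is an incomplete block design:
three blocks (one per shelter), each split into five column strips of 53
single-row plots. Every accession is replicated a fixed number of times per
field except a designated control cultivar, which is over-replicated so the
grid fills exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Field",
    "Maturity",
    "RegionGroup",
    "VarietyType",
    "Accession",
    "Plot",
    "Geometry",
    "TrialDesign",
    "DesignError",
    "build_design",
    "validate_design",
    "classify_maturity",
    "NONFLOWERING_CODE",
]

#: FLD code recording that a plot never started flowering (documented ceiling).
NONFLOWERING_CODE = 222


class Field(str, Enum):
    control = "control"
    drought = "drought"


class Maturity(str, Enum):
    early = "early"
    late = "late"
    unknown = "unknown"


class RegionGroup(str, Enum):
    N_Europe = "N_Europe"
    W_Europe = "W_Europe"
    Central_Europe = "Central_Europe"
    SE_Europe = "SE_Europe"
    Non_European = "Non_European"


class VarietyType(str, Enum):
    ecotype = "ecotype"
    landrace = "landrace"
    cultivar = "cultivar"
    breeding = "breeding"


class DesignError(ValueError):
    """Raised when a design cannot be constructed from the given inputs."""


@dataclass(frozen=True)
class Accession:
    accession_id: str
    country: str = ""
    region_group: RegionGroup | None = None
    variety_type: VarietyType | None = None
    maturity: Maturity = Maturity.unknown


@dataclass(frozen=True)
class Plot:
    plot_id: str
    field: Field
    block: int
    column: int  # within-block index
    row: int
    accession_id: str
    is_border: bool = False


@dataclass(frozen=True)
class Geometry:
    blocks: int = 3
    columns: int = 5
    rows: int = 53

    @property
    def plots_per_block(self) -> int:
        return self.columns * self.rows

    @property
    def plots_per_field(self) -> int:
        return self.blocks * self.plots_per_block


@dataclass
class TrialDesign:
    plots: list[Plot]
    panel: list[Accession]
    geometry: Geometry
    reps: int
    control_accession_id: str
    control_reps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Long layout table, one row per plot (both fields)."""
        return pd.DataFrame(
            {
                "field": [p.field.value for p in self.plots],
                "block": [p.block for p in self.plots],
                "column": [p.column for p in self.plots],
                "row": [p.row for p in self.plots],
                "plot_id": [p.plot_id for p in self.plots],
                "accession_id": [p.accession_id for p in self.plots],
                "is_border": [p.is_border for p in self.plots],
            }
        )

    def field_plots(self, field: Field | str) -> list[Plot]:
        field = Field(field)
        return [p for p in self.plots if p.field is field and not p.is_border]

    @property
    def accession_ids(self) -> list[str]:
        return [a.accession_id for a in self.panel]


def _assign_blocks(
    n_slots_per_block: np.ndarray,
    accession_ids: Sequence[str],
    reps: int,
    rng: np.random.Generator,
    distinct_blocks: bool,
) -> dict[str, list[int]]:
    """Assign each accession `reps` block indices honouring block capacities.

    When ``distinct_blocks`` is set, the replicates of one accession go to
    different blocks whenever capacity allows (greedy on the blocks with the
    most remaining slots, random tie-break), which maximizes spatial
    separation; otherwise blocks are drawn at random proportional to the
    remaining capacity.
    """
    remaining = n_slots_per_block.astype(int).copy()
    n_blocks = len(remaining)
    out: dict[str, list[int]] = {}
    order = list(accession_ids)
    rng.shuffle(order)
    for acc in order:
        chosen: list[int] = []
        for _ in range(reps):
            if distinct_blocks:
                candidates = [b for b in range(n_blocks) if remaining[b] > 0 and b not in chosen]
                if not candidates:  # capacity forces a repeat block
                    candidates = [b for b in range(n_blocks) if remaining[b] > 0]
            else:
                candidates = [b for b in range(n_blocks) if remaining[b] > 0]
            if not candidates:
                raise DesignError("ran out of block capacity during assignment")
            cap = remaining[candidates]
            # favour the fullest blocks so the greedy fill always completes
            best = cap.max()
            top = [b for b, c in zip(candidates, cap) if c == best]
            pick = int(top[rng.integers(len(top))]) if len(top) > 1 else top[0]
            chosen.append(pick)
            remaining[pick] -= 1
        out[acc] = chosen
    return out


def build_design(
    panel: Iterable[Accession | str],
    geometry: Geometry | tuple[int, int, int] = Geometry(),
    reps: int = 2,
    control_id: str = "Lemmon",
    control_reps: int = 7,
    seed: int = 0,
    distinct_blocks: bool = True,
    border: bool = False,
) -> TrialDesign:
    """Build the two-field randomized incomplete block layout.

    Both fields use the same design rules (blocks × columns × rows grid,
    ``reps`` replicates of every accession, ``control_reps`` of the control
    cultivar) but are randomized independently. Deterministic for a fixed
    ``seed``.

    Raises
    ------
    DesignError
        If grid capacity does not match the required number of plots, on
        duplicate accession ids, or if ``control_id`` is not in the panel.
    """
    panel = [a if isinstance(a, Accession) else Accession(str(a)) for a in panel]
    if not panel:
        raise DesignError("panel is empty")
    ids = [a.accession_id for a in panel]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DesignError(f"duplicate accession ids in panel: {dupes}")
    if control_id not in ids:
        raise DesignError(f"control accession {control_id!r} not in panel")
    if isinstance(geometry, tuple):
        geometry = Geometry(*geometry)

    required = (len(panel) - 1) * reps + control_reps
    available = geometry.plots_per_field
    if required != available:
        raise DesignError(
            f"grid capacity mismatch: layout needs {required} plots "
            f"({len(panel) - 1} accessions x {reps} reps + control x {control_reps}) "
            f"but the {geometry.blocks}x{geometry.columns}x{geometry.rows} grid has {available}"
        )

    ss = np.random.SeedSequence(seed)
    plots: list[Plot] = []
    for field, child in zip((Field.control, Field.drought), ss.spawn(2)):
        rng = np.random.default_rng(child)
        # slot bookkeeping: control first (spread round-robin), then the rest
        cap = np.full(geometry.blocks, geometry.plots_per_block, dtype=int)
        control_blocks = [b % geometry.blocks for b in range(control_reps)]
        for b in control_blocks:
            cap[b] -= 1
        others = [i for i in ids if i != control_id]
        assign = _assign_blocks(cap, others, reps, rng, distinct_blocks)
        per_block: dict[int, list[str]] = {b: [] for b in range(geometry.blocks)}
        for b in control_blocks:
            per_block[b].append(control_id)
        for acc, blocks in assign.items():
            for b in blocks:
                per_block[b].append(acc)
        cells = list(itertools.product(range(1, geometry.columns + 1), range(1, geometry.rows + 1)))
        for b in range(geometry.blocks):
            entries = per_block[b]
            rng.shuffle(entries)
            if len(entries) != len(cells):
                raise DesignError(
                    f"block {b + 1} holds {len(entries)} entries for {len(cells)} cells"
                )
            for (col, row), acc in zip(cells, entries):
                plots.append(
                    Plot(
                        plot_id=f"{field.value[0].upper()}{b + 1}-{col}-{row}",
                        field=field,
                        block=b + 1,
                        column=col,
                        row=row,
                        accession_id=acc,
                    )
                )
        if border:
            for b in range(geometry.blocks):
                plots.append(
                    Plot(
                        plot_id=f"{field.value[0].upper()}{b + 1}-border",
                        field=field,
                        block=b + 1,
                        column=0,
                        row=0,
                        accession_id=control_id,
                        is_border=True,
                    )
                )

    return TrialDesign(
        plots=plots,
        panel=panel,
        geometry=geometry,
        reps=reps,
        control_accession_id=control_id,
        control_reps=control_reps,
        seed=seed,
    )


def validate_design(design: TrialDesign) -> list[str]:
    """Check every design invariant; return one message per violation.

    An empty list means the design is valid. This is a reporting operation:
    it never raises.
    """
    violations: list[str] = []
    geom = design.geometry
    for field in (Field.control, Field.drought):
        plots = design.field_plots(field)
        if len(plots) != geom.plots_per_field:
            violations.append(
                f"{field.value}: {len(plots)} non-border plots, expected {geom.plots_per_field}"
            )
        seen: dict[tuple, str] = {}
        for p in plots:
            cell = (p.block, p.column, p.row)
            if cell in seen:
                violations.append(f"{field.value}: duplicate cell {cell}")
            seen[cell] = p.plot_id
            if not (1 <= p.block <= geom.blocks):
                violations.append(f"{field.value}: plot {p.plot_id} block {p.block} out of 1..{geom.blocks}")
            if not (1 <= p.column <= geom.columns):
                violations.append(f"{field.value}: plot {p.plot_id} column {p.column} out of 1..{geom.columns}")
            if not (1 <= p.row <= geom.rows):
                violations.append(f"{field.value}: plot {p.plot_id} row {p.row} out of 1..{geom.rows}")
        counts: dict[str, int] = {}
        for p in plots:
            counts[p.accession_id] = counts.get(p.accession_id, 0) + 1
        for acc in design.accession_ids:
            expected = design.control_reps if acc == design.control_accession_id else design.reps
            got = counts.get(acc, 0)
            if got != expected:
                violations.append(
                    f"{field.value}: accession {acc} placed {got} times, expected {expected}"
                )
        extra = set(counts) - set(design.accession_ids)
        for acc in sorted(extra):
            violations.append(f"{field.value}: unknown accession {acc} in layout")
    return violations


def classify_maturity(
    flowering: Mapping[str, Sequence[float]] | pd.DataFrame,
    nonflowering_code: int = NONFLOWERING_CODE,
) -> pd.DataFrame:
    """Classify accession maturity from first-year flowering (FLD) records.

    An accession is ``early`` (double-cut type) if it started flowering in at
    least one of its plots, i.e. any FLD value below the non-flowering code;
    ``late`` (single-cut type) if every plot carries the code; ``unknown``
    when no FLD data exist. Independent of plot order and idempotent.

    Parameters
    ----------
    flowering
        Either a mapping accession -> FLD values, or a DataFrame with
        ``accession_id`` and ``value`` columns.

    Returns
    -------
    DataFrame indexed by accession with ``maturity`` and ``n_plots`` (the
    evidence count) columns.

    Raises
    ------
    ValueError
        If any FLD value exceeds ``nonflowering_code`` (the documented
        ceiling of the encoding).
    """
    if isinstance(flowering, pd.DataFrame):
        grouped = {
            acc: sub["value"].to_numpy()
            for acc, sub in flowering.groupby("accession_id")
        }
    else:
        grouped = {acc: np.asarray(vals, dtype=float) for acc, vals in flowering.items()}

    records = []
    for acc, vals in grouped.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size and vals.max() > nonflowering_code:
            raise ValueError(
                f"accession {acc}: FLD value {vals.max():g} exceeds the "
                f"non-flowering code {nonflowering_code}"
            )
        if vals.size == 0:
            label = Maturity.unknown
        elif (vals < nonflowering_code).any():
            label = Maturity.early
        else:
            label = Maturity.late
        records.append((acc, label.value, int(vals.size)))
    out = pd.DataFrame(records, columns=["accession_id", "maturity", "n_plots"])
    return out.set_index("accession_id").sort_index()


def read_design_csv(path) -> pd.DataFrame:
    """Read a layout table written by :meth:`TrialDesign.to_frame`."""
    return pd.read_csv(path, dtype={"accession_id": str, "plot_id": str})
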