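"""Five-segment chimpanzee vocal-tract simulacrum and its parameter sweep.

The tract is modelled, glottis to lips, as: an optional narrow
constriction, an in-line air-sac cavity, the main vocal tract (18 cm x
1 cm^2 for an adult male), a lip-protrusion extension, and a short
narrow lip opening.  Four parameters are swept on a fixed grid —
protrusion length, sac length, sac area and lip-opening area — and the
first two formants of every configuration are tabulated.

The sweep is fully deterministic: rows are emitted in enumeration order
(protrusion slowest, then sac length, sac area, lip area fastest) and
identical runs produce byte-identical CSV output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

from hootube.tube_acoustics import (
    AcousticConstants,
    PeakCountError,
    TubeSegment,
    TubeSequence,
    find_formants,
    transfer_function,
)

SWEEP_COLUMNS = [
    "protrusion_length_cm",
    "sac_length_cm",
    "sac_area_cm2",
    "lip_area_cm2",
    "total_length_cm",
    "f1_hz",
    "f2_hz",
    "status",
]


def _positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class TractParams:
    """Parameters of the five-segment tract.

    Fixed anatomy: ``vtl`` 18 cm (adult male chimpanzee glottis-to-lips
    estimate), ``tract_area`` 1 cm^2, ``lip_opening_length`` 0.2 cm.  The
    air-sac simulacrum sits in line before the tract behind a narrow
    constriction (0.125 cm long x 0.125 cm^2 by default; both
    configurable, and the constriction can be disabled).  A sac area of
    1 cm^2 equals the tract bore, i.e. no sac.  The protrusion segment
    inherits the tract bore by default.
    """

    vtl: float = 18.0
    tract_area: float = 1.0
    sac_length: float = 1.0
    sac_area: float = 1.0
    protrusion_length: float = 0.2
    protrusion_area: float = 1.0
    lip_opening_area: float = 1.0
    lip_opening_length: float = 0.2
    constriction_length: float = 0.125
    constriction_area: float = 0.125
    constriction_enabled: bool = True

    def __post_init__(self) -> None:
        for name in (
            "vtl", "tract_area", "sac_length", "sac_area",
            "protrusion_length", "protrusion_area",
            "lip_opening_area", "lip_opening_length",
            "constriction_length", "constriction_area",
        ):
            _positive(name, getattr(self, name))

    @property
    def total_length(self) -> float:
        base = self.vtl + self.sac_length + self.protrusion_length + self.lip_opening_length
        if self.constriction_enabled:
            base += self.constriction_length
        return base


@dataclass(frozen=True)
class ParamGrid:
    """The swept parameter grid.

    Defaults: protrusion 0.2-3.8 cm step 0.2 (19 values), sac length
    1-2 cm step 0.5 (3), sac area 1-30 cm^2 step 1 (30), lip-opening
    area 0.2-1.0 cm^2 step 0.2 (5) — 8550 combinations.
    """

    protrusion_lengths: tuple[float, ...] = tuple(np.round(np.arange(0.2, 3.8001, 0.2), 10))
    sac_lengths: tuple[float, ...] = (1.0, 1.5, 2.0)
    sac_areas: tuple[float, ...] = tuple(float(a) for a in range(1, 31))
    lip_opening_areas: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)

    def __post_init__(self) -> None:
        for name in ("protrusion_lengths", "sac_lengths", "sac_areas", "lip_opening_areas"):
            values = tuple(float(v) for v in getattr(self, name))
            if not values:
                raise ValueError(f"{name} must be non-empty")
            if any(v <= 0 for v in values):
                raise ValueError(f"{name} must be all positive")
            object.__setattr__(self, name, values)

    @property
    def cardinality(self) -> int:
        return (
            len(self.protrusion_lengths) * len(self.sac_lengths)
            * len(self.sac_areas) * len(self.lip_opening_areas)
        )


@dataclass(frozen=True)
class SweepResult:
    """Formant table for a grid sweep, one row per configuration."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SWEEP_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"sweep table missing columns {missing}")

    @property
    def ok(self) -> pd.DataFrame:
        """Rows whose formant extraction succeeded."""
        return self.rows[self.rows["status"] == "ok"]

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        return cls(rows=pd.read_csv(path))


def build_tract(params: TractParams) -> TubeSequence:
    """Area function of the simulacrum, glottis first.

    Order: [constriction if enabled] -> air sac -> main tract ->
    lip protrusion -> lip opening.
    """
    segments = []
    if params.constriction_enabled:
        segments.append(TubeSegment(params.constriction_length, params.constriction_area))
    segments += [
        TubeSegment(params.sac_length, params.sac_area),
        TubeSegment(params.vtl, params.tract_area),
        TubeSegment(params.protrusion_length, params.protrusion_area),
        TubeSegment(params.lip_opening_length, params.lip_opening_area),
    ]
    return TubeSequence(segments)


def enumerate_grid(grid: ParamGrid, fixed: TractParams = TractParams()) -> Iterator[TractParams]:
    """Cartesian product of the four swept lists over the fixed constants.

    Deterministic order: protrusion length varies slowest, then sac
    length, sac area, and lip-opening area fastest.
    """
    for prot, sac_l, sac_a, lip_a in itertools.product(
        grid.protrusion_lengths, grid.sac_lengths, grid.sac_areas, grid.lip_opening_areas
    ):
        yield replace(
            fixed,
            protrusion_length=prot,
            sac_length=sac_l,
            sac_area=sac_a,
            lip_opening_area=lip_a,
        )


def run_sweep(
    grid: ParamGrid = ParamGrid(),
    fixed: TractParams = TractParams(),
    constants: AcousticConstants = AcousticConstants(),
    f_min: float = 50.0,
    f_max: float = 5000.0,
    f_step: float = 1.0,
) -> SweepResult:
    """Formants of every grid configuration, in enumeration order.

    A configuration whose peak picking fails is kept as a flagged row
    (status names the failure) rather than aborting the sweep.
    """
    records = []
    for params in enumerate_grid(grid, fixed):
        row = {
            "protrusion_length_cm": params.protrusion_length,
            "sac_length_cm": params.sac_length,
            "sac_area_cm2": params.sac_area,
            "lip_area_cm2": params.lip_opening_area,
            "total_length_cm": params.total_length,
        }
        try:
            tf = transfer_function(build_tract(params), constants, f_min, f_max, f_step)
            est = find_formants(tf, n_formants=2)
            row.update(f1_hz=est.f1, f2_hz=est.f2, status="ok")
        except (PeakCountError, ArithmeticError) as exc:
            row.update(f1_hz=np.nan, f2_hz=np.nan, status=f"failed: {exc}")
        records.append(row)
    return SweepResult(rows=pd.DataFrame.from_records(records, columns=SWEEP_COLUMNS))
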