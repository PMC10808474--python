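"""Multilevel calibration design for the four-component mixture.

The calibration set is a five-level, four-factor design in 25 runs: the
first run sits at the centre of all four factors and the remaining 24 runs
are obtained by cyclically shifting a single 24-element sequence of coded
levels, one shift per factor.  Coded levels run from -2 to +2 and map to
concentrations through per-analyte level maps.  Concentrations are stored
internally as integer tenths of a microgram per millilitre so the design
can be compared cell-for-cell against reference tables without float
round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ANALYTES",
    "DEFAULT_GENERATOR",
    "LevelMap",
    "CalibrationDesign",
    "default_level_maps",
    "build_design",
    "validation_set",
    "validation_mixture_ids",
    "design_ranges",
]

#: Analyte order used for every matrix column in the package.
ANALYTES: tuple[str, ...] = ("CAF", "COD", "PAR", "PAP")

#: 24-element coded-level generator that reproduces the reference design.
DEFAULT_GENERATOR: tuple[int, ...] = (
    0, -2, -2, 2, -1, 2, 0, -1, -1, 1, 2, 1,
    0, 2, 2, -2, 1, -2, 0, 1, 1, -1, -2, -1,
)

_CODES = (-2, -1, 0, 1, 2)

# Level maps in tenths of a µg/mL: centre levels 3.6, 8, 12 and 4.5 µg/mL
# for CAF, COD, PAR and PAP with equal spacing between adjacent codes.
_DEFAULT_LEVELS_TENTHS: dict[str, dict[int, int]] = {
    "CAF": {-2: 12, -1: 24, 0: 36, 1: 48, 2: 60},
    "COD": {-2: 20, -1: 50, 0: 80, 1: 110, 2: 140},
    "PAR": {-2: 40, -1: 80, 0: 120, 1: 160, 2: 200},
    "PAP": {-2: 15, -1: 30, 0: 45, 1: 60, 2: 75},
}

# Validation mixtures 26-31 (tenths of µg/mL, analyte order CAF/COD/PAR/PAP).
_VALIDATION_TENTHS: tuple[tuple[int, int, int, int], ...] = (
    (12, 20, 200, 20),
    (36, 80, 120, 45),
    (40, 40, 40, 40),
    (60, 20, 160, 15),
    (12, 140, 40, 75),
    (60, 140, 40, 15),
)


@dataclass(frozen=True)
class LevelMap:
    """Map from coded level (-2..+2) to concentration for one analyte."""

    analyte: str
    levels_tenths: dict[int, int]

    def __post_init__(self) -> None:
        if sorted(self.levels_tenths) != list(_CODES):
            raise ValueError(
                f"invalid-levels: level map for {self.analyte!r} must define "
                f"exactly the codes {_CODES}"
            )
        vals = [self.levels_tenths[c] for c in _CODES]
        if not all(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError(
                f"invalid-levels: concentrations for {self.analyte!r} must "
                "increase strictly with the coded level"
            )

    @property
    def levels(self) -> dict[int, float]:
        """Coded level -> concentration in µg/mL."""
        return {c: v / 10.0 for c, v in self.levels_tenths.items()}

    def concentration(self, code: int) -> float:
        return self.levels_tenths[code] / 10.0

    @property
    def centre(self) -> float:
        return self.concentration(0)


def default_level_maps() -> tuple[LevelMap, ...]:
    """Level maps with centre levels 3.6, 8, 12 and 4.5 µg/mL."""
    return tuple(LevelMap(a, dict(_DEFAULT_LEVELS_TENTHS[a])) for a in ANALYTES)


@dataclass(frozen=True)
class CalibrationDesign:
    """25-run, four-factor calibration design.

    Attributes
    ----------
    generator:
        The 24 coded levels that seed runs 2-25.
    coded:
        25 x 4 integer matrix of coded levels.
    concentrations_tenths:
        25 x 4 integer matrix in tenths of µg/mL (exact).
    analytes:
        Factor (column) names, fixed order CAF, COD, PAR, PAP.
    """

    generator: tuple[int, ...]
    coded: np.ndarray
    concentrations_tenths: np.ndarray
    analytes: tuple[str, ...] = ANALYTES
    level_maps: tuple[LevelMap, ...] = field(default_factory=default_level_maps)

    @property
    def concentrations(self) -> np.ndarray:
        """25 x 4 concentration matrix in µg/mL."""
        return self.concentrations_tenths / 10.0

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]


def build_design(
    generator: tuple[int, ...] | list[int] | None = None,
    level_maps: tuple[LevelMap, ...] | None = None,
) -> CalibrationDesign:
    """Build the 25-run calibration design from a 24-element generator.

    Run 1 is the all-centre run (every factor at code 0).  For run i >= 2,
    factor j (1-based) takes the code ``generator[(i - 2 + j - 1) mod 24]``,
    i.e. each factor column is the generator cyclically shifted by one
    position relative to the previous factor.  Each code then appears
    exactly five times per factor column.
    """
    gen = tuple(int(g) for g in (generator if generator is not None else DEFAULT_GENERATOR))
    if len(gen) != 24:
        raise ValueError("invalid-generator: generator must have exactly 24 entries")
    if any(g not in _CODES for g in gen):
        raise ValueError("invalid-generator: generator codes must lie in -2..2")
    maps = tuple(level_maps) if level_maps is not None else default_level_maps()
    if len(maps) != 4:
        raise ValueError("invalid-levels: exactly four level maps required, one per analyte")

    coded = np.zeros((25, 4), dtype=int)
    for i in range(2, 26):          # runs 2..25
        for j in range(1, 5):       # factors 1..4
            coded[i - 1, j - 1] = gen[(i - 2 + j - 1) % 24]

    tenths = np.empty((25, 4), dtype=int)
    for j, lm in enumerate(maps):
        for code in _CODES:
            tenths[coded[:, j] == code, j] = lm.levels_tenths[code]

    return CalibrationDesign(
        generator=gen,
        coded=coded,
        concentrations_tenths=tenths,
        analytes=tuple(lm.analyte for lm in maps),
        level_maps=maps,
    )


def validation_set() -> np.ndarray:
    """The fixed six-mixture validation set (µg/mL), rows 26-31."""
    return np.asarray(_VALIDATION_TENTHS, dtype=float) / 10.0


def validation_mixture_ids() -> tuple[int, ...]:
    """Mixture identifiers of the validation rows."""
    return tuple(range(26, 32))


def design_ranges(design: CalibrationDesign) -> dict[str, tuple[float, float]]:
    """Per-analyte (min, max) concentration over the calibration runs."""
    conc = design.concentrations
    return {
        a: (float(conc[:, j].min()), float(conc[:, j].max()))
        for j, a in enumerate(design.analytes)
    }
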