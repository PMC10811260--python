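"""Season timelines: cuts, drought windows, irrigation.

The trial's management calendar is data, not code: four mowing events per
growing season, a rain-out-shelter drought window opened right after the
first cut, and a handful of irrigation events per field. Two default
timelines reproduce the trial's two production years.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

__all__ = [
    "Timeline",
    "drought_duration_days",
    "YEAR1_TIMELINE",
    "YEAR2_TIMELINE",
]


@dataclass(frozen=True)
class Timeline:
    """Management calendar of one production year.

    ``drought_window`` is (start DOY, end DOY) of the rain-out shelters;
    ``irrigation`` maps field name to (DOY, mm) events. ``season_start`` /
    ``season_end`` bound the period with usable observations.
    """

    year: int
    cut_doys: tuple[int, ...]
    drought_window: tuple[int, int]
    irrigation: dict = dc_field(default_factory=dict)
    season_start: int = 60
    season_end: int = 300

    def validate(self) -> list[str]:
        problems = []
        if list(self.cut_doys) != sorted(set(self.cut_doys)):
            problems.append(f"cut DOYs not strictly increasing: {self.cut_doys}")
        a, b = self.drought_window
        if not a < b:
            problems.append(f"drought window start {a} not before end {b}")
        if a < self.season_start or b > self.season_end:
            problems.append(
                f"drought window {a}..{b} outside season {self.season_start}..{self.season_end}"
            )
        for field, events in self.irrigation.items():
            for doy, mm in events:
                if mm < 0:
                    problems.append(f"negative irrigation amount {mm} on DOY {doy} ({field})")
                if not 1 <= doy <= 366:
                    problems.append(f"irrigation DOY {doy} out of range ({field})")
        return problems

    def growth_periods(self) -> list[tuple[int, int]]:
        """Intervals between consecutive cuts (plus the spring run-up)."""
        bounds = [self.season_start, *self.cut_doys, self.season_end]
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1) if bounds[i] < bounds[i + 1]]


def drought_duration_days(window: tuple[int, int] | Timeline) -> int:
    """Drought duration in days: nights spent under the shelters (end − start)."""
    if isinstance(window, Timeline):
        window = window.drought_window
    start, end = window
    if end < start:
        raise ValueError(f"drought window end {end} before start {start}")
    return end - start


#: first production year: cuts on DOY 134/185/232/277, shelters DOY 134–184
YEAR1_TIMELINE = Timeline(
    year=1,
    cut_doys=(134, 185, 232, 277),
    drought_window=(134, 184),
    irrigation={
        "control": ((144, 23.0), (152, 23.0), (167, 23.0)),
        "drought": ((185, 10.0), (191, 10.0)),
    },
)

#: second production year: cuts on DOY 134/198/246/290, shelters DOY 134–203
YEAR2_TIMELINE = Timeline(
    year=2,
    cut_doys=(134, 198, 246, 290),
    drought_window=(134, 203),
    irrigation={
        "control": ((143, 23.0), (152, 23.0)),
        "drought": ((204, 23.0), (219, 29.0), (224, 32.0)),
    },
)
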