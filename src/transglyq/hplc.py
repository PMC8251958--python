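"""HPLC peak-area conversion quantification.

Conversions are computed from integrated peak areas at a single detection
wavelength (307 nm for the 2-selenopyrimidines, where both the selenium
nucleobase and its nucleoside absorb maximally):

    conversion_X [%] = 100 * P_X / P_total

with P_X the peak area of compound X and P_total the summed areas of the
compounds included in the balance.  By default the balance is restricted to
the selenium-containing species (free base + nucleoside), since the sugar
donors absorb only weakly at 307 nm; widening it to all detected peaks is a
configuration choice.  Equal detector response factors are assumed at the
quantification wavelength unless per-compound factors are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "Peak",
    "PeakTable",
    "ConversionResult",
    "DEFAULT_RETENTION_TIMES",
    "DEFAULT_RT_TOLERANCE",
    "NoSignalError",
    "OverlappingWindowsError",
    "series_rt_map",
    "assign_peaks",
    "conversion",
]

# typical retention times (min) under the isocratic 3% acetonitrile method
DEFAULT_RETENTION_TIMES: dict[str, float] = {
    "1": 3.4,
    "2": 6.0,
    "a": 3.6,
    "b": 8.6,
    "a''": 3.0,
    "b''": 4.5,
    "1a": 7.0,
    "1b": 12.0,
    "2a": 12.0,
    "2b": 13.0,
}

DEFAULT_RT_TOLERANCE = 0.3  # min

QUANT_WAVELENGTH = 307.0  # nm


class NoSignalError(ValueError):
    """The conversion denominator is zero (no included peak has area)."""


class OverlappingWindowsError(ValueError):
    """Two retention-time windows overlap; assignment would be ambiguous."""


@dataclass(frozen=True)
class Peak:
    """A single integrated chromatographic peak."""

    retention_time: float  # min
    area: float  # AU*s
    wavelength: float = QUANT_WAVELENGTH  # nm
    compound: str | None = None

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError("retention_time must be > 0")
        if self.area < 0:
            raise ValueError("area must be >= 0")


@dataclass(frozen=True)
class PeakTable:
    """Integrated peaks plus the wavelength used for quantification."""

    peaks: tuple
    quant_wavelength: float = QUANT_WAVELENGTH

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def at_quant_wavelength(self) -> tuple:
        return tuple(
            p for p in self.peaks if p.wavelength == self.quant_wavelength
        )

    def area_of(self, compound: str) -> float:
        return sum(
            p.area
            for p in self.at_quant_wavelength()
            if p.compound == compound
        )


@dataclass(frozen=True)
class ConversionResult:
    """Peak-area conversion with its numerator/denominator bookkeeping."""

    compound: str
    conversion_pct: float
    target_area: float
    total_area: float
    included: tuple


def series_rt_map(product: str) -> dict[str, tuple[float, float]]:
    """Retention-time windows for the compounds present in one reaction
    series (acceptor base, product nucleoside, sugar donor, donor base).

    The full compound list contains co-eluting pairs that never co-occur in
    a single reaction (e.g. the two 12 min nucleosides), so windows are
    built per series; tolerances are the default +/-0.3 min, shrunk where
    neighbors in the series sit closer than that.
    """
    if product not in {"1a", "1b", "2a", "2b"}:
        raise ValueError(f"unknown product series {product!r}")
    base, donor = product[0], product[1]
    members = [base, product, donor, donor + "''"]
    rts = {m: DEFAULT_RETENTION_TIMES[m] for m in members}
    ordered = sorted(rts.values())
    min_gap = min(b - a for a, b in zip(ordered, ordered[1:]))
    tol = min(DEFAULT_RT_TOLERANCE, 0.4 * min_gap)
    return {m: (rt, tol) for m, rt in rts.items()}


def assign_peaks(
    table: PeakTable,
    rt_map: dict[str, tuple[float, float]],
) -> PeakTable:
    """Assign peaks to compounds by retention-time windows.

    ``rt_map`` maps compound labels to (center, tolerance) in minutes; see
    :func:`series_rt_map` for the windows of one reaction series.  A peak
    falling inside exactly one window gets that compound label; peaks
    outside every window stay unassigned.  Overlapping windows are rejected
    up front.
    """
    windows = sorted(
        (center - tol, center + tol, name) for name, (center, tol) in rt_map.items()
    )
    for (lo, hi, name), (lo2, hi2, name2) in zip(windows, windows[1:]):
        if hi > lo2:
            raise OverlappingWindowsError(
                f"retention windows of {name!r} and {name2!r} overlap"
            )
    for name, (center, tol) in rt_map.items():
        if tol <= 0:
            raise ValueError(f"tolerance for {name!r} must be > 0")
    assigned = []
    for p in table.peaks:
        label = None
        for lo, hi, name in windows:
            if lo <= p.retention_time <= hi:
                label = name
                break
        assigned.append(replace(p, compound=label))
    return PeakTable(peaks=tuple(assigned), quant_wavelength=table.quant_wavelength)


def conversion(
    table: PeakTable,
    target: str,
    include: set[str] | None = None,
    response_factors: dict[str, float] | None = None,
) -> ConversionResult:
    """Percent conversion of the target compound from peak areas.

    The denominator sums the areas of the ``include`` set (default: the
    selenium species sharing the target's series, e.g. {"2", "2b"} for
    target "2b") at the quantification wavelength.  Areas are divided by
    per-compound response factors when given, turning the area ratio into a
    mole ratio.
    """
    if include is None:
        base = target[0]
        include = {base, target}
    if target not in include:
        raise ValueError("target must be a member of the included set")
    factors = response_factors or {}

    def corrected_area(name: str) -> float:
        return table.area_of(name) / factors.get(name, 1.0)

    target_area = corrected_area(target)
    total = sum(corrected_area(name) for name in include)
    if total <= 0:
        raise NoSignalError(
            f"no signal at {table.quant_wavelength:g} nm for compounds {sorted(include)}"
        )
    return ConversionResult(
        compound=target,
        conversion_pct=100.0 * target_area / total,
        target_area=target_area,
        total_area=total,
        included=tuple(sorted(include)),
    )
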