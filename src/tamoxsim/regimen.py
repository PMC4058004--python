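"""Multiple-dosing regimens: ordered dose blocks per compound.

A regimen is a set of :class:`DoseBlock` entries, each giving a compound
(TAM or END), a dose in mg, a dosing interval (24 h = once daily, 12 h =
twice daily) and a day range ``[start_day, end_day)``.  Blocks for the
same compound may not overlap in time, which lets a regimen express both
dose switches (group B escalation at the end of month 4) and
co-administration of tamoxifen with endoxifen (group C).
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import DOSED_COMPOUNDS

ALLOWED_INTERVALS = (12.0, 24.0)


class RegimenError(ValueError):
    pass


@dataclass(frozen=True)
class DoseBlock:
    compound: str
    dose_mg: float
    interval_h: float
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.compound not in DOSED_COMPOUNDS:
            raise RegimenError(f"compound must be one of {DOSED_COMPOUNDS}")
        if self.dose_mg < 0:
            raise RegimenError("dose must be >= 0 mg")
        if float(self.interval_h) not in ALLOWED_INTERVALS:
            raise RegimenError("interval must be 12 h (b.i.d.) or 24 h (q.d.)")
        if self.end_day <= self.start_day:
            raise RegimenError("end_day must exceed start_day")

    def dose_times_h(self) -> list[float]:
        """Administration times in hours; doses fall on [start, end) days."""
        t0, t1 = self.start_day * 24.0, self.end_day * 24.0
        times, t = [], t0
        while t < t1 - 1e-9:
            times.append(t)
            t += self.interval_h
        return times


@dataclass(frozen=True)
class Regimen:
    blocks: tuple[DoseBlock, ...]

    def __post_init__(self) -> None:
        by_compound: dict[str, list[DoseBlock]] = {}
        for b in self.blocks:
            by_compound.setdefault(b.compound, []).append(b)
        for comp, blocks in by_compound.items():
            blocks = sorted(blocks, key=lambda b: b.start_day)
            for a, b in zip(blocks, blocks[1:]):
                if b.start_day < a.end_day:
                    raise RegimenError(f"overlapping {comp} blocks at day {b.start_day}")

    def events(self) -> list[tuple[float, str, float]]:
        """Sorted (time_h, compound, dose_mg) administration events."""
        out = [
            (t, b.compound, b.dose_mg) for b in self.blocks for t in b.dose_times_h()
        ]
        out.sort(key=lambda e: (e[0], e[1]))
        return out

    @property
    def end_day(self) -> int:
        return max(b.end_day for b in self.blocks)

    def covers_day(self, day: int) -> bool:
        """True if ``day`` lies inside a dose block, i.e. a pre-dose trough
        at hour ``24*day`` falls within (or exactly at the end of) dosing."""
        return any(b.start_day < day <= b.end_day for b in self.blocks)


def once_daily(compound: str, dose_mg: float, days: int, start_day: int = 0) -> Regimen:
    return Regimen((DoseBlock(compound, dose_mg, 24.0, start_day, start_day + days),))


def twice_daily(compound: str, dose_mg: float, days: int, start_day: int = 0) -> Regimen:
    return Regimen((DoseBlock(compound, dose_mg, 12.0, start_day, start_day + days),))


def combine(*regimens: Regimen) -> Regimen:
    """Concurrent administration: union of all dose blocks."""
    blocks: list[DoseBlock] = []
    for r in regimens:
        blocks.extend(r.blocks)
    return Regimen(tuple(blocks))
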