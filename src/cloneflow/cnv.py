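"""CNV cellular fractions and cross-patient recurrent segments.

A segment at integer copy number CN carried by a fraction f of cells
shifts the normalized depth ratio to R = (2 (1 - f) + CN f) / 2; inverting
gives f = 2 (R - 1) / (CN - 2).  Recurrence across patients is a
sweep-line intersection of per-patient interval unions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import CnvSegment, _merge_intervals

__all__ = ["CnvFractionEstimate", "RecurrentSegment", "fraction_from_ratio", "recurrent_segments"]

_CLIP_TOL = 0.05


@dataclass
class CnvFractionEstimate:
    segment: CnvSegment
    fraction: float
    clipped: bool

    @property
    def stage(self) -> str:
        return self.segment.stage


@dataclass
class RecurrentSegment:
    chrom: str
    start: int
    end: int
    direction: str
    patient_ids: tuple[str, ...]

    @property
    def support(self) -> int:
        return len(self.patient_ids)


def fraction_from_ratio(segment: CnvSegment) -> CnvFractionEstimate:
    """Aberrant-cell fraction from a segment's depth ratio and copy number.

    f = 2 (R - 1) / (CN - 2), clamped to [0, 1]; flagged when the raw value
    lies more than 0.05 outside.  CN = 2 carries no mixture signal and is
    an error.
    """
    if segment.copy_number == 2:
        raise ValueError("copy_number 2 is not an aberration; fraction undefined")
    raw = 2.0 * (segment.depth_ratio - 1.0) / (segment.copy_number - 2.0)
    f = min(max(raw, 0.0), 1.0)
    return CnvFractionEstimate(segment=segment, fraction=f, clipped=abs(raw - f) > _CLIP_TOL)


def recurrent_segments(
    segments: Iterable[CnvSegment],
    min_support: int = 2,
    direction: str | None = None,
) -> list[RecurrentSegment]:
    """Maximal intervals where >= ``min_support`` patients share a CNV.

    Per chromosome and direction (gain/loss), each patient's segments are
    merged into a union; a boundary sweep then reports the maximal
    intervals whose patient support meets the threshold, with the
    supporting patient ids.  Patients are distinguished by ``patient_id``.
    """
    by_key: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for seg in segments:
        if direction is not None and seg.direction != direction:
            continue
        by_key.setdefault((seg.chrom, seg.direction, seg.patient_id), []).append(
            (seg.start, seg.end)
        )

    merged = {k: _merge_intervals(v) for k, v in by_key.items()}
    out: list[RecurrentSegment] = []
    chrom_dirs = sorted({(c, d) for c, d, _ in merged})
    for chrom, dirn in chrom_dirs:
        patients = {p: ivals for (c, d, p), ivals in merged.items() if c == chrom and d == dirn}
        bounds = sorted({x for ivals in patients.values() for s, e in ivals for x in (s, e)})
        open_run: tuple[int, frozenset] | None = None  # (start, supporting patients)
        for i in range(len(bounds) - 1):
            s, e = bounds[i], bounds[i + 1]
            covering = frozenset(
                p for p, ivals in patients.items() if any(a <= s and e <= b for a, b in ivals)
            )
            active = covering if len(covering) >= min_support else None
            if open_run is not None and (active is None or active != open_run[1]):
                out.append(
                    RecurrentSegment(chrom, open_run[0], s, dirn, tuple(sorted(open_run[1])))
                )
                open_run = None
            if active is not None and open_run is None:
                open_run = (s, active)
        if open_run is not None:
            out.append(
                RecurrentSegment(chrom, open_run[0], bounds[-1], dirn, tuple(sorted(open_run[1])))
            )
    # merge adjacent runs with identical support (boundary at a non-event point)
    out = _coalesce(out)
    return out


def _coalesce(segs: Sequence[RecurrentSegment]) -> list[RecurrentSegment]:
    done: list[RecurrentSegment] = []
    for s in segs:
        if (
            done
            and done[-1].chrom == s.chrom
            and done[-1].direction == s.direction
            and done[-1].end == s.start
            and done[-1].patient_ids == s.patient_ids
        ):
            done[-1] = RecurrentSegment(s.chrom, done[-1].start, s.end, s.direction, s.patient_ids)
        else:
            done.append(s)
    return done
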