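"""Chip design container: probe spots plus the target segments they query."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .fragments import TargetSegment

__all__ = ["ProbeSpot", "ChipDesign"]

_DNA = set("ACGT")


@dataclass
class ProbeSpot:
    """One feature: a spot of identical oligos, written 5'->3'.

    ``strand`` says which target strand the spot queries; forward/reverse
    partners share a ``locus`` tag.  Spots printed in several places with the
    same sequence share a ``replicate_group``.
    """

    probe_id: str
    sequence: str
    strand: str
    segment_id: str
    locus: str | None = None
    replicate_group: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(f"probe {self.probe_id!r}: non-ACGT characters {sorted(bad)}")
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"probe {self.probe_id!r}: strand must be forward/reverse")


@dataclass
class ChipDesign:
    """Probes plus the segments that can bind them.

    Probe ids must be unique and every referenced segment must exist.  Probe
    lengths are expected to be uniform (25-mers on the modelled arrays); a
    ragged design raises in strict mode and warns otherwise.
    """

    probes: list[ProbeSpot]
    segments: list[TargetSegment]
    strict: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        seen = set()
        for p in self.probes:
            if p.probe_id in seen:
                raise ValueError(f"duplicate probe_id {p.probe_id!r}")
            seen.add(p.probe_id)
        seg_ids = {s.id for s in self.segments}
        for p in self.probes:
            if p.segment_id not in seg_ids:
                raise ValueError(
                    f"probe {p.probe_id!r} references unknown segment {p.segment_id!r}"
                )
        lengths = {len(p.sequence) for p in self.probes}
        if len(lengths) > 1:
            msg = f"ragged probe lengths {sorted(lengths)}"
            if self.strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)

    @property
    def probe_length(self) -> int:
        return len(self.probes[0].sequence) if self.probes else 0

    def segment(self, seg_id: str) -> TargetSegment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)
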