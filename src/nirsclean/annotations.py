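"""Typed artifact intervals over a signal.

Artifacts are annotated as half-open sample intervals ``[start, end)`` with a
category: ``severe`` or ``slight`` oscillation, or ``baseline_shift`` (a
sustained level change co-located with an oscillation event).
"""

from __future__ import annotations

from dataclasses import dataclass, field

SEVERE = "severe"
SLIGHT = "slight"
BASELINE_SHIFT = "baseline_shift"
CATEGORIES = (SEVERE, SLIGHT, BASELINE_SHIFT)

SOURCES = ("fnirs", "accel")


@dataclass(frozen=True)
class ArtifactSegment:
    """One annotated interval, half-open and 0-based in samples."""

    start: int
    end: int
    category: str
    source: str = "fnirs"

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid segment bounds [{self.start}, {self.end})"
            )

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class ArtifactAnnotation:
    """A set of artifact segments over one signal of ``n_samples`` samples.

    Invariants (checked by :meth:`validate`):

    * all segments lie inside ``[0, n_samples)``;
    * severe and slight segments are mutually disjoint;
    * every baseline-shift segment spans exactly one oscillation region
      (the union of severe/slight segments it covers);
    * segments are kept sorted by ``(start, end, category)``.
    """

    segments: list[ArtifactSegment] = field(default_factory=list)
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (s.start, s.end, s.category)
        )

    def __len__(self) -> int:
        return len(self.segments)

    def of(self, *categories: str) -> list[tuple[int, int]]:
        """Intervals of the given categories, sorted by start."""
        return [
            (s.start, s.end) for s in self.segments if s.category in categories
        ]

    @property
    def is_empty(self) -> bool:
        return not self.segments

    def validate(self) -> "ArtifactAnnotation":
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        for s in self.segments:
            if s.end > self.n_samples:
                raise ValueError(
                    f"segment [{s.start}, {s.end}) exceeds signal length "
                    f"{self.n_samples}"
                )
        osc = sorted(self.of(SEVERE, SLIGHT))
        for (a0, a1), (b0, b1) in zip(osc, osc[1:]):
            if b0 < a1:
                raise ValueError(
                    f"oscillation segments overlap: [{a0},{a1}) and [{b0},{b1})"
                )
        for s0, s1 in self.of(BASELINE_SHIFT):
            inside = [(a, b) for a, b in osc if a >= s0 and b <= s1]
            if not inside or inside[0][0] != s0 or inside[-1][1] != s1:
                raise ValueError(
                    f"baseline-shift segment [{s0},{s1}) does not coincide "
                    "with the span of an oscillation region"
                )
        return self
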