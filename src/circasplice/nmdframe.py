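"""Reading-frame consequences of skipping a cassette exon.

Classifies an internal cassette exon by what its removal does to the open
reading frame: frame-preserving (length divisible by three), a new amino or
carboxy terminus, NMD candidacy, or NMD insensitivity because the exon is
the penultimate exon (a premature termination codon created downstream of
the last exon-exon junction is not recognized).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "TranscriptModel",
    "SkipClassification",
    "classify_skip",
    "batch_frame_report",
    "validated_cassette_models",
]

CATEGORIES = (
    "frame_preserving",
    "new_c_terminus",
    "new_n_terminus",
    "nmd_candidate",
    "nmd_insensitive_penultimate",
    "noncoding_region",
)


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exon lengths with a cassette exon and CDS in transcript coords.

    ``cassette_index`` is the 1-based exon number; ``cds_start``/``cds_end``
    are 1-based inclusive transcript coordinates.
    """

    transcript_id: str
    exon_lengths: tuple[int, ...]
    cassette_index: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.exon_lengths):
            raise ValueError("exon lengths must be > 0")
        n = len(self.exon_lengths)
        if not 1 <= self.cassette_index <= n:
            raise ValueError("cassette index out of range")
        total = sum(self.exon_lengths)
        if not 1 <= self.cds_start < self.cds_end <= total:
            raise ValueError("CDS must satisfy 1 <= start < end <= transcript length")
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValueError("CDS length must be a multiple of 3")

    def exon_span(self, index: int) -> tuple[int, int]:
        """1-based inclusive transcript coordinates of exon ``index``."""
        start = sum(self.exon_lengths[: index - 1]) + 1
        return start, start + self.exon_lengths[index - 1] - 1

    def exon_containing(self, coord: int) -> int:
        for i in range(1, len(self.exon_lengths) + 1):
            s, e = self.exon_span(i)
            if s <= coord <= e:
                return i
        raise ValueError(f"coordinate {coord} outside transcript")


@dataclass(frozen=True)
class SkipClassification:
    frame_shifting: bool
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_skip(model: TranscriptModel) -> SkipClassification:
    """Apply the skip-consequence rules in order.

    (1) exon outside the CDS -> noncoding_region; (2) length divisible by
    three -> frame_preserving; otherwise the skip shifts the frame and:
    (3) exon containing the CDS start -> new_n_terminus; (4) penultimate
    exon -> nmd_insensitive_penultimate; (5) last CDS exon before the
    stop-containing exon -> new_c_terminus; (6) otherwise nmd_candidate.
    """
    n = len(model.exon_lengths)
    i = model.cassette_index
    if i == 1 or i == n:
        raise ValueError("cassette exon must be internal (not first or last)")
    start, end = model.exon_span(i)
    length = model.exon_lengths[i - 1]

    if end < model.cds_start or start > model.cds_end:
        return SkipClassification(frame_shifting=False, category="noncoding_region")
    contains_start = start <= model.cds_start <= end
    contains_end = start <= model.cds_end <= end
    if contains_start and contains_end:
        raise ValueError("cassette exon straddles both CDS start and end; malformed model")
    if length % 3 == 0:
        return SkipClassification(frame_shifting=False, category="frame_preserving")
    if contains_start:
        return SkipClassification(frame_shifting=True, category="new_n_terminus")
    if i == n - 1:
        return SkipClassification(frame_shifting=True, category="nmd_insensitive_penultimate")
    stop_exon = model.exon_containing(model.cds_end)
    if i == stop_exon - 1:
        return SkipClassification(frame_shifting=True, category="new_c_terminus")
    return SkipClassification(frame_shifting=True, category="nmd_candidate")


def batch_frame_report(models: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Classify every model, continuing past per-record errors.

    Returns one row per transcript with the category, frame_shifting flag
    and (where classification failed) the error message. Summary counts are
    attached as ``result.attrs['category_counts']`` and
    ``result.attrs['n_frame_shifting']``.
    """
    if len(models) == 0:
        raise ValueError("need >= 1 transcript model")
    rows = []
    for model in models:
        try:
            cls = classify_skip(model)
            rows.append(
                {
                    "transcript_id": model.transcript_id,
                    "cassette_length": model.exon_lengths[model.cassette_index - 1],
                    "frame_shifting": cls.frame_shifting,
                    "category": cls.category,
                    "error": "",
                }
            )
        except ValueError as exc:
            rows.append(
                {
                    "transcript_id": model.transcript_id,
                    "cassette_length": model.exon_lengths[model.cassette_index - 1],
                    "frame_shifting": False,
                    "category": "error",
                    "error": str(exc),
                }
            )
    report = pd.DataFrame(rows)
    ok = report[report["category"] != "error"]
    report.attrs["category_counts"] = ok["category"].value_counts().to_dict()
    report.attrs["n_frame_shifting"] = int(ok["frame_shifting"].sum())
    return report


def validated_cassette_models() -> list[TranscriptModel]:
    """The nine validated internal cassette exons as structural fixtures.

    Exon counts, cassette positions and CDS placement encode each gene's
    documented structural situation (penultimate position, CDS-start
    overlap, position relative to the stop-containing exon, and length
    modulo three); absolute lengths are schematic.
    """
    return [
        TranscriptModel("Pcsk4", (150, 100, 130, 120, 200), 3, 31, 450),
        TranscriptModel("Npas2", (180, 100, 140, 160, 220), 2, 61, 540),
        TranscriptModel("Usp2", (50, 70, 100, 130), 2, 61, 339),
        TranscriptModel("Fbxo21", (160, 95, 120, 140, 180), 2, 41, 520),
        TranscriptModel("Nr1d1", (120, 51, 90, 150), 2, 30, 329),
        TranscriptModel("Ash2l", (100, 114, 80, 120), 2, 21, 320),
        TranscriptModel("Loxl4", (100, 90, 100, 80), 3, 11, 370),
        TranscriptModel("Adrbk2", (90, 60, 75, 130), 2, 10, 309),
        TranscriptModel("Clock", (200, 110, 112, 150), 3, 51, 500),
    ]
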