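"""Universal residue labels for P-loop channel pore domains.

Pore-domain residues of P-loop channels (Kv, Nav, Cav, NavAb, ...) can be
named in a sequence-independent way by a label of the form ``<repeat><segment
letter><relative position>``: repeat number 1-4, a segment letter — ``k`` for
the S4-S5 linker helix, ``o`` for the outer (S5) helix, ``p`` for the P-loop
and ``i`` for the inner (S6) helix — and the position of the residue within
that segment.  For the P-loop, positions are counted relative to position
``p50``, the selectivity-filter residue (the DEKA ring in Nav channels), so
``1p54`` is four residues downstream of the repeat-I selectivity residue.
For example, F1760 in helix S6 of repeat IV of the human cardiac channel
hNav1.5 is ``4i15``.

Mapping between labels and UniProt residue numbers is affine per
(repeat, segment) and driven by a small anchor table; an hNav1.5 table is
packaged (see :func:`hnav15_anchors`).  Residues outside the pore-domain
segments (e.g. voltage-sensor residues) have no label and are referred to by
plain residue numbers.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ResidueLabel",
    "SegmentAnchorTable",
    "LabelError",
    "parse_label",
    "format_label",
    "resolve",
    "label_of",
    "hnav15_anchors",
    "hnav15_segment_ranges",
    "SEGMENTS",
]

SEGMENTS = ("k", "o", "p", "i")

_LABEL_RE = re.compile(r"^(?:[A-Z])?([0-9])([a-z])([0-9]+)$")


class LabelError(ValueError):
    """Malformed label text or unresolvable label."""


@dataclass(frozen=True, order=True)
class ResidueLabel:
    """A universal pore-domain residue label such as ``4i15``.

    ``relpos`` is 1-based for the k/o/i segments; for the p segment it is
    relative to the selectivity-filter position p50 and may be well below 50
    (e.g. ``3p37``) or above it (``1p54``).
    """

    repeat: int
    segment: str
    relpos: int

    def __post_init__(self) -> None:
        if self.repeat not in (1, 2, 3, 4):
            raise LabelError(f"repeat must be 1-4, got {self.repeat!r}")
        if self.segment not in SEGMENTS:
            raise LabelError(
                f"segment must be one of {'/'.join(SEGMENTS)}, got {self.segment!r}"
            )
        if self.segment != "p" and self.relpos < 1:
            raise LabelError(
                f"relpos must be >= 1 for segment {self.segment!r}, got {self.relpos}"
            )
        if self.relpos < 0:
            raise LabelError(f"relpos must be non-negative, got {self.relpos}")

    def __str__(self) -> str:
        return f"{self.repeat}{self.segment}{self.relpos}"


def parse_label(text: str) -> ResidueLabel:
    """Parse a label string like ``"4i15"`` (or ``"F4i15"``; the one-letter
    amino-acid prefix is tolerated and ignored).

    Raises :class:`LabelError` naming the offending token for malformed
    strings, repeats outside 1-4 or unknown segment letters.
    """
    m = _LABEL_RE.match(text.strip())
    if not m:
        raise LabelError(f"malformed residue label: {text!r}")
    repeat_s, segment, relpos_s = m.groups()
    repeat = int(repeat_s)
    if repeat not in (1, 2, 3, 4):
        raise LabelError(f"invalid repeat {repeat_s!r} in label {text!r}")
    if segment not in SEGMENTS:
        raise LabelError(f"unknown segment letter {segment!r} in label {text!r}")
    return ResidueLabel(repeat, segment, int(relpos_s))


def format_label(label: ResidueLabel) -> str:
    """Inverse of :func:`parse_label`: ``format_label(parse_label(s))`` is a
    canonical form of ``s`` (prefix stripped)."""
    return str(label)


class SegmentAnchorTable:
    """Affine anchors mapping labels of one channel to residue numbers.

    One anchor per (repeat, segment): the residue number of a single known
    label position.  Resolution is then
    ``resnum = anchor_resnum + (relpos - anchor_relpos)``.
    """

    def __init__(
        self,
        entries: Iterable[tuple[int, str, int, int]],
        channel: str = "",
    ) -> None:
        self.channel = channel
        self._anchors: dict[tuple[int, str], tuple[int, int]] = {}
        for repeat, segment, anchor_relpos, anchor_resnum in entries:
            key = (int(repeat), segment)
            if key[1] not in SEGMENTS:
                raise LabelError(f"unknown segment {segment!r} in anchor table")
            if key in self._anchors:
                raise LabelError(f"duplicate anchor for repeat {repeat} segment {segment}")
            self._anchors[key] = (int(anchor_relpos), int(anchor_resnum))

    @property
    def entries(self) -> list[tuple[int, str, int, int]]:
        return [(r, s, ar, an) for (r, s), (ar, an) in sorted(self._anchors.items())]

    def anchor(self, repeat: int, segment: str) -> tuple[int, int]:
        try:
            return self._anchors[(repeat, segment)]
        except KeyError:
            raise LabelError(
                f"no anchor for repeat {repeat} segment {segment!r}"
                + (f" in table for {self.channel}" if self.channel else "")
            ) from None

    @classmethod
    def from_csv(cls, path, channel: str | None = None) -> "SegmentAnchorTable":
        """Load from a delimited text file with columns
        ``channel,repeat,segment,anchor_relpos,anchor_resnum``."""
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                if channel is not None and rec["channel"] != channel:
                    continue
                rows.append(
                    (int(rec["repeat"]), rec["segment"],
                     int(rec["anchor_relpos"]), int(rec["anchor_resnum"]))
                )
        if not rows:
            raise LabelError(f"no anchor rows found in {path}")
        return cls(rows, channel=channel or "")


def resolve(label: ResidueLabel | str, anchors: SegmentAnchorTable) -> int:
    """Residue number of ``label`` under ``anchors`` (affine mapping)."""
    if isinstance(label, str):
        label = parse_label(label)
    anchor_relpos, anchor_resnum = anchors.anchor(label.repeat, label.segment)
    resnum = anchor_resnum + (label.relpos - anchor_relpos)
    if resnum <= 0:
        raise LabelError(f"label {label} resolves to non-positive residue {resnum}")
    return resnum


def label_of(
    resnum: int,
    anchors: SegmentAnchorTable,
    segment_ranges: Mapping[tuple[int, str], tuple[int, int]],
) -> ResidueLabel | None:
    """Inverse of :func:`resolve` on the covered segment spans.

    ``segment_ranges`` maps (repeat, segment) to an inclusive residue-number
    span ``(first, last)``.  Returns ``None`` when ``resnum`` lies in no
    pore-domain segment (e.g. voltage-sensor residues keep their plain
    numbers).  Overlapping spans are a configuration error.
    """
    spans = sorted(segment_ranges.items(), key=lambda kv: kv[1])
    for (_, span_a), (_, span_b) in zip(spans, spans[1:]):
        if span_b[0] <= span_a[1]:
            raise LabelError(
                f"overlapping segment ranges {span_a} and {span_b}"
            )
    for (repeat, segment), (lo, hi) in segment_ranges.items():
        if lo <= resnum <= hi:
            anchor_relpos, anchor_resnum = anchors.anchor(repeat, segment)
            return ResidueLabel(repeat, segment, anchor_relpos + (resnum - anchor_resnum))
    return None


def hnav15_anchors() -> SegmentAnchorTable:
    """Packaged anchor table for the human cardiac channel hNav1.5
    (UniProt Q14524): e.g. ``4i15`` -> 1760, ``4o1`` -> 1652."""
    with resources.as_file(
        resources.files("poremcm.data").joinpath("hnav15_anchors.csv")
    ) as p:
        return SegmentAnchorTable.from_csv(p, channel="hNav1.5")


def hnav15_segment_ranges() -> dict[tuple[int, str], tuple[int, int]]:
    """Inclusive residue spans of the hNav1.5 pore-domain segments, for
    :func:`label_of`.  Spans are conservative helix extents around the
    packaged anchors."""
    anchors = hnav15_anchors()
    ranges: dict[tuple[int, str], tuple[int, int]] = {}
    for repeat in (1, 2, 3, 4):
        k1 = resolve(ResidueLabel(repeat, "k", 1), anchors)
        o1 = resolve(ResidueLabel(repeat, "o", 1), anchors)
        p36 = resolve(ResidueLabel(repeat, "p", 36), anchors)
        i1 = resolve(ResidueLabel(repeat, "i", 1), anchors)
        ranges[(repeat, "k")] = (k1, o1 - 1)
        ranges[(repeat, "o")] = (o1, o1 + 29)
        ranges[(repeat, "p")] = (p36, p36 + 20)
        ranges[(repeat, "i")] = (i1, i1 + 29)
    return ranges
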