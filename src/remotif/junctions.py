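"""Percent usage of splice junctions sharing a donor or acceptor.

For hand-selected events, usage of alternative x anchored at donor D is
100 * reads(D->Ax) / sum_i reads(D->Ai); swapping the roles gives the
percent of reads at an acceptor coming from each donor. Events with zero
total reads are flagged undefined rather than reported as 0%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import JunctionRecord


@dataclass(frozen=True)
class JunctionEvent:
    """A shared-anchor splice choice between alternative partners.

    ``anchor`` is 'donor' (anchor at the intron start, alternatives are
    acceptor coordinates) or 'acceptor' (the reverse). Coordinates follow
    the internal convention: intron [donor_pos, acceptor_pos) 0-based
    half-open.
    """

    event_id: str
    anchor: str
    seq_id: str
    anchor_pos: int
    alternatives: tuple[tuple[str, int], ...]  # (label, partner coordinate)
    strand: str = "."

    def __post_init__(self) -> None:
        if self.anchor not in ("donor", "acceptor"):
            raise ValueError("anchor must be 'donor' or 'acceptor'")
        coords = [c for _, c in self.alternatives]
        if len(set(coords)) != len(coords):
            raise ValueError(f"event {self.event_id}: duplicate partner coordinates")
        if not self.alternatives:
            raise ValueError(f"event {self.event_id}: no alternatives")


@dataclass
class UsageResult:
    """Per-alternative reads and percents for one event."""

    event_id: str
    reads: dict[str, int]
    percents: dict[str, float] = field(default_factory=dict)
    total_reads: int = 0
    defined: bool = True


def _junction_coords(rec: JunctionRecord, anchor: str) -> tuple[int, int]:
    if anchor == "donor":
        return rec.donor_pos, rec.acceptor_pos
    return rec.acceptor_pos, rec.donor_pos


def usage(event: JunctionEvent, junctions: Iterable[JunctionRecord],
          include_multi: bool = False) -> UsageResult:
    """Percent of junction reads at the event's anchor supporting each
    alternative partner.

    Junctions are matched on exact (seq_id, anchor, partner) coordinates;
    strand must be compatible ('.' matches anything). Alternatives with no
    matching record count zero reads; a zero grand total flags the result
    undefined with missing percents.
    """
    reads = {label: 0 for label, _ in event.alternatives}
    partner_of = {coord: label for label, coord in event.alternatives}
    for rec in junctions:
        if rec.seq_id != event.seq_id:
            continue
        if event.strand != "." and rec.strand != "." and rec.strand != event.strand:
            continue
        anchor_c, partner_c = _junction_coords(rec, event.anchor)
        if anchor_c != event.anchor_pos or partner_c not in partner_of:
            continue
        n = rec.unique_reads + (rec.multi_reads if include_multi else 0)
        reads[partner_of[partner_c]] += n

    total = sum(reads.values())
    if total == 0:
        return UsageResult(event.event_id, reads, {}, 0, defined=False)
    percents = {label: 100.0 * r / total for label, r in reads.items()}
    return UsageResult(event.event_id, reads, percents, total, defined=True)


def usage_by_acceptor(event: JunctionEvent, junctions: Iterable[JunctionRecord],
                      include_multi: bool = False) -> UsageResult:
    """Usage with donor/acceptor roles exchanged (anchor at the acceptor)."""
    if event.anchor != "acceptor":
        event = JunctionEvent(event.event_id, "acceptor", event.seq_id,
                              event.anchor_pos, event.alternatives, event.strand)
    return usage(event, junctions, include_multi=include_multi)


def usage_per_sample(event: JunctionEvent,
                     samples: Mapping[str, Sequence[JunctionRecord]],
                     include_multi: bool = False,
                     pooled: bool = True) -> dict[str, UsageResult]:
    """Usage per sample, plus a 'pooled' entry over all samples' reads."""
    out = {name: usage(event, recs, include_multi) for name, recs in samples.items()}
    if pooled:
        all_recs = [r for recs in samples.values() for r in recs]
        out["pooled"] = usage(event, all_recs, include_multi)
    return out


def junctions_sharing_anchor(junctions: Iterable[JunctionRecord], seq_id: str,
                             anchor: str, anchor_pos: int) -> list[JunctionRecord]:
    """Helper for event definition: all junctions at a given anchor."""
    out = []
    for rec in junctions:
        if rec.seq_id != seq_id:
            continue
        anchor_c, _ = _junction_coords(rec, anchor)
        if anchor_c == anchor_pos:
            out.append(rec)
    return sorted(out, key=lambda r: (r.donor_pos, r.acceptor_pos))
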