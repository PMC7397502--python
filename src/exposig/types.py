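"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = ["MutationRecord", "ClassifiedMutation", "GeneModel", "SkipRecord"]

_VALID_KINDS = ("SNV", "DBS", "INS", "DEL")


class SkipRecord(Exception):
    """Raised when a record cannot be classified and must be skipped.

    Carries a human-readable reason; callers count these rather than
    letting them abort a run (ambiguous context, 'N' bases, channels the
    scheme does not cover).
    """


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call.

    Coordinates are 1-based and refer to the first reference base of
    ``ref`` (the VCF convention); insertions and deletions carry a
    single shared anchor base as the first character of the longer
    allele.
    """

    sample_id: str
    contig: str
    pos: int
    ref: str
    alt: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"invalid mutation kind {self.kind!r}")
        r, a = self.ref, self.alt
        if self.kind == "SNV":
            if len(r) != 1 or len(a) != 1 or r == a:
                raise ValueError(f"not an SNV: {r}>{a}")
        elif self.kind == "DBS":
            if len(r) != 2 or len(a) != 2 or r == a:
                raise ValueError(f"not a doublet substitution: {r}>{a}")
        elif self.kind == "INS":
            if not (len(a) > len(r) == 1 and a[0] == r):
                raise ValueError(f"not an anchored insertion: {r}>{a}")
        elif self.kind == "DEL":
            if not (len(r) > len(a) == 1 and r[0] == a):
                raise ValueError(f"not an anchored deletion: {r}>{a}")

    @property
    def indel_seq(self) -> str:
        """Inserted or deleted bases (without the anchor)."""
        if self.kind == "INS":
            return self.alt[1:]
        if self.kind == "DEL":
            return self.ref[1:]
        raise ValueError("indel_seq is defined for INS/DEL records only")


@dataclass(frozen=True)
class ClassifiedMutation:
    """A mutation record together with its assigned channel."""

    record: MutationRecord
    scheme_id: str
    channel_label: str
    channel_index: int


@dataclass
class GeneModel:
    """A named gene footprint: merged genomic intervals plus optional
    expression level (any consistent transcript-abundance unit)."""

    name: str
    intervals: list[tuple[str, int, int]]  # (contig, start, end), 0-based half-open
    expression: Optional[float] = None
    footprint_bp: int = field(init=False)

    def __post_init__(self) -> None:
        merged: list[tuple[str, int, int]] = []
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in self.intervals:
            if end <= start:
                raise ValueError(
                    f"gene {self.name}: interval end {end} <= start {start}"
                )
            by_contig.setdefault(contig, []).append((start, end))
        for contig in sorted(by_contig):
            ivs = sorted(by_contig[contig])
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((contig, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((contig, cur_s, cur_e))
        self.intervals = merged
        self.footprint_bp = sum(e - s for _, s, e in merged)
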