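"""Assign mutations to canonical channels.

Single-base substitutions are reported on the strand where the mutated
base is a pyrimidine (C or T), with the reference-strand flanks
reverse-complemented and swapped when the call is purine-centred.
Doublet substitutions are collapsed to the 78 strand-agnostic channels.
Indels are classified by type, length and sequence context: homopolymer
run length for 1-bp events (with G/A collapsed to C/T), repeat-unit
count for longer events, and microhomology length for deletions at
non-repetitive sites.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Sequence

from .io import ReferenceGenome
from .schemes import (
    DBS78,
    ID83,
    SBS96,
    ChannelScheme,
    canonical_dbs,
    complement,
    revcomp,
)
from .types import ClassifiedMutation, MutationRecord, SkipRecord

log = logging.getLogger("exposig")

__all__ = [
    "classify_sbs",
    "classify_dbs",
    "classify_indel",
    "classify_record",
    "classify_records",
    "merge_adjacent_snvs",
]


def _classified(record: MutationRecord, scheme: ChannelScheme, label: str) -> ClassifiedMutation:
    return ClassifiedMutation(
        record=record,
        scheme_id=scheme.scheme_id,
        channel_label=label,
        channel_index=scheme.index[label],
    )


def classify_sbs(record: MutationRecord, genome: ReferenceGenome) -> ClassifiedMutation:
    """SBS96 channel of a single-base substitution."""
    if record.kind != "SNV":
        raise ValueError(f"classify_sbs needs an SNV, got {record.kind}")
    tri = genome.context(record.contig, record.pos, 1)
    if "N" in tri:
        raise SkipRecord(
            f"{record.contig}:{record.pos} trinucleotide {tri} contains N"
        )
    if tri[1] != record.ref:
        raise ValueError(
            f"{record.contig}:{record.pos} reference mismatch: "
            f"VCF says {record.ref}, genome says {tri[1]}"
        )
    ref, alt = record.ref, record.alt
    if ref in "CT":
        label = f"{tri[0]}[{ref}>{alt}]{tri[2]}"
    else:
        rc = revcomp(tri)
        label = f"{rc[0]}[{complement(ref)}>{complement(alt)}]{rc[2]}"
    return _classified(record, SBS96, label)


def classify_dbs(record: MutationRecord) -> ClassifiedMutation:
    """DBS78 channel of a doublet-base substitution."""
    if record.kind != "DBS":
        raise ValueError(f"classify_dbs needs a DBS, got {record.kind}")
    if record.ref == record.alt:
        raise ValueError(f"{record.ref}>{record.alt} is not a substitution")
    if "N" in record.ref or "N" in record.alt:
        raise SkipRecord(f"{record.contig}:{record.pos} doublet contains N")
    if record.ref[0] == record.alt[0] or record.ref[1] == record.alt[1]:
        raise SkipRecord(
            f"{record.contig}:{record.pos} {record.ref}>{record.alt} changes "
            "only one base; no doublet channel covers it"
        )
    ref, alt = canonical_dbs(record.ref, record.alt)
    return _classified(record, DBS78, f"{ref}>{alt}")


def _run_length(seq: str, i0: int, base: str, direction: int) -> int:
    """Consecutive ``base`` matches in ``seq`` starting at ``i0``."""
    n = 0
    i = i0
    while 0 <= i < len(seq) and seq[i] == base:
        n += 1
        i += direction
    return n


def _copy_count(seq: str, ref: str, i0: int, direction: int) -> int:
    """Whole copies of ``seq`` in ``ref`` adjacent to index ``i0``.

    ``direction=+1`` counts copies starting at i0, i0+len, ...;
    ``direction=-1`` counts copies ending just before i0.
    """
    L = len(seq)
    n = 0
    if direction > 0:
        i = i0
        while ref[i : i + L] == seq:
            n += 1
            i += L
    else:
        i = i0
        while i - L >= 0 and ref[i - L : i] == seq:
            n += 1
            i -= L
    return n


def classify_indel(record: MutationRecord, genome: ReferenceGenome) -> ClassifiedMutation:
    """ID83 channel of a small insertion or deletion.

    The record is assumed left-aligned (``read_vcf`` does this when a
    genome is supplied); run and repeat counts scan both directions, so
    the channel is invariant to placement within a repeat tract and to
    strand.
    """
    if record.kind not in ("INS", "DEL"):
        raise ValueError(f"classify_indel needs INS/DEL, got {record.kind}")
    seq = record.indel_seq
    L = len(seq)
    ref_seq = genome.contigs[record.contig]
    # window the classification will look at; N anywhere inside it is
    # treated as unclassifiable rather than run-terminating
    w_lo = max(0, record.pos - 1 - 6 * L)
    w_hi = min(len(ref_seq), record.pos + 7 * L)
    if "N" in seq or "N" in ref_seq[w_lo:w_hi]:
        raise SkipRecord(f"{record.contig}:{record.pos} indel window contains N")

    anchor0 = record.pos - 1  # 0-based anchor index
    if L == 1:
        base = seq
        cbase = complement(base) if base in "AG" else base
        if record.kind == "DEL":
            d0 = anchor0 + 1  # 0-based index of the deleted base
            run = 1 + _run_length(ref_seq, d0 - 1, base, -1) + _run_length(
                ref_seq, d0 + 1, base, +1
            )
            label = f"1:Del:{cbase}:{min(run, 6) - 1}"
        else:
            # insertion lands between anchor0 and anchor0+1
            run = _run_length(ref_seq, anchor0, base, -1) + _run_length(
                ref_seq, anchor0 + 1, base, +1
            )
            label = f"1:Ins:{cbase}:{min(run, 5)}"
        return _classified(record, ID83, label)

    lcode = min(L, 5)
    if record.kind == "DEL":
        d0 = anchor0 + 1  # deleted segment occupies [d0, d0+L)
        n_rep = 1 + _copy_count(seq, ref_seq, d0 + L, +1) + _copy_count(
            seq, ref_seq, d0, -1
        )
        if n_rep >= 2:
            label = f"{lcode}:Del:R:{min(n_rep, 6) - 1}"
        else:
            mh = 0
            j = 0
            while j < L - 1 and d0 + L + j < len(ref_seq) and seq[j] == ref_seq[d0 + L + j]:
                j += 1
            mh = j
            j = 0
            while j < L - 1 and d0 - 1 - j >= 0 and seq[L - 1 - j] == ref_seq[d0 - 1 - j]:
                j += 1
            mh = max(mh, j)
            if mh >= 1:
                label = f"{lcode}:Del:M:{min(mh, 5)}"
            else:
                label = f"{lcode}:Del:R:0"
    else:
        i0 = anchor0 + 1  # insertion point (before this 0-based index)
        n_rep = _copy_count(seq, ref_seq, i0, +1) + _copy_count(seq, ref_seq, i0, -1)
        label = f"{lcode}:Ins:R:{min(n_rep, 5)}"
    return _classified(record, ID83, label)


def classify_record(
    record: MutationRecord, genome: ReferenceGenome
) -> ClassifiedMutation:
    """Dispatch a record to its scheme's classifier."""
    if record.kind == "SNV":
        return classify_sbs(record, genome)
    if record.kind == "DBS":
        return classify_dbs(record)
    return classify_indel(record, genome)


def classify_records(
    records: Iterable[MutationRecord],
    genome: ReferenceGenome,
    scheme_id: str,
) -> tuple[list[ClassifiedMutation], dict[str, int]]:
    """Classify every record belonging to one scheme.

    Records of other kinds are ignored; records the scheme cannot place
    (N contexts, half-changed doublets) are skipped and counted per
    sample.  Returns (classified list, skipped counts by sample).
    """
    kinds = {"SBS96": ("SNV",), "DBS78": ("DBS",), "ID": ("INS", "DEL")}[
        "ID" if scheme_id in ("ID", "ID83") else scheme_id
    ]
    out: list[ClassifiedMutation] = []
    skipped: dict[str, int] = defaultdict(int)
    for rec in records:
        if rec.kind not in kinds:
            continue
        try:
            out.append(classify_record(rec, genome))
        except SkipRecord as exc:
            skipped[rec.sample_id] += 1
            log.debug("skipped record: %s", exc)
    if skipped:
        log.warning(
            "%s classification skipped %d record(s)", scheme_id, sum(skipped.values())
        )
    return out, dict(skipped)


def merge_adjacent_snvs(
    records: Sequence[MutationRecord],
) -> tuple[list[MutationRecord], list[list[MutationRecord]]]:
    """Merge pairs of adjacent same-sample SNVs into doublet records.

    Exactly two SNVs at consecutive positions become one DBS anchored at
    the first; runs of three or more consecutive SNVs cover no doublet
    channel, so they are kept as-is and returned in the flagged list
    (callers typically exclude them from both SBS and DBS catalogues).
    Non-SNV records pass through untouched.
    """
    passthrough = [r for r in records if r.kind != "SNV"]
    snvs = sorted(
        (r for r in records if r.kind == "SNV"),
        key=lambda r: (r.sample_id, r.contig, r.pos),
    )
    merged: list[MutationRecord] = list(passthrough)
    flagged: list[list[MutationRecord]] = []
    i = 0
    while i < len(snvs):
        j = i + 1
        while (
            j < len(snvs)
            and snvs[j].sample_id == snvs[i].sample_id
            and snvs[j].contig == snvs[i].contig
            and snvs[j].pos == snvs[j - 1].pos + 1
        ):
            j += 1
        run = snvs[i:j]
        if len(run) == 1:
            merged.append(run[0])
        elif len(run) == 2:
            a, b = run
            merged.append(
                MutationRecord(
                    sample_id=a.sample_id,
                    contig=a.contig,
                    pos=a.pos,
                    ref=a.ref + b.ref,
                    alt=a.alt + b.alt,
                    kind="DBS",
                )
            )
        else:
            merged.extend(run)
            flagged.append(run)
        i = j
    if flagged:
        log.warning(
            "%d run(s) of >=3 adjacent SNVs flagged as multi-base events", len(flagged)
        )
    merged.sort(key=lambda r: (r.sample_id, r.contig, r.pos))
    return merged, flagged
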