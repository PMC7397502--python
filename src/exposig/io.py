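"""Reading and writing the external formats the pipeline touches.

All coordinate conversions happen here, once: VCF and
:class:`~exposig.types.MutationRecord` are 1-based inclusive, BED is
0-based half-open.  The rest of the package never converts coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta, FastaIndexingError

from .schemes import ChannelScheme, scheme_for_labels
from .types import GeneModel, MutationRecord

log = logging.getLogger("exposig")

__all__ = [
    "ReferenceGenome",
    "SignatureCatalog",
    "load_reference",
    "read_vcf",
    "write_vcf",
    "read_signature_catalog",
    "write_signature_catalog",
    "read_gene_models",
]

_ALPHABET_RE = re.compile(r"[^ACGTN]")


class ReferenceGenome:
    """An in-memory reference: ordered contigs over {A,C,G,T,N}.

    Sequences are stored uppercase.  Intended for the megabase-scale
    references this pipeline works with (synthetic genomes, subsets of
    real assemblies); context lookups are plain string slices.
    """

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("reference genome has no contigs")
        clean: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            m = _ALPHABET_RE.search(seq)
            if m:
                raise ValueError(
                    f"contig {name!r} contains invalid base {m.group()!r} "
                    f"at position {m.start() + 1} (alphabet is A/C/G/T/N)"
                )
            clean[name] = seq
        self.contigs = clean
        self.lengths = {name: len(seq) for name, seq in clean.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def base(self, contig: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.context(contig, pos, 0)

    def context(self, contig: str, pos: int, flank: int) -> str:
        """(2*flank+1)-mer centred on a 1-based position.

        Positions hanging over either contig end are filled with 'N' so
        the returned string always has the requested length.
        """
        try:
            seq = self.contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None
        if not 1 <= pos <= len(seq):
            raise ValueError(
                f"position {pos} outside contig {contig!r} (length {len(seq)})"
            )
        if flank < 0:
            raise ValueError("flank must be non-negative")
        i = pos - 1
        lo, hi = i - flank, i + flank + 1
        left_pad = max(0, -lo)
        right_pad = max(0, hi - len(seq))
        return "N" * left_pad + seq[max(lo, 0) : min(hi, len(seq))] + "N" * right_pad

    def slice(self, contig: str, start: int, end: int) -> str:
        """0-based half-open slice (no padding; clipped to the contig)."""
        return self.contigs[contig][max(start, 0) : end]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def load_reference(path) -> ReferenceGenome:
    """Load a FASTA file (index sidecar created/reused by pyfaidx)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference FASTA not found: {path}")
    if path.stat().st_size == 0:
        raise ValueError(f"reference FASTA is empty: {path}")
    try:
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    except FastaIndexingError as exc:  # carries the offending line number
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    contigs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    if not contigs:
        raise ValueError(f"no sequences found in FASTA: {path}")
    return ReferenceGenome(contigs)


def context(genome: ReferenceGenome, contig: str, pos: int, flank: int) -> str:
    """Functional alias for :meth:`ReferenceGenome.context`."""
    return genome.context(contig, pos, flank)


# ---------------------------------------------------------------------------
# VCF


def _is_symbolic(allele: str) -> bool:
    return any(c in allele for c in "<>[]*.") or allele == ""


def _type_variant(ref: str, alt: str) -> Optional[str]:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV" if ref != alt else None
    if len(ref) == 2 and len(alt) == 2:
        return "DBS" if ref != alt else None
    if len(alt) > len(ref) == 1 and alt[0] == ref:
        return "INS"
    if len(ref) > len(alt) == 1 and ref[0] == alt:
        return "DEL"
    return None


def _left_align(
    genome: ReferenceGenome, contig: str, anchor_pos: int, seq: str
) -> tuple[int, str]:
    """Shift an indel's inserted/deleted sequence maximally 5'-ward.

    ``anchor_pos`` is the 1-based position of the shared anchor base;
    ``seq`` the inserted/deleted bases.  While the anchor base equals
    the last base of ``seq`` the event can be rotated one base left.
    """
    while anchor_pos >= 1:
        prev = genome.base(contig, anchor_pos)
        if prev != seq[-1] or anchor_pos == 1:
            break
        seq = prev + seq[:-1]
        anchor_pos -= 1
    return anchor_pos, seq


def read_vcf(
    path,
    sample_id: str,
    genome: Optional[ReferenceGenome] = None,
    keep_all_filters: bool = False,
) -> list[MutationRecord]:
    """Read somatic variant calls from a VCF (v4.2) file.

    By default only records with FILTER of PASS or '.' are kept
    (``keep_all_filters=True`` disables the filter).  Multi-allelic
    records are split per alt allele.  Symbolic/breakend alleles and
    substitutions longer than 2 bp are skipped with a counted warning.
    When ``genome`` is given, indels are left-aligned against it so
    homopolymer-run classification sees a canonical placement.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ValueError(f"failed to parse VCF {path}: {exc}") from exc

    records: list[MutationRecord] = []
    n_filtered = n_skipped = 0
    for v in vcf:
        if not keep_all_filters and v.FILTER is not None:
            n_filtered += 1
            continue
        ref = v.REF.upper()
        for alt in v.ALT:
            alt = alt.upper()
            if _is_symbolic(alt) or _is_symbolic(ref):
                n_skipped += 1
                continue
            kind = _type_variant(ref, alt)
            if kind is None:
                n_skipped += 1
                continue
            pos, r, a = v.POS, ref, alt
            if kind in ("INS", "DEL") and genome is not None:
                seq = a[1:] if kind == "INS" else r[1:]
                new_pos, new_seq = _left_align(genome, v.CHROM, pos, seq)
                if new_pos != pos:
                    anchor = genome.base(v.CHROM, new_pos)
                    pos = new_pos
                    if kind == "INS":
                        r, a = anchor, anchor + new_seq
                    else:
                        r, a = anchor + new_seq, anchor
            records.append(
                MutationRecord(
                    sample_id=sample_id, contig=v.CHROM, pos=pos, ref=r, alt=a, kind=kind
                )
            )
    vcf.close()
    if n_filtered or n_skipped:
        log.warning(
            "%s: kept %d records; %d failed FILTER, %d unsupported alleles skipped",
            path.name,
            len(records),
            n_filtered,
            n_skipped,
        )
    return records


def write_vcf(
    records: Iterable[MutationRecord],
    path,
    contig_lengths: dict[str, int],
    source: str = "exposig",
) -> None:
    """Write site-only VCF v4.2 (records sorted by contig then position)."""
    recs = sorted(records, key=lambda r: (r.contig, r.pos, r.ref, r.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in recs:
            fh.write(f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# Signature catalogues


@dataclass
class SignatureCatalog:
    """A set of named signatures over one channel scheme.

    ``profiles`` is a DataFrame with the scheme's canonical channel
    labels as index (canonical order) and one column per signature,
    each column non-negative and summing to 1.
    """

    scheme: ChannelScheme
    profiles: pd.DataFrame

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    def vector(self, name: str) -> np.ndarray:
        return self.profiles[name].to_numpy(dtype=float)

    def matrix(self) -> np.ndarray:
        """Channels x signatures matrix in canonical order."""
        return self.profiles.to_numpy(dtype=float)


def read_signature_catalog(path) -> SignatureCatalog:
    """Load a signature catalogue TSV.

    First column holds channel labels (any header, commonly ``Type``);
    remaining columns are signatures.  Labels must be exactly one
    scheme's canonical set (any row order); vectors are validated
    non-negative and renormalised to sum 1.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a label column plus >=1 signature column")
    labels = df.iloc[:, 0].astype(str)
    dup = labels[labels.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated channel label {dup.iloc[0]!r}")
    scheme = scheme_for_labels(labels)
    unknown = set(labels) - set(scheme.labels)
    if unknown:
        raise ValueError(f"{path}: unknown channel label {sorted(unknown)[0]!r}")
    body = df.set_index(df.columns[0]).astype(float)
    if (body.to_numpy() < 0).any():
        bad = body.columns[(body < 0).any()][0]
        raise ValueError(f"{path}: negative entry in signature {bad!r}")
    body = body.reindex(list(scheme.labels))
    sums = body.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"{path}: signature {bad!r} sums to zero")
    body = body / sums
    body.index.name = "Type"
    return SignatureCatalog(scheme=scheme, profiles=body)


def write_signature_catalog(catalog: SignatureCatalog, path) -> None:
    catalog.profiles.to_csv(path, sep="\t", index_label="Type")


# ---------------------------------------------------------------------------
# Gene models


def read_gene_models(bed_path, expression_path=None) -> list[GeneModel]:
    """Read gene footprints from BED4 plus an optional expression TSV.

    Overlapping intervals of the same gene are merged.  The expression
    table maps gene name to a non-negative value; genes absent from it
    keep ``expression=None``, names absent from the BED are warned
    about and ignored.
    """
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["contig", "start", "end", "name"],
        dtype={"contig": str, "start": int, "end": int, "name": str},
    )
    if len(bed) == 0:
        raise ValueError(f"{bed_path}: no intervals")
    bad = bed[bed.end <= bed.start]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"{bed_path}: interval end <= start for gene {row['name']!r} "
            f"({row.contig}:{row.start}-{row.end})"
        )
    expr: dict[str, float] = {}
    if expression_path is not None:
        tab = pd.read_csv(expression_path, sep="\t")
        if tab.shape[1] >= 2 and len(tab):
            expr = dict(zip(tab.iloc[:, 0].astype(str), tab.iloc[:, 1].astype(float)))
    genes: list[GeneModel] = []
    seen_order = bed["name"].drop_duplicates().tolist()
    grouped = bed.groupby("name", sort=False)
    for name in seen_order:
        g = grouped.get_group(name)
        genes.append(
            GeneModel(
                name=name,
                intervals=[(r.contig, r.start, r.end) for r in g.itertuples()],
                expression=expr.get(name),
            )
        )
    missing = set(expr) - set(seen_order)
    if missing:
        log.warning(
            "expression table names %d gene(s) absent from the BED (e.g. %s)",
            len(missing),
            sorted(missing)[0],
        )
    return genes


def write_gene_bed(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for contig, start, end in g.intervals:
                fh.write(f"{contig}\t{start}\t{end}\t{g.name}\n")


def write_expression_tsv(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tvalue\n")
        for g in genes:
            if g.expression is not None:
                fh.write(f"{g.name}\t{g.expression:.6g}\n")
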