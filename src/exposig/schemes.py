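"""Canonical mutation-channel schemes: SBS96, DBS78 and ID83.

Every somatic mutation is assigned to one channel of a fixed, ordered
scheme.  Single-base substitutions use the 96-channel scheme (6
pyrimidine-centred substitution classes x 16 flanking-base pairs);
doublet substitutions use the 78-channel strand-agnostic scheme; small
insertions/deletions use the 83-channel scheme (event type, length,
homopolymer/repeat context, microhomology).

The label tables built here are normative: the packaged TSV copies under
``exposig/data`` are byte-identical exports of these lists, and all
catalogue I/O validates against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "ChannelScheme",
    "SBS96",
    "DBS78",
    "ID83",
    "SBS_CLASSES",
    "DBS_CANONICAL_REFS",
    "revcomp",
    "complement",
    "scheme_by_id",
    "scheme_for_labels",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

SBS_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The ten reference doublets that represent the 78 strand-collapsed
#: doublet-substitution channels (fixed field convention).
DBS_CANONICAL_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")

_DBS_PALINDROMIC = frozenset({"AT", "CG", "GC", "TA"})


def complement(base: str) -> str:
    """Complement of a single base (N maps to N)."""
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N}."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ChannelScheme:
    """An ordered, closed set of mutation channels.

    Attributes
    ----------
    scheme_id:
        One of ``"SBS96"``, ``"DBS78"``, ``"ID"``.
    labels:
        Canonical ordered label tuple; the order is normative and used
        for every matrix, TSV export and signature vector.
    """

    scheme_id: str
    labels: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "index", {lab: i for i, lab in enumerate(self.labels)}
        )

    @property
    def size(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.index


def _build_sbs96() -> tuple[str, ...]:
    # class-major order, then 5' flank, then 3' flank, each A<C<G<T
    return tuple(
        f"{f5}[{sub}]{f3}"
        for sub in SBS_CLASSES
        for f5 in "ACGT"
        for f3 in "ACGT"
    )


def _dbs_alt_canonical(ref: str, alt: str) -> str:
    """Representative alt for a palindromic reference doublet.

    For palindromic refs (AT, CG, GC, TA) an alt and its reverse
    complement denote the same event; the lexicographically smaller
    member is the fixed representative.
    """
    rc = revcomp(alt)
    return min(alt, rc)


def _build_dbs78() -> tuple[str, ...]:
    labels: list[str] = []
    for ref in DBS_CANONICAL_REFS:
        alts = set()
        for a0 in "ACGT":
            for a1 in "ACGT":
                if a0 == ref[0] or a1 == ref[1]:
                    continue  # doublet channels require both bases changed
                alt = a0 + a1
                if ref in _DBS_PALINDROMIC:
                    alt = _dbs_alt_canonical(ref, alt)
                alts.add(alt)
        labels.extend(f"{ref}>{alt}" for alt in sorted(alts))
    return tuple(labels)


def _build_id83() -> tuple[str, ...]:
    labels: list[str] = []
    # 1-bp deletions: homopolymer run length 1..6+ encoded 0..5
    labels += [f"1:Del:{b}:{r}" for b in "CT" for r in range(6)]
    # 1-bp insertions: matching-base run length 0..5+ encoded 0..5
    labels += [f"1:Ins:{b}:{r}" for b in "CT" for r in range(6)]
    # longer deletions at repeats: repeat-unit count 1..6+ encoded 0..5
    labels += [f"{l}:Del:R:{r}" for l in (2, 3, 4, 5) for r in range(6)]
    # longer insertions at repeats: pre-existing unit count 0..5+
    labels += [f"{l}:Ins:R:{r}" for l in (2, 3, 4, 5) for r in range(6)]
    # deletions at microhomology: overlap length 1..len-1 (the 5+ length
    # bin covers deletions of 6+ bp, so its overlap runs to 5)
    labels += [
        f"{l}:Del:M:{m}"
        for l in (2, 3, 4, 5)
        for m in range(1, (l if l == 5 else l - 1) + 1)
    ]
    return tuple(labels)


SBS96 = ChannelScheme("SBS96", _build_sbs96())
DBS78 = ChannelScheme("DBS78", _build_dbs78())
ID83 = ChannelScheme("ID", _build_id83())

_SCHEMES = {"SBS96": SBS96, "DBS78": DBS78, "ID": ID83, "ID83": ID83}


def scheme_by_id(scheme_id: str) -> ChannelScheme:
    try:
        return _SCHEMES[scheme_id]
    except KeyError:
        raise ValueError(
            f"unknown channel scheme {scheme_id!r}; expected SBS96, DBS78 or ID"
        ) from None


def scheme_for_labels(labels) -> ChannelScheme:
    """Identify the scheme whose canonical label set matches ``labels``.

    Order is not required to match (catalogue files may be row-permuted)
    but the label *set* must be exactly one scheme's set.
    """
    got = set(labels)
    for scheme in (SBS96, DBS78, ID83):
        want = set(scheme.labels)
        if got == want:
            return scheme
        if got < want and len(got) > 0:
            missing = sorted(want - got)
            if len(missing) <= len(want) // 2:
                raise ValueError(
                    f"labels look like {scheme.scheme_id} but are missing "
                    f"channel(s): {', '.join(missing[:5])}"
                    + (" ..." if len(missing) > 5 else "")
                )
    raise ValueError("labels do not match any known channel scheme")


def packaged_label_table(scheme_id: str) -> tuple[str, ...]:
    """Read the shipped TSV label table for a scheme (normative order)."""
    name = {"SBS96": "sbs96_labels.tsv", "DBS78": "dbs78_labels.tsv", "ID": "id83_labels.tsv"}[
        scheme_by_id(scheme_id).scheme_id
    ]
    text = resources.files("exposig.data").joinpath(name).read_text()
    return tuple(line.strip() for line in text.splitlines() if line.strip())


def canonical_dbs(ref: str, alt: str) -> tuple[str, str]:
    """Map an arbitrary doublet substitution to its canonical (ref, alt).

    The reference doublet is replaced by its reverse complement when the
    latter is the canonical set member; palindromic refs additionally
    canonicalise the alt.  Raises if the two alleles do not differ at
    both positions (no DBS78 channel exists for half-changed doublets).
    """
    if len(ref) != 2 or len(alt) != 2:
        raise ValueError(f"not a doublet substitution: {ref}>{alt}")
    if ref[0] == alt[0] or ref[1] == alt[1]:
        raise ValueError(
            f"{ref}>{alt} changes only one position; no doublet channel exists"
        )
    if ref not in DBS_CANONICAL_REFS:
        ref, alt = revcomp(ref), revcomp(alt)
    if ref in _DBS_PALINDROMIC:
        alt = _dbs_alt_canonical(ref, alt)
    return ref, alt
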