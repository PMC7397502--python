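"""Synthetic clone studies with known ground truth.

The generator emulates the design of a carcinogen-exposure clone
experiment: control clones accumulate mutations from a background
process alone (C>T/T>C-enriched substitutions, T-homopolymer slippage
indels), while exposed clones additionally carry an exposure process
(C>A-dominated substitutions, CC>AA doublets, C deletions in short
homopolymer runs, the pattern of polycyclic-aromatic-hydrocarbon
mutagenesis).  Mutations are placed on a simulated reference at sites
whose local sequence context matches the sampled channel, so context
classification of the output reproduces the generating channel exactly.

Every drawn mutation is logged in a truth table with its generating
process, enabling recovery experiments (derived signature vs truth,
planted gene enrichment, expression-coupled rate slopes).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ReferenceGenome, write_expression_tsv, write_gene_bed, write_vcf
from .schemes import DBS78, ID83, SBS96, revcomp
from .types import GeneModel, MutationRecord

log = logging.getLogger("exposig")

__all__ = [
    "SimulationConfig",
    "StudyResult",
    "simulate_reference",
    "simulate_clone",
    "simulate_study",
    "default_background_sbs96",
    "default_exposure_sbs96",
    "default_background_dbs78",
    "default_exposure_dbs78",
    "default_background_id83",
    "default_exposure_id83",
]

_BASES = "ACGT"
_BYTE_OF = {b: ord(b) for b in _BASES}


# ---------------------------------------------------------------------------
# Toy process profiles.  Shapes follow the qualitative structure of the
# modelled experiment; exact weights are package defaults (see the
# methods note).  The copies under exposig/data are exports of these.

_BACKGROUND_SBS_CLASS_WEIGHTS = {
    "C>A": 0.06,
    "C>G": 0.06,
    "C>T": 0.42,
    "T>A": 0.05,
    "T>C": 0.33,
    "T>G": 0.08,
}

_EXPOSURE_SBS_CLASS_WEIGHTS = {
    "C>A": 0.75,
    "C>G": 0.05,
    "C>T": 0.10,
    "T>A": 0.04,
    "T>C": 0.03,
    "T>G": 0.03,
}

# mild 5'-flank preference for the exposure's C>A channels
_EXPOSURE_CA_FLANK5 = {"A": 1.2, "C": 1.5, "G": 0.8, "T": 0.5}

_BACKGROUND_DBS = {
    "CC>TT": 0.40,
    "TC>CT": 0.20,
    "TT>CC": 0.20,
    "GC>AA": 0.10,
    "AT>CA": 0.10,
}

_EXPOSURE_DBS = {
    "CC>AA": 0.70,
    "TG>AT": 0.10,
    "TG>CA": 0.10,
    "CC>AT": 0.05,
    "CC>TA": 0.05,
}

_BACKGROUND_ID = {
    "1:Del:T:3": 0.30,
    "1:Del:T:4": 0.20,
    "1:Ins:T:3": 0.15,
    "1:Del:C:1": 0.20,
    "1:Ins:C:1": 0.15,
}

_EXPOSURE_ID = {
    "1:Del:C:1": 0.40,
    "1:Del:C:2": 0.30,
    "1:Del:C:3": 0.15,
    "1:Del:C:0": 0.10,
    "1:Del:T:1": 0.05,
}


def _vector(scheme, weights: dict[str, float]) -> np.ndarray:
    v = np.zeros(scheme.size)
    for label, w in weights.items():
        v[scheme.index[label]] = w
    return v / v.sum()


def default_background_sbs96() -> np.ndarray:
    """Background substitution spectrum: C>T/T>C transition-enriched,
    uniform across flanking contexts within each class."""
    v = np.zeros(96)
    for i, label in enumerate(SBS96.labels):
        v[i] = _BACKGROUND_SBS_CLASS_WEIGHTS[label[2:5]] / 16.0
    return v / v.sum()


def default_exposure_sbs96() -> np.ndarray:
    """Exposure substitution spectrum: C>A transversion-dominated with a
    mild 5'-flank preference within the C>A channels."""
    v = np.zeros(96)
    for i, label in enumerate(SBS96.labels):
        cls = label[2:5]
        w = _EXPOSURE_SBS_CLASS_WEIGHTS[cls] / 16.0
        if cls == "C>A":
            w *= _EXPOSURE_CA_FLANK5[label[0]]
        v[i] = w
    return v / v.sum()


def default_background_dbs78() -> np.ndarray:
    return _vector(DBS78, _BACKGROUND_DBS)


def default_exposure_dbs78() -> np.ndarray:
    """Exposure doublet spectrum: CC>AA-dominated with TG>AT / TG>CA."""
    return _vector(DBS78, _EXPOSURE_DBS)


def default_background_id83() -> np.ndarray:
    return _vector(ID83, _BACKGROUND_ID)


def default_exposure_id83() -> np.ndarray:
    """Exposure indel spectrum: single C deletions in homopolymer runs
    of mostly two to four C/G."""
    return _vector(ID83, _EXPOSURE_ID)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimulationConfig:
    """Parameters of a synthetic clone study.

    Burdens are expected mutation totals per clone (Poisson means);
    ``dbs_fraction``/``indel_fraction`` are the per-process fractions
    of events emitted as doublets and indels.  When
    ``expression_rate_slope`` is set, the per-base placement weight of
    substitutions inside a gene becomes ``1 + slope * expression``.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length_bp: int = 500_000
    gc_fraction: float = 0.41
    n_control_clones: int = 3
    n_exposed_clones: int = 4
    background_burden: float = 3000.0
    exposure_burden: float = 5000.0
    dbs_fraction: float = 0.02
    indel_fraction: float = 0.05
    n_genes: int = 0
    gene_length_bp: int = 10_000
    expression_rate_slope: Optional[float] = None
    background_sbs: np.ndarray = field(default_factory=default_background_sbs96)
    exposure_sbs: np.ndarray = field(default_factory=default_exposure_sbs96)
    background_dbs: np.ndarray = field(default_factory=default_background_dbs78)
    exposure_dbs: np.ndarray = field(default_factory=default_exposure_dbs78)
    background_id: np.ndarray = field(default_factory=default_background_id83)
    exposure_id: np.ndarray = field(default_factory=default_exposure_id83)

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must lie in (0, 1)")
        if self.background_burden < 0 or self.exposure_burden < 0:
            raise ValueError("burdens must be non-negative")
        for name in ("dbs_fraction", "indel_fraction"):
            f = getattr(self, name)
            if not 0 <= f <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dbs_fraction + self.indel_fraction > 1:
            raise ValueError("dbs_fraction + indel_fraction must not exceed 1")
        if self.contig_length_bp < 1000:
            raise ValueError("contigs must be >= 1000 bp (contexts need flanks)")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_jsonable(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = [round(float(x), 10) for x in v]
            out[f.name] = v
        return out


@dataclass
class _Process:
    name: str
    sbs: np.ndarray
    dbs: np.ndarray
    ids: np.ndarray
    burden: float
    dbs_fraction: float
    indel_fraction: float


# ---------------------------------------------------------------------------
# Reference simulation and site indexing


def simulate_reference(config: SimulationConfig) -> ReferenceGenome:
    """I.i.d. random reference at the configured GC fraction.

    The same config and seed give a byte-identical genome (the seed is
    fanned out with ``SeedSequence.spawn``; stream 0 is the reference).
    """
    rng = np.random.Generator(np.random.PCG64(_child_seeds(config.seed, 1)[0]))
    at = (1.0 - config.gc_fraction) / 2.0
    gc = config.gc_fraction / 2.0
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    contigs = {}
    for i in range(config.n_contigs):
        codes = rng.choice(4, size=config.contig_length_bp, p=[at, gc, gc, at])
        contigs[f"chr{i + 1}"] = lut[codes].tobytes().decode("ascii")
    return ReferenceGenome(contigs)


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


class SiteIndex:
    """Per-contig indexes of sequence contexts for channel-conditional
    site sampling: trinucleotide center positions, doublet start
    positions, and maximal homopolymer runs by base and exact length."""

    MAX_RUN = 8

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.tri: dict[str, dict[str, np.ndarray]] = {}
        self.dbl: dict[str, dict[str, np.ndarray]] = {}
        self.runs: dict[str, dict[str, dict[int, np.ndarray]]] = {}
        for contig, seq in genome.contigs.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            code = np.full(len(arr), -1, dtype=np.int8)
            for k, b in enumerate(_BASES):
                code[arr == _BYTE_OF[b]] = k
            self.tri[contig] = self._index_kmers(code, 3)
            self.dbl[contig] = self._index_kmers(code, 2)
            self.runs[contig] = self._index_runs(code)

    @staticmethod
    def _index_kmers(code: np.ndarray, k: int) -> dict[str, np.ndarray]:
        n = len(code)
        if n < k:
            return {}
        kcode = np.zeros(n - k + 1, dtype=np.int32)
        valid = np.ones(n - k + 1, dtype=bool)
        for j in range(k):
            c = code[j : n - k + 1 + j]
            kcode = kcode * 4 + np.maximum(c, 0)
            valid &= c >= 0
        out: dict[str, np.ndarray] = {}
        idx = np.nonzero(valid)[0]
        kc = kcode[idx]
        order = np.argsort(kc, kind="stable")
        kc_sorted = kc[order]
        pos_sorted = idx[order]
        bounds = np.searchsorted(kc_sorted, np.arange(4**k + 1))
        for v in range(4**k):
            lo, hi = bounds[v], bounds[v + 1]
            if hi > lo:
                kmer = "".join(_BASES[(v >> (2 * (k - 1 - j))) & 3] for j in range(k))
                # store the position of the *center* for trinucleotides,
                # the start for doublets
                positions = pos_sorted[lo:hi] + (1 if k == 3 else 0)
                out[kmer] = np.sort(positions)
        return out

    @staticmethod
    def _index_runs(code: np.ndarray) -> dict[str, dict[int, np.ndarray]]:
        n = len(code)
        starts = np.flatnonzero(np.r_[True, code[1:] != code[:-1]])
        lengths = np.diff(np.r_[starts, n])
        out: dict[str, dict[int, np.ndarray]] = {b: {} for b in _BASES}
        for k, b in enumerate(_BASES):
            mask = code[starts] == k
            # exclude runs at the very contig start: deletions and
            # insertions need an anchor base before the run
            mask &= starts > 0
            s, L = starts[mask], lengths[mask]
            for r in range(1, SiteIndex.MAX_RUN + 1):
                sel = L == r if r < SiteIndex.MAX_RUN else L >= r
                if sel.any():
                    out[b][r] = np.sort(s[sel])
        return out


# ---------------------------------------------------------------------------
# Clone simulation


class _PlacementState:
    """Blocked-position bookkeeping: no two events within 1 bp of each
    other inside a clone, so emitted SNVs never form accidental
    doublets and every record classifies to its truth channel."""

    def __init__(self) -> None:
        self.blocked: dict[str, set[int]] = {}

    def free(self, contig: str, lo: int, hi: int) -> bool:
        b = self.blocked.get(contig)
        if b is None:
            return True
        return all(p not in b for p in range(lo, hi))

    def reserve(self, contig: str, lo: int, hi: int) -> None:
        self.blocked.setdefault(contig, set()).update(range(lo - 1, hi + 1))


class _SitePicker:
    """Draws genomic sites matching a channel, optionally weighted by a
    per-base placement weight (expression coupling)."""

    def __init__(
        self,
        index: SiteIndex,
        rng: np.random.Generator,
        weights: Optional[dict[str, np.ndarray]] = None,
    ):
        self.index = index
        self.rng = rng
        self.weights = weights
        self._cumw_cache: dict[tuple, tuple[np.ndarray, float]] = {}

    def _pools(self, table_name: str, keys: Sequence):
        table = getattr(self.index, table_name)
        pools = []
        for contig in self.index.genome.contigs:
            sub = table[contig]
            for key in keys:
                if table_name == "runs":
                    base, r = key
                    arr = sub.get(base, {}).get(r)
                else:
                    arr = sub.get(key)
                if arr is not None and len(arr):
                    pools.append((contig, key, arr))
        return pools

    def _pool_weight(self, table_name, key, contig, arr) -> tuple[np.ndarray, float]:
        cache_key = (table_name, key, contig)
        got = self._cumw_cache.get(cache_key)
        if got is None:
            w = self.weights[contig][arr]
            cum = np.cumsum(w)
            got = (cum, float(cum[-1]))
            self._cumw_cache[cache_key] = got
        return got

    def draw(self, table_name: str, keys: Sequence, channel: str, tries: int = 200):
        """Yield up to ``tries`` candidate (contig, position, key) sites
        matching the channel, drawn with the configured weighting."""
        pools = self._pools(table_name, keys)
        if not pools:
            raise ValueError(f"channel {channel!r}: no matching site in the genome")
        if self.weights is None:
            sizes = np.array([len(a) for _, _, a in pools], dtype=float)
        else:
            sizes = np.array(
                [
                    self._pool_weight(table_name, key, contig, arr)[1]
                    for contig, key, arr in pools
                ]
            )
        probs = sizes / sizes.sum()
        for _ in range(tries):
            pi = int(self.rng.choice(len(pools), p=probs))
            contig, key, arr = pools[pi]
            if self.weights is None:
                pos = int(arr[self.rng.integers(len(arr))])
            else:
                cum, total = self._pool_weight(table_name, key, contig, arr)
                j = int(np.searchsorted(cum, self.rng.random() * total, side="right"))
                pos = int(arr[min(j, len(arr) - 1)])
            yield contig, pos, key


def _sbs_site_keys(label: str) -> list[str]:
    # "A[C>G]T" -> forward trinucleotide and its reverse complement
    tri = label[0] + label[2] + label[6]
    rc = revcomp(tri)
    return [tri] if rc == tri else [tri, rc]


def _dbs_site_keys(label: str) -> list[str]:
    ref = label[:2]
    rc = revcomp(ref)
    return [ref] if rc == ref else [ref, rc]


def _id_site_keys(label: str) -> list[tuple[str, int]]:
    parts = label.split(":")
    if parts[0] != "1":
        raise ValueError(
            f"channel {label!r}: no matching site index (the simulator "
            "places 1-bp indels only)"
        )
    base = parts[2]
    code = int(parts[3])
    if parts[1] == "Del":
        # exact run length code+1; top bin (code 5) means run >= 6
        runs = [code + 1] if code < 5 else list(range(6, SiteIndex.MAX_RUN + 1))
    else:
        # code 0 is handled separately (isolated insertion site)
        runs = [code] if code < 5 else list(range(5, SiteIndex.MAX_RUN + 1))
    comp = {"C": "G", "T": "A"}[base]
    return [(b, r) for b in (base, comp) for r in runs]


def simulate_clone(
    genome: ReferenceGenome,
    processes: Sequence[_Process],
    rng: np.random.Generator,
    sample_id: str,
    site_index: Optional[SiteIndex] = None,
    weights: Optional[dict[str, np.ndarray]] = None,
) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Draw one clone's mutations from its generating processes.

    Returns the mutation records plus a truth table with one row per
    record: (sample, contig, pos, ref, alt, kind, channel, process).
    Sites are never reused within a clone and events keep at least one
    reference base between them.
    """
    if site_index is None:
        site_index = SiteIndex(genome)
    picker = _SitePicker(site_index, rng, weights)
    state = _PlacementState()
    records: list[MutationRecord] = []
    truth_rows: list[tuple] = []

    for proc in processes:
        n = int(rng.poisson(proc.burden))
        if n == 0:
            continue
        p_kinds = [
            1.0 - proc.dbs_fraction - proc.indel_fraction,
            proc.dbs_fraction,
            proc.indel_fraction,
        ]
        n_snv, n_dbs, n_id = rng.multinomial(n, p_kinds)
        for kind, count, profile, scheme in (
            ("SNV", n_snv, proc.sbs, SBS96),
            ("DBS", n_dbs, proc.dbs, DBS78),
            ("ID", n_id, proc.ids, ID83),
        ):
            if count == 0:
                continue
            channel_idx = rng.choice(scheme.size, size=count, p=profile)
            for ci in channel_idx:
                label = scheme.labels[int(ci)]
                rec = _place_mutation(
                    kind, label, genome, picker, state, rng, sample_id
                )
                if rec is None:
                    raise RuntimeError(
                        f"could not place a mutation for channel {label!r} "
                        "(genome too small or too crowded)"
                    )
                records.append(rec)
                truth_rows.append(
                    (sample_id, rec.contig, rec.pos, rec.ref, rec.alt, rec.kind, label, proc.name)
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "contig", "pos", "ref", "alt", "kind", "channel", "process"],
    )
    return records, truth


def _place_mutation(kind, label, genome, picker, state, rng, sample_id):
    if kind == "SNV":
        tri = label[0] + label[2] + label[6]
        ref_c, alt_c = label[2], label[4]
        for contig, pos0, key in picker.draw("tri", _sbs_site_keys(label), label):
            if not state.free(contig, pos0, pos0 + 1):
                continue
            state.reserve(contig, pos0, pos0 + 1)
            if key == tri:
                ref, alt = ref_c, alt_c
            else:  # site matched on the reverse strand
                ref, alt = revcomp(ref_c), revcomp(alt_c)
            return MutationRecord(sample_id, contig, pos0 + 1, ref, alt, "SNV")
        return None
    if kind == "DBS":
        ref_d, alt_d = label.split(">")
        for contig, pos0, key in picker.draw("dbl", _dbs_site_keys(label), label):
            if not state.free(contig, pos0, pos0 + 2):
                continue
            state.reserve(contig, pos0, pos0 + 2)
            if key == ref_d:
                ref, alt = ref_d, alt_d
            else:
                ref, alt = revcomp(ref_d), revcomp(alt_d)
            return MutationRecord(sample_id, contig, pos0 + 1, ref, alt, "DBS")
        return None
    # 1-bp indel channels
    parts = label.split(":")
    ev, cbase, code = parts[1], parts[2], int(parts[3])
    if ev == "Ins" and code == 0:
        # isolated site: insert a base next to a position matching neither side
        for _ in range(500):
            contig = list(genome.contigs)[int(rng.integers(len(genome.contigs)))]
            seq = genome.contigs[contig]
            a0 = int(rng.integers(1, len(seq) - 2))
            base = cbase if rng.random() < 0.5 else revcomp(cbase)
            if seq[a0] == base or seq[a0 + 1] == base:
                continue
            if not state.free(contig, a0, a0 + 2):
                continue
            state.reserve(contig, a0, a0 + 2)
            anchor = seq[a0]
            return MutationRecord(sample_id, contig, a0 + 1, anchor, anchor + base, "INS")
        return None
    for contig, run_start, key in picker.draw("runs", _id_site_keys(label), label):
        base, run = key
        if ev == "Del":
            lo, hi = run_start - 1, run_start + run
        else:
            lo, hi = run_start - 1, run_start + run
        if not state.free(contig, max(lo, 0), hi):
            continue
        state.reserve(contig, max(lo, 0), hi)
        seq = genome.contigs[contig]
        anchor = seq[run_start - 1]
        if ev == "Del":
            return MutationRecord(
                sample_id, contig, run_start, anchor + base, anchor, "DEL"
            )
        return MutationRecord(
            sample_id, contig, run_start, anchor, anchor + base, "INS"
        )
    return None


# ---------------------------------------------------------------------------
# Whole-study simulation


@dataclass
class StudyResult:
    """Outputs of a simulated study (in memory plus files on disk)."""

    config: SimulationConfig
    genome: ReferenceGenome
    records: dict[str, list[MutationRecord]]
    truth: pd.DataFrame
    genes: list[GeneModel]
    groups: dict[str, str]  # sample -> control|exposed
    outdir: Optional[Path] = None

    @property
    def control_samples(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == "control"]

    @property
    def exposed_samples(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == "exposed"]

    def all_records(self) -> list[MutationRecord]:
        out: list[MutationRecord] = []
        for s in self.groups:
            out.extend(self.records[s])
        return out


def _place_genes(config: SimulationConfig, genome: ReferenceGenome, rng) -> list[GeneModel]:
    if config.n_genes == 0:
        return []
    contigs = list(genome.contigs)
    per = [config.n_genes // len(contigs)] * len(contigs)
    for i in range(config.n_genes % len(contigs)):
        per[i] += 1
    genes: list[GeneModel] = []
    gi = 0
    for contig, n_here in zip(contigs, per):
        if n_here == 0:
            continue
        L = genome.lengths[contig]
        slot = L // n_here
        if slot < config.gene_length_bp + 10:
            raise ValueError(
                f"genes do not fit: {n_here} x {config.gene_length_bp} bp "
                f"in contig of {L} bp"
            )
        for k in range(n_here):
            jitter = int(rng.integers(0, slot - config.gene_length_bp - 5))
            start = k * slot + jitter
            genes.append(
                GeneModel(
                    name=f"gene{gi + 1:04d}",
                    intervals=[(contig, start, start + config.gene_length_bp)],
                    expression=float(np.round(rng.uniform(0.0, 100.0), 4)),
                )
            )
            gi += 1
    return genes


def _placement_weights(
    config: SimulationConfig, genome: ReferenceGenome, genes: Sequence[GeneModel]
) -> Optional[dict[str, np.ndarray]]:
    if config.expression_rate_slope is None:
        return None
    slope = config.expression_rate_slope
    weights = {c: np.ones(genome.lengths[c]) for c in genome.contigs}
    for g in genes:
        w = 1.0 + slope * (g.expression or 0.0)
        if w < 0:
            raise ValueError(
                f"expression_rate_slope makes gene {g.name} weight negative"
            )
        for contig, start, end in g.intervals:
            weights[contig][start:end] = w
    return weights


def simulate_study(config: SimulationConfig, outdir=None) -> StudyResult:
    """Simulate the full clone panel.

    Control clones draw from the background process only; exposed
    clones draw from background plus exposure.  When ``outdir`` is
    given, writes reference FASTA, one VCF per clone, a sample sheet,
    the truth table, gene BED / expression TSV and the config JSON.
    The seed fans out deterministically (stream 0: reference, stream 1:
    genes, streams 2..: clones in sample-sheet order), so the same
    config yields a byte-identical output tree.
    """
    n_clones = config.n_control_clones + config.n_exposed_clones
    seeds = _child_seeds(config.seed, 2 + n_clones)
    genome = simulate_reference(config)
    gene_rng = np.random.Generator(np.random.PCG64(seeds[1]))
    genes = _place_genes(config, genome, gene_rng)
    weights = _placement_weights(config, genome, genes)
    site_index = SiteIndex(genome)

    background = _Process(
        "background",
        config.background_sbs,
        config.background_dbs,
        config.background_id,
        config.background_burden,
        config.dbs_fraction,
        config.indel_fraction,
    )
    exposure = _Process(
        "exposure",
        config.exposure_sbs,
        config.exposure_dbs,
        config.exposure_id,
        config.exposure_burden,
        config.dbs_fraction,
        config.indel_fraction,
    )

    samples = [f"control_{i + 1}" for i in range(config.n_control_clones)] + [
        f"exposed_{i + 1}" for i in range(config.n_exposed_clones)
    ]
    groups = {
        s: ("control" if s.startswith("control") else "exposed") for s in samples
    }
    records: dict[str, list[MutationRecord]] = {}
    truth_parts = []
    for k, sample in enumerate(samples):
        rng = np.random.Generator(np.random.PCG64(seeds[2 + k]))
        procs = [background] if groups[sample] == "control" else [background, exposure]
        recs, truth = simulate_clone(
            genome, procs, rng, sample, site_index=site_index, weights=weights
        )
        records[sample] = recs
        truth_parts.append(truth)
    truth = (
        pd.concat(truth_parts, ignore_index=True)
        if truth_parts
        else pd.DataFrame(
            columns=["sample", "contig", "pos", "ref", "alt", "kind", "channel", "process"]
        )
    )

    result = StudyResult(
        config=config,
        genome=genome,
        records=records,
        truth=truth,
        genes=genes,
        groups=groups,
        outdir=Path(outdir) if outdir is not None else None,
    )
    if outdir is not None:
        _write_study(result)
    return result


def _write_study(result: StudyResult) -> None:
    outdir = result.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    result.genome.to_fasta(outdir / "reference.fa")
    with open(outdir / "samplesheet.tsv", "w") as fh:
        fh.write("sample\tvcf\tgroup\n")
        for sample, group in result.groups.items():
            fh.write(f"{sample}\t{sample}.vcf\t{group}\n")
    for sample in result.groups:
        write_vcf(
            result.records[sample], outdir / f"{sample}.vcf", result.genome.lengths
        )
    result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if result.genes:
        write_gene_bed(result.genes, outdir / "genes.bed")
        write_expression_tsv(result.genes, outdir / "expression.tsv")
    with open(outdir / "config.json", "w") as fh:
        json.dump(result.config.to_jsonable(), fh, indent=1, sort_keys=True)
    log.info(
        "wrote study to %s: %d clones, %d mutations",
        outdir,
        len(result.groups),
        len(result.truth),
    )
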