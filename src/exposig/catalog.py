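"""Per-sample mutation catalogues and class-level summaries.

A catalogue is a samples x channels matrix of non-negative integer
counts over one canonical channel scheme.  For SBS96 catalogues the 96
channels collapse to the six substitution classes (C>A, C>G, C>T, T>A,
T>C, T>G); per-clone class percentages, their across-clone mean and
standard deviation, and a one-way ANOVA with Tukey post hoc comparisons
across classes reproduce the standard burden-composition summary for a
clone panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schemes import SBS_CLASSES, ChannelScheme, scheme_by_id, scheme_for_labels
from .types import ClassifiedMutation

__all__ = [
    "MutationCatalog",
    "ClassSummary",
    "AnovaReport",
    "build_catalog",
    "class_percentages",
    "class_anova",
]


@dataclass
class MutationCatalog:
    """Channel-count matrix for a set of samples.

    ``counts`` has samples as the index and the scheme's canonical
    channel labels as columns (canonical order).  ``skipped`` records
    how many input records per sample could not be classified.
    """

    scheme: ChannelScheme
    counts: pd.DataFrame
    skipped: dict[str, int] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset(self, sample_ids: Sequence[str]) -> "MutationCatalog":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise KeyError(f"samples not in catalogue: {missing}")
        return MutationCatalog(
            scheme=self.scheme,
            counts=self.counts.loc[list(sample_ids)].copy(),
            skipped={s: self.skipped.get(s, 0) for s in sample_ids},
        )

    def to_tsv(self, path) -> None:
        """Write channels as rows, samples as columns."""
        self.counts.T.to_csv(path, sep="\t", index_label="Type")

    @classmethod
    def from_tsv(cls, path) -> "MutationCatalog":
        """Read a catalogue TSV; channel-row vs channel-column
        orientation is auto-detected from which axis carries the
        canonical label set."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        try:
            scheme = scheme_for_labels(df.index)
            df = df.T
        except ValueError:
            scheme = scheme_for_labels(df.columns)
        counts = df[list(scheme.labels)].astype(int)
        counts.columns.name = None
        return cls(scheme=scheme, counts=counts)


def build_catalog(
    classified: Iterable[ClassifiedMutation],
    scheme: ChannelScheme | str,
    sample_ids: Optional[Sequence[str]] = None,
    skipped: Optional[dict[str, int]] = None,
) -> MutationCatalog:
    """Tally classified mutations into a catalogue.

    Sample order is the order of first appearance unless ``sample_ids``
    pins it (samples with no mutations then get all-zero rows).
    """
    if isinstance(scheme, str):
        scheme = scheme_by_id(scheme)
    order: list[str] = list(sample_ids) if sample_ids is not None else []
    row_of = {s: i for i, s in enumerate(order)}
    tallies: list[np.ndarray] = [np.zeros(scheme.size, dtype=np.int64) for _ in order]
    for cm in classified:
        if cm.scheme_id != scheme.scheme_id:
            raise ValueError(
                f"mixed schemes: catalogue is {scheme.scheme_id}, "
                f"got a {cm.scheme_id} classification"
            )
        s = cm.record.sample_id
        if s not in row_of:
            if sample_ids is not None:
                raise KeyError(f"unexpected sample {s!r}")
            row_of[s] = len(order)
            order.append(s)
            tallies.append(np.zeros(scheme.size, dtype=np.int64))
        tallies[row_of[s]][cm.channel_index] += 1
    mat = np.vstack(tallies) if tallies else np.zeros((0, scheme.size), dtype=np.int64)
    counts = pd.DataFrame(mat, index=order, columns=list(scheme.labels))
    return MutationCatalog(scheme=scheme, counts=counts, skipped=dict(skipped or {}))


@dataclass
class ClassSummary:
    """Per-sample six-class percentage composition of an SBS96 catalogue."""

    sample_ids: list[str]
    class_labels: tuple[str, ...]
    percentages: pd.DataFrame  # samples x 6, rows sum to 100
    mean: pd.Series
    sd: pd.Series  # across-sample standard deviation (n-1 denominator)


def _sbs_class_of(label: str) -> str:
    return label[2:5]  # "A[C>A]C" -> "C>A"


def class_percentages(catalog: MutationCatalog) -> ClassSummary:
    """Collapse an SBS96 catalogue to per-sample class percentages.

    Percentages are computed per sample and then averaged across
    samples (clones are replicates); the spread is the sample standard
    deviation (n-1 denominator).
    """
    if catalog.scheme.scheme_id != "SBS96":
        raise ValueError("class percentages are defined for SBS96 catalogues")
    totals = catalog.row_totals()
    empty = totals[totals == 0]
    if len(empty):
        raise ValueError(f"sample {empty.index[0]!r} has no classified mutations")
    classes = catalog.counts.T.groupby(_sbs_class_of).sum().T[list(SBS_CLASSES)]
    pct = classes.div(totals, axis=0) * 100.0
    return ClassSummary(
        sample_ids=list(catalog.counts.index),
        class_labels=SBS_CLASSES,
        percentages=pct,
        mean=pct.mean(axis=0),
        sd=pct.std(axis=0, ddof=1),
    )


@dataclass
class AnovaReport:
    """One-way ANOVA across substitution classes with Tukey HSD post hoc."""

    f_stat: float
    p_value: float
    tukey: pd.DataFrame  # columns: class_a, class_b, mean_diff, p_adj


_P_FLOOR = float(np.finfo(float).tiny)


def class_anova(summary: ClassSummary) -> AnovaReport:
    """Test whether the six class percentages differ, treating samples
    (clones) as replicates within each class.

    Degenerate inputs are resolved explicitly: zero between-class
    variation reports F=0, p=1; non-zero between-class variation with
    zero within-class variance reports an infinite F with the p-value
    floored at the smallest positive double rather than exactly zero.
    """
    if len(summary.sample_ids) < 2:
        raise ValueError("ANOVA needs at least 2 samples per class")
    groups = [summary.percentages[c].to_numpy(dtype=float) for c in summary.class_labels]
    grand = np.concatenate(groups)
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_between <= 1e-12 * max(1.0, abs(grand.mean())) ** 2:
        return AnovaReport(0.0, 1.0, _tukey_table(summary, degenerate_equal=True))
    if ss_within <= 1e-12 * ss_between:
        return AnovaReport(np.inf, _P_FLOOR, _tukey_table(summary))
    f, p = stats.f_oneway(*groups)
    return AnovaReport(float(f), float(p), _tukey_table(summary))


def _tukey_table(summary: ClassSummary, degenerate_equal: bool = False) -> pd.DataFrame:
    labels = list(summary.class_labels)
    pairs = list(combinations(range(len(labels)), 2))
    if degenerate_equal:
        rows = [(labels[i], labels[j], 0.0, 1.0) for i, j in pairs]
        return pd.DataFrame(rows, columns=["class_a", "class_b", "mean_diff", "p_adj"])
    groups = [summary.percentages[c].to_numpy(dtype=float) for c in labels]
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    rows = []
    if ss_within <= 1e-12:
        # zero replicate variance: any mean difference is infinitely sharp
        for i, j in pairs:
            diff = float(groups[i].mean() - groups[j].mean())
            rows.append((labels[i], labels[j], diff, 1.0 if diff == 0 else _P_FLOOR))
    else:
        res = stats.tukey_hsd(*groups)
        for i, j in pairs:
            p = float(np.clip(res.pvalue[i, j], _P_FLOOR, 1.0))
            diff = float(groups[i].mean() - groups[j].mean())
            rows.append((labels[i], labels[j], diff, p))
    return pd.DataFrame(rows, columns=["class_a", "class_b", "mean_diff", "p_adj"])
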