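"""Gene-level selection statistics on a clone mutation set.

Two questions are asked of the mutation placements.  First, does a
gene carry more (overmutation) or fewer (protection) mutations than
expected if mutations fell uniformly on the genome in proportion to the
gene's footprint?  Each gene gets upper- and lower-tail probabilities
under a Poisson (default) or exact binomial null, with the two one-sided
families FDR-controlled separately (Benjamini-Hochberg).  Second, does
the per-Mb mutation rate vary with transcription?  Genes are ranked by
expression, split into equal-size bins, and the bin rate is regressed
on the bin's expression statistic by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GeneModel, MutationRecord

__all__ = [
    "EnrichmentResult",
    "RateRegressionResult",
    "count_gene_mutations",
    "enrichment_tails",
    "gene_enrichment_test",
    "fdr_adjust",
    "expression_rate_regression",
]


def count_gene_mutations(
    mutations: Sequence[MutationRecord], genes: Sequence[GeneModel]
) -> dict[str, int]:
    """Mutations whose first altered base falls inside each gene.

    For substitutions the first altered base is the record position;
    for anchored indels it is the base after the anchor.  A mutation
    inside two overlapping genes counts for both.
    """
    by_contig: dict[str, list[int]] = {}
    for m in mutations:
        p0 = m.pos - 1  # 0-based first reference base
        if m.kind in ("INS", "DEL"):
            p0 += 1  # first inserted-after/deleted base, not the anchor
        by_contig.setdefault(m.contig, []).append(p0)
    pos_arrays = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_contig.items()}
    out: dict[str, int] = {}
    for gene in genes:
        n = 0
        for contig, start, end in gene.intervals:
            arr = pos_arrays.get(contig)
            if arr is None:
                continue
            n += int(np.searchsorted(arr, end) - np.searchsorted(arr, start))
        out[gene.name] = n
    return out


@dataclass
class EnrichmentResult:
    """Observed vs expected mutation count for one gene."""

    gene: str
    observed: int
    expected: float
    p_over: float
    p_under: float
    q_over: float = np.nan
    q_under: float = np.nan
    call: str = "consistent"


def enrichment_tails(
    observed: int,
    total_mutations: int,
    footprint_bp: int,
    effective_genome_bp: int,
    model: str = "poisson",
) -> tuple[float, float, float]:
    """(expected, p_over, p_under) for one gene under the uniform null.

    ``p_over = P(X >= observed)`` and ``p_under = P(X <= observed)``
    with X ~ Poisson(lambda), lambda = total * footprint / genome, or
    X ~ Binomial(total, footprint/genome) with ``model="binomial"``.
    """
    if footprint_bp > effective_genome_bp:
        raise ValueError(
            f"footprint ({footprint_bp}) exceeds effective genome "
            f"({effective_genome_bp})"
        )
    if not 0 <= observed <= total_mutations:
        raise ValueError("need 0 <= observed <= total_mutations")
    frac = footprint_bp / effective_genome_bp
    expected = total_mutations * frac
    if model == "poisson":
        p_over = float(stats.poisson.sf(observed - 1, expected))
        p_under = float(stats.poisson.cdf(observed, expected))
    elif model == "binomial":
        p_over = float(stats.binom.sf(observed - 1, total_mutations, frac))
        p_under = float(stats.binom.cdf(observed, total_mutations, frac))
    else:
        raise ValueError(f"unknown null model {model!r}")
    return expected, p_over, p_under


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_enrichment_test(
    observed: dict[str, int],
    total_mutations: int,
    footprints: dict[str, int],
    effective_genome_bp: int,
    model: str = "poisson",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-gene overmutation/protection calls across a gene family.

    Upper- and lower-tail p-values are FDR-adjusted separately; a gene
    is called ``overmutated`` when q_over < alpha, ``protected`` when
    q_under < alpha, else ``consistent`` (with random placement).
    """
    names = list(observed)
    results = []
    for name in names:
        expected, p_over, p_under = enrichment_tails(
            observed[name], total_mutations, footprints[name], effective_genome_bp, model
        )
        results.append(
            EnrichmentResult(
                gene=name,
                observed=observed[name],
                expected=expected,
                p_over=p_over,
                p_under=p_under,
            )
        )
    q_over = fdr_adjust([r.p_over for r in results])
    q_under = fdr_adjust([r.p_under for r in results])
    for r, qo, qu in zip(results, q_over, q_under):
        r.q_over = float(qo)
        r.q_under = float(qu)
        if qo < alpha:
            r.call = "overmutated"
        elif qu < alpha:
            r.call = "protected"
        else:
            r.call = "consistent"
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene, r.observed, r.expected, r.p_over, r.p_under, r.q_over, r.q_under, r.call)
            for r in results
        ],
        columns=["gene", "observed", "expected", "p_over", "p_under", "q_over", "q_under", "call"],
    )


@dataclass
class RateRegressionResult:
    """OLS fit of per-bin mutation rate (per Mb) on expression level."""

    bins: list[tuple[float, float]]  # (expression statistic, rate per Mb)
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    slope_stderr: float
    x_mode: str

    def to_dict(self) -> dict:
        return {
            "bins": [{"x": x, "rate_per_mb": r} for x, r in self.bins],
            "slope": self.slope,
            "intercept": self.intercept,
            "p_value": self.p_value,
            "r_squared": self.r_squared,
            "slope_stderr": self.slope_stderr,
            "x_mode": self.x_mode,
        }


def expression_rate_regression(
    mutations: Sequence[MutationRecord],
    genes: Sequence[GeneModel],
    n_bins: int = 10,
    x_mode: str = "midrank",
) -> RateRegressionResult:
    """Regress mutation rate on transcription level across gene bins.

    Genes carrying an expression value are ranked by it and split into
    ``n_bins`` equal-size bins (deciles by default).  Each bin's rate is
    its mutation count divided by its footprint in Mb.  The regressor is
    the bin's mean expression rank (``midrank``, default), mean
    expression (``mean_expression``) or mean log10 expression
    (``mean_log_expression``).
    """
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    expressed = [g for g in genes if g.expression is not None]
    if len(expressed) < n_bins:
        raise ValueError(
            f"need >= {n_bins} genes with expression, got {len(expressed)}"
        )
    order = sorted(range(len(expressed)), key=lambda i: (expressed[i].expression, i))
    rank_of = {gene_i: r + 1 for r, gene_i in enumerate(order)}
    counts = count_gene_mutations(mutations, expressed)
    bin_groups = np.array_split(np.asarray(order), n_bins)
    xs, rates = [], []
    for b, idx in enumerate(bin_groups):
        members = [expressed[i] for i in idx]
        fp = sum(g.footprint_bp for g in members)
        if fp == 0:
            raise ValueError(f"bin {b} has zero footprint")
        n_mut = sum(counts[g.name] for g in members)
        rates.append(n_mut / (fp / 1e6))
        ranks = [rank_of[i] for i in idx]
        if x_mode == "midrank":
            xs.append(float(np.mean(ranks)))
        elif x_mode == "mean_expression":
            xs.append(float(np.mean([g.expression for g in members])))
        elif x_mode == "mean_log_expression":
            vals = np.array([g.expression for g in members], dtype=float)
            if (vals <= 0).any():
                raise ValueError("log-expression mode needs positive expression values")
            xs.append(float(np.mean(np.log10(vals))))
        else:
            raise ValueError(f"unknown x_mode {x_mode!r}")
    x = np.asarray(xs)
    y = np.asarray(rates)
    res = stats.linregress(x, y)
    slope = float(res.slope)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    p = float(res.pvalue)
    if not np.isfinite(p):
        # degenerate residuals: flat rates are a perfect null fit, an
        # exact non-flat line is infinitely significant (floored)
        p = 1.0 if slope == 0.0 else float(np.finfo(float).tiny)
    return RateRegressionResult(
        bins=list(zip(xs, rates)),
        slope=slope,
        intercept=float(res.intercept),
        p_value=p,
        r_squared=r2,
        slope_stderr=float(res.stderr),
        x_mode=x_mode,
    )
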