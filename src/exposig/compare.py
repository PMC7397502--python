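"""Compare a derived profile against a signature catalogue.

Cosine similarity ranks catalogue signatures by shape match; a
non-negative least-squares refit decomposes the profile into a
non-negative combination of catalogue signatures and reports the
reconstruction quality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .derive import SignatureProfile
from .io import SignatureCatalog

__all__ = ["SimilarityReport", "ExposureFit", "cosine_similarity", "rank_matches", "fit_exposures"]


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two profile vectors.

    Scale-invariant; 1 means identical shape, 0 disjoint support.  For
    non-negative inputs the value is clamped to [0, 1] against rounding.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    if np.array_equal(a, b):
        return 1.0  # identical shape is exactly 1, untouched by rounding
    cos = float(a @ b / (na * nb))
    if (a >= 0).all() and (b >= 0).all():
        return float(np.clip(cos, 0.0, 1.0))
    return float(np.clip(cos, -1.0, 1.0))


@dataclass
class SimilarityReport:
    """Catalogue signatures ranked by cosine similarity to a query."""

    query: str
    scheme_id: str
    ranked: list[tuple[str, float]]  # non-increasing; ties keep catalogue order

    @property
    def best_match(self) -> tuple[str, float]:
        return self.ranked[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i + 1, name, score) for i, (name, score) in enumerate(self.ranked)],
            columns=["rank", "signature", "cosine"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def rank_matches(profile: SignatureProfile, catalog: SignatureCatalog) -> SimilarityReport:
    """Cosine similarity of a profile against every catalogue signature."""
    if catalog.scheme.scheme_id != profile.scheme_id:
        raise ValueError(
            f"scheme mismatch: profile {profile.scheme_id} vs "
            f"catalogue {catalog.scheme.scheme_id}"
        )
    scores = [
        (name, cosine_similarity(profile.weights, catalog.vector(name)))
        for name in catalog.names
    ]
    # stable sort: equal scores keep catalogue column order
    ranked = sorted(scores, key=lambda t: -t[1])
    return SimilarityReport(query=profile.name, scheme_id=profile.scheme_id, ranked=ranked)


@dataclass
class ExposureFit:
    """Non-negative decomposition of a profile over catalogue signatures."""

    query: str
    exposures: dict[str, float]
    residual_norm: float
    reconstruction_cosine: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "query": self.query,
                    "exposures": self.exposures,
                    "residual_norm": self.residual_norm,
                    "reconstruction_cosine": self.reconstruction_cosine,
                },
                fh,
                indent=2,
            )


def fit_exposures(
    profile: SignatureProfile,
    catalog: SignatureCatalog,
    subset: Optional[Sequence[str]] = None,
) -> ExposureFit:
    """Non-negative least squares refit of the profile onto the catalogue.

    Minimises ||query - sum_i w_i sig_i||_2 subject to w >= 0 over the
    selected catalogue signatures (all by default).
    """
    if catalog.scheme.scheme_id != profile.scheme_id:
        raise ValueError(
            f"scheme mismatch: profile {profile.scheme_id} vs "
            f"catalogue {catalog.scheme.scheme_id}"
        )
    names = list(subset) if subset is not None else catalog.names
    if not names:
        raise ValueError("no catalogue signatures selected")
    missing = [n for n in names if n not in catalog.names]
    if missing:
        raise KeyError(f"signatures not in catalogue: {missing}")
    A = np.column_stack([catalog.vector(n) for n in names])
    if (A.sum(axis=0) <= 0).any():
        bad = names[int(np.argmax(A.sum(axis=0) <= 0))]
        raise ValueError(f"degenerate catalogue signature {bad!r} (all zero)")
    y = profile.weights
    w, rnorm = nnls(A, y)
    recon = A @ w
    if recon.sum() <= 0:
        recon_cos = 0.0
    else:
        recon_cos = cosine_similarity(y, recon)
    return ExposureFit(
        query=profile.name,
        exposures={n: float(x) for n, x in zip(names, w)},
        residual_norm=float(rnorm),
        reconstruction_cosine=float(recon_cos),
    )
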