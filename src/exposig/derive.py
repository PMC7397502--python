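"""Derive an exposure signature by normalising exposed clones against
control clones.

The exposed clones carry background mutagenesis plus the exposure
process; the control clones carry the background alone.  The default
derivation subtracts the per-channel mean control count from the
per-channel mean exposed count, floors negative excesses at zero and
renormalises the positive excess to a unit-sum profile.  A "pooled"
variant subtracts raw pooled counts instead of per-clone means, for
sensitivity checks when clone numbers are unbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import MutationCatalog
from .io import SignatureCatalog
from .schemes import ChannelScheme, scheme_by_id

__all__ = ["SignatureProfile", "derive_exposure_signature", "profile_percentages"]


@dataclass
class SignatureProfile:
    """A unit-sum, non-negative weight vector over one channel scheme."""

    scheme_id: str
    name: str
    weights: np.ndarray
    support: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError(f"profile {self.name!r} has negative weights")
        total = w.sum()
        if total <= 0:
            raise ValueError(f"profile {self.name!r} has zero total weight")
        self.weights = w / total
        scheme = scheme_by_id(self.scheme_id)
        if len(self.weights) != scheme.size:
            raise ValueError(
                f"profile {self.name!r}: {len(self.weights)} weights for "
                f"{scheme.scheme_id} ({scheme.size} channels)"
            )

    @property
    def scheme(self) -> ChannelScheme:
        return scheme_by_id(self.scheme_id)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.scheme.labels), name=self.name)

    def to_catalog(self) -> SignatureCatalog:
        """Single-signature catalogue (round-trips through catalogue TSV)."""
        df = self.as_series().to_frame()
        df.index.name = "Type"
        return SignatureCatalog(scheme=self.scheme, profiles=df)

    def to_tsv(self, path) -> None:
        df = self.as_series().to_frame()
        df.to_csv(path, sep="\t", index_label="Type")


def derive_exposure_signature(
    exposed: MutationCatalog,
    control: MutationCatalog,
    mode: str = "mean-subtract",
    pseudocount: float = 0.0,
    name: Optional[str] = None,
) -> SignatureProfile:
    """Subtract the control (background) catalogue from the exposed one.

    ``mode="mean-subtract"`` (default) works on per-clone channel
    means; ``mode="pooled"`` subtracts raw pooled counts.  Negative
    excesses are floored at zero; the result is renormalised to sum 1.
    ``support`` is the rounded total positive excess, i.e. the number
    of mutations attributed to the exposure.  Raises when no channel
    shows positive excess rather than returning a zero vector.
    """
    if exposed.scheme.scheme_id != control.scheme.scheme_id:
        raise ValueError(
            f"scheme mismatch: exposed {exposed.scheme.scheme_id} vs "
            f"control {control.scheme.scheme_id}"
        )
    if len(exposed.counts) < 1 or len(control.counts) < 1:
        raise ValueError("need at least one exposed and one control sample")
    if mode == "mean-subtract":
        e = exposed.counts.mean(axis=0).to_numpy(dtype=float)
        c = control.counts.mean(axis=0).to_numpy(dtype=float)
    elif mode == "pooled":
        e = exposed.counts.sum(axis=0).to_numpy(dtype=float)
        c = control.counts.sum(axis=0).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown derivation mode {mode!r}")
    excess = e - c + float(pseudocount)
    excess[excess < 0] = 0.0
    total = excess.sum()
    if total <= 0:
        raise ValueError(
            "no exposure-attributable excess: exposed counts do not exceed "
            "control counts in any channel"
        )
    if name is None:
        name = f"{exposed.scheme.scheme_id}-exposure"
    return SignatureProfile(
        scheme_id=exposed.scheme.scheme_id,
        name=name,
        weights=excess / total,
        support=int(round(total if mode == "mean-subtract" else total)),
        provenance={
            "mode": mode,
            "pseudocount": pseudocount,
            "n_exposed": len(exposed.counts),
            "n_control": len(control.counts),
        },
    )


def profile_percentages(profile: SignatureProfile) -> np.ndarray:
    """Profile weights expressed as percentages (sums to 100)."""
    return profile.weights * 100.0
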