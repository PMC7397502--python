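"""Derive the exposure signature by control normalisation and compare
it to a signature catalogue.

The derived profile is the per-channel mean excess of exposed clones
over control clones (floored at zero, renormalised). Ranking it against
a catalogue that contains the true generating signature plus random
decoys should put the truth first; the NNLS refit decomposes the
profile into non-negative catalogue contributions.
"""

import numpy as np
import pandas as pd

from exposig.catalog import build_catalog
from exposig.classify import classify_records
from exposig.compare import cosine_similarity, fit_exposures, rank_matches
from exposig.derive import derive_exposure_signature
from exposig.io import SignatureCatalog
from exposig.schemes import SBS96
from exposig.simulate import SimulationConfig, default_exposure_sbs96, simulate_study

study = simulate_study(
    SimulationConfig(seed=3, n_contigs=2, contig_length_bp=200_000,
                     background_burden=1500, exposure_burden=2500)
)
classified, _ = classify_records(study.all_records(), study.genome, "SBS96")
catalog = build_catalog(classified, "SBS96", sample_ids=list(study.groups))

profile = derive_exposure_signature(
    catalog.subset(study.exposed_samples),
    catalog.subset(study.control_samples),
    name="exposure-NHU-like",
)
truth = default_exposure_sbs96()
print(f"derived profile support: {profile.support} excess mutations")
print(f"cosine vs generating signature: {cosine_similarity(profile.weights, truth):.4f}")

rng = np.random.Generator(np.random.PCG64(99))
cols = {f"decoy{i}": rng.dirichlet(np.full(96, 0.4)) for i in range(1, 10)}
cols["true_exposure"] = truth
sig_catalog = SignatureCatalog(
    SBS96, pd.DataFrame(cols, index=list(SBS96.labels)).pipe(lambda d: d / d.sum())
)

report = rank_matches(profile, sig_catalog)
print("\ntop 3 catalogue matches (cosine):")
for name, score in report.ranked[:3]:
    print(f"  {name:15s} {score:.4f}")

fit = fit_exposures(profile, sig_catalog)
top = sorted(fit.exposures.items(), key=lambda t: -t[1])[:3]
print("\nNNLS exposure weights (top 3):")
for name, w in top:
    print(f"  {name:15s} {w:.4f}")
print(f"reconstruction cosine: {fit.reconstruction_cosine:.4f}")
print(
    "\nA cosine near 1 against the generating signature, the truth at "
    "rank 1 and a dominant NNLS weight on it mean the control "
    "normalisation isolated the exposure process from the shared "
    "background."
)
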