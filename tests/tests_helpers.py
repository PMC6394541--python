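"""Small builders and shared constants for the test modules."""

import numpy as np

# generating values of the full covariate model, in sampler order
TRUTH_BETA = {
    "lnCL_mb": np.log(0.80),
    "lnCL_bo": -0.16,
    "lnk_mm": np.log(0.10),
    "lnV_m": 3.49,
    "slope_Vm_MWT": 0.62,
    "slope_CLbo_BWT": 0.17,
}

from dtmilk.io import EnrichmentRecord, PairDataset
from dtmilk.kinetics import Dose, InfantPool, PairParameters, predict_enrichment


def cohort_with_weights(mother_weights, infant_weight=5.0):
    """Noise-free pairs with prescribed maternal weights (for design checks)."""
    pairs = []
    pool = InfantPool(weight_start=infant_weight, weight_end=infant_weight + 0.3)
    for i, mwt in enumerate(mother_weights):
        params = PairParameters.from_pool(
            k_mm=0.10, V_m=0.4 * mwt, CL_mb=0.8, CL_bo=0.9, pool=pool
        )
        records = []
        for role in ("mother", "infant"):
            records.append(EnrichmentRecord(f"P{i}", role, 0.0, 0.0, is_baseline=True))
            for day in (1.0, 2.0, 5.0, 6.0, 13.0, 14.0):
                f = float(predict_enrichment(params, pool, Dose(0.030), role, day))
                records.append(EnrichmentRecord(f"P{i}", role, day, f))
        pairs.append(
            PairDataset(
                pair_id=f"P{i}",
                dose=0.030,
                mother_weight=float(mwt),
                infant_weight_start=pool.weight_start,
                infant_weight_end=pool.weight_end,
                infant_age=3.0,
                records=records,
            )
        )
    return pairs
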