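"""End-to-end helpers: simulate -> normalize -> classify, with scoring."""

from __future__ import annotations

from . import azf as azfmod
from . import depthcnv, sexkaryo, simcov
from .refmodel import default_target_map

__all__ = ["run_validation_arm"]


def run_validation_arm(arm: str, seed: int = 0, mean_depth: float = 100.0,
                       n_reference: int = 90, targets=None,
                       params: simcov.DepthParams | None = None) -> dict:
    """Simulate one validation arm and score calls against planted truth.

    For the AZF arm, concordance compares the AZF classification with the
    planted deletion class; for the sex arm, the karyotype class.  Returns
    per-sample calls plus the concordance percent (one decimal).
    """
    targets = targets if targets is not None else default_target_map()
    params = params or simcov.DepthParams(mean_depth=mean_depth, seed=seed)
    cohort = simcov.simulate_validation_cohort(params, targets, arm=arm,
                                               n_reference=n_reference,
                                               seed=seed)
    results = []
    concordant = 0
    for table in cohort.samples:
        profile = depthcnv.normalize(table, cohort.reference, targets)
        if arm == "azf":
            call = azfmod.classify_profile(profile).azf_class
            truth = table.truth["azf"]
        else:
            dosages = sexkaryo.estimate_sex_dosages(profile)
            call = sexkaryo.classify_karyotype(dosages).karyotype
            truth = table.truth["karyotype"]
        ok = call == truth
        concordant += ok
        results.append({"sample": table.sample_id, "truth": truth,
                        "call": call, "concordant": ok})
    n = len(results)
    return {
        "arm": arm,
        "n": n,
        "concordant": concordant,
        "concordance_percent": round(100.0 * concordant / n, 1),
        "results": results,
    }
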