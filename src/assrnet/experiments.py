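"""Standard study experiments at desk scale.

These functions bundle the cohort runs behind the headline results so the
test suite and the reproduction script exercise exactly the same pipeline:
entrainment and the GABAergic conditions on the drive-dominated fixture,
the coherence dissociation on the resonance fixture, variant-combination
additivity, and the structural echoes of the printed configuration.  All
randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .analysis import cohort_table, evoked_psd, mean_difference
from .cells import StepProtocol, build_l5pc
from .config import default_config, forced_fixture, resonant_fixture
from .network import Condition, build_network
from .pipeline import CohortPlan, run_cohort
from .variants import (
    FeatureBands,
    downscale,
    get_variant,
    load_bundled_variants,
    scale_variant,
    combine_variants,
)

__all__ = [
    "exemplar_coefficients",
    "entrainment_experiment",
    "coherence_experiment",
    "additivity_experiment",
    "jitter_robustness_experiment",
    "structure_summary",
    "control_ci",
]

#: variants used in the network experiments: the strong Ca²⁺ exemplar and a
#: second moderate-effect CaHVA variant from the bundled library
PRIMARY_VARIANT = "Ca7"
SECONDARY_VARIANT = "CACNA1C-s10"


def exemplar_coefficients(ids=(PRIMARY_VARIANT, SECONDARY_VARIANT)) -> dict[str, float]:
    """Downscaling coefficients of the exemplar variants.

    Computed from scratch with the feature-band criterion on the pyramidal
    cell (deterministic; no randomness involved).
    """
    cell = build_l5pc()
    bands = FeatureBands(protocol=StepProtocol(dt_ms=0.05))
    library = load_bundled_variants()
    return {vid: downscale(get_variant(library, vid), cell, criteria=bands).coefficient
            for vid in ids}


def control_ci(values, n_boot: int = 3000, seed: int = 5, alpha: float = 0.05):
    """Percentile bootstrap CI of the control-group mean."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _summarize(table, measure):
    return {cond: table.loc[table.condition == cond, measure].to_numpy()
            for cond in table.condition.unique()}


def entrainment_experiment(seed: int, variant_coefficient: float | None = None,
                           n_subjects: int = 5, n_trials: int = 3) -> dict:
    """Control / variant / Gmax / IPSC cohorts on the drive-dominated fixture.

    Returns per-condition 4040 and 2040 band powers per subject plus the
    control evoked PSD (for the entrainment-peak check).
    """
    cfg = forced_fixture()
    conds = [Condition.control(), Condition.gmax(), Condition.ipsc()]
    if variant_coefficient is not None:
        sv = scale_variant(get_variant(load_bundled_variants(), PRIMARY_VARIANT),
                           variant_coefficient)
        conds.insert(1, Condition.from_variant(sv))
    plan = CohortPlan(conditions=tuple(conds), n_subjects=n_subjects,
                      n_trials=n_trials)
    cohort = run_cohort(plan, cfg, seed)
    table = cohort_table(cohort)

    lo = int(plan.analysis_start)
    hi = int(plan.analysis_stop)
    lfps = np.vstack([cohort.lfp_matrix("control", s)[:, lo:hi]
                      for s in range(plan.n_subjects)])
    spec = evoked_psd(lfps)
    nonzero = spec.freqs > 1.0
    peak_hz = float(spec.freqs[nonzero][np.argmax(spec.psd[nonzero])])
    return {
        "peak_hz": peak_hz,
        "power_4040": _summarize(table, "power_4040"),
        "power_2040": _summarize(table, "power_2040"),
        "n_failed": cohort.n_failed(),
        "table": table,
    }


def coherence_experiment(seed: int, variant_coefficient: float,
                         n_subjects: int = 5, n_trials: int = 5) -> dict:
    """ITC dissociation cohorts on the resonance fixture (half scale)."""
    cfg = resonant_fixture()
    sv = scale_variant(get_variant(load_bundled_variants(), PRIMARY_VARIANT),
                       variant_coefficient)
    plan = CohortPlan(
        conditions=(Condition.control(), Condition.from_variant(sv),
                    Condition.gmax(), Condition.ipsc()),
        n_subjects=n_subjects, n_trials=n_trials,
    )
    cohort = run_cohort(plan, cfg, seed)
    table = cohort_table(cohort)
    out = {"itc_40": _summarize(table, "itc_40"),
           "power_4040": _summarize(table, "power_4040"),
           "variant_label": f"variant:{PRIMARY_VARIANT}",
           "n_failed": cohort.n_failed(),
           "table": table}
    out["control_ci"] = control_ci(out["itc_40"]["control"])
    return out


def additivity_experiment(seed: int, coefficients: dict[str, float],
                          n_subjects: int = 5, n_trials: int = 5) -> dict:
    """Single-variant vs combined-variant 4040 effects on the forced fixture.

    The combined condition superposes the two scaled variants (shifts add,
    factors multiply); additivity holds when the combined mean difference
    matches the sum of the single mean differences within its bootstrap CI.
    """
    cfg = forced_fixture()
    library = load_bundled_variants()
    a = scale_variant(get_variant(library, PRIMARY_VARIANT),
                      coefficients[PRIMARY_VARIANT])
    b = scale_variant(get_variant(library, SECONDARY_VARIANT),
                      coefficients[SECONDARY_VARIANT])
    ab = combine_variants([a, b])
    plan = CohortPlan(
        conditions=(Condition.control(), Condition.from_variant(a),
                    Condition.from_variant(b), Condition.from_variant(ab)),
        n_subjects=n_subjects, n_trials=n_trials,
    )
    cohort = run_cohort(plan, cfg, seed)
    table = cohort_table(cohort)
    vals = _summarize(table, "power_4040")
    ctrl = vals["control"]
    est_a = mean_difference(vals[f"variant:{a.id}"], ctrl, n_boot=3000, seed=5)
    est_b = mean_difference(vals[f"variant:{b.id}"], ctrl, n_boot=3000, seed=6)
    est_ab = mean_difference(vals[f"variant:{ab.id}"], ctrl, n_boot=3000, seed=7)
    return {
        "md_a": est_a.mean_difference, "md_b": est_b.mean_difference,
        "md_combined": est_ab.mean_difference,
        "sum_singles": est_a.mean_difference + est_b.mean_difference,
        "combined_ci": (est_ab.ci_low, est_ab.ci_high),
        "n_failed": cohort.n_failed(),
    }


def jitter_robustness_experiment(seed: int, variant_coefficient: float,
                                 n_subjects: int = 3, n_trials: int = 3) -> dict:
    """Variant 4040 effect under instantaneous vs ±2 ms jittered drive."""
    sv = scale_variant(get_variant(load_bundled_variants(), PRIMARY_VARIANT),
                       variant_coefficient)
    out = {}
    for label, jitter in (("instantaneous", 0.0), ("jittered", 2.0)):
        cfg = forced_fixture()
        cfg.drive = replace(cfg.drive, jitter_ms=jitter)
        plan = CohortPlan(conditions=(Condition.control(),
                                      Condition.from_variant(sv)),
                          n_subjects=n_subjects, n_trials=n_trials)
        cohort = run_cohort(plan, cfg, seed)
        table = cohort_table(cohort)
        vals = _summarize(table, "power_4040")
        est = mean_difference(vals[f"variant:{sv.id}"], vals["control"],
                              n_boot=2000, seed=3)
        out[label] = est.mean_difference
    return out


def structure_summary() -> dict:
    """Structural echoes of the printed default configuration."""
    cfg = default_config()
    net = build_network(cfg, subject_seed=0)
    plan = CohortPlan()
    return {
        "n_exc": net.n_exc,
        "n_inh": net.n_inh,
        "n_drive_free_inh": int(net.no_drive_inh.sum()),
        "simulations_per_condition": plan.n_simulations_per_condition,
        "inter_bout_interval_ms": cfg.drive.inter_bout_interval,
        "gaba_decay_control_ms": cfg.gaba.tau_decay,
    }
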