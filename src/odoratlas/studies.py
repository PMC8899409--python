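"""Canonical validation studies on synthetic data.

Each function runs one closed-loop experiment at its documented study
conditions and returns plain numbers: the permutation-test calibration,
the tuning-parameter recovery, the descriptor-model-vs-control
comparison, the concentration-slope recovery, and the technique
crosstab under a planted sensitivity threshold.  The test suite asserts
on these outputs and the acceptance script reports them; both call the
same code.
"""

from __future__ import annotations

import numpy as np

from . import compare as cmp
from .descriptors import predict_or_responses
from .simulate import SyntheticConfig, generate_database
from .tuning import fit_gaussian_tuning, gaussian_curve, permutation_test_sigma


def permutation_calibration(
    seed: int,
    n_replicates: int = 1000,
    n_pairs: int = 100,
    n_shuffles: int = 200,
    alpha: float = 0.05,
    noise_sd: float = 10.0,
) -> dict:
    """Type-I error of the sigma permutation test on untuned data.

    Each replicate draws property values and responses independently
    (no tuning), runs the permutation test, and rejects at ``alpha``.
    Under the null the p-value is uniform on its 1/n_shuffles grid, so
    the rejection rate should sit near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        x = rng.normal(130.0, 40.0, n_pairs)
        r = rng.normal(0.0, noise_sd, n_pairs)
        fit = permutation_test_sigma(
            np.column_stack([x, r]), n_shuffles=n_shuffles,
            seed=int(rng.integers(2**31)),
        )
        rejections += fit.p_value < alpha
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


def tuning_recovery(
    seed: int,
    n_seeds: int = 50,
    n_pairs: int = 200,
    a: float = 100.0,
    b: float = 130.0,
    sigma: float = 30.0,
    noise_frac: float = 0.1,
) -> dict:
    """Median recovery error of the planted Gaussian center and width.

    Over ``n_seeds`` datasets of ``n_pairs`` pairs with additive noise
    of SD ``noise_frac * a``, fits the tuning curve and reports the
    median relative errors of b and sigma (percent).
    """
    rng = np.random.default_rng(seed)
    b_errs, s_errs = [], []
    for _ in range(n_seeds):
        x = rng.normal(b, 40.0, n_pairs)
        r = gaussian_curve(x, a, b, sigma) + rng.normal(0, noise_frac * a, n_pairs)
        _, b_hat, s_hat = fit_gaussian_tuning(np.column_stack([x, r]))
        b_errs.append(abs(b_hat - b) / b)
        s_errs.append(abs(s_hat - sigma) / sigma)
    return {
        "median_center_error_pct": 100.0 * float(np.median(b_errs)),
        "median_width_error_pct": 100.0 * float(np.median(s_errs)),
        "n_seeds": n_seeds,
        "n_pairs": n_pairs,
    }


def strong_tuning_p(seed: int, n_pairs: int = 200, n_shuffles: int = 1000) -> dict:
    """Permutation p for sharply tuned data (width 0.2 x property range)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(130.0, 40.0, n_pairs)
    sigma_star = 0.2 * float(np.ptp(x))
    r = gaussian_curve(x, 100.0, 130.0, sigma_star) + rng.normal(0, 10.0, n_pairs)
    fit = permutation_test_sigma(
        np.column_stack([x, r]), n_shuffles=n_shuffles, seed=seed
    )
    return {"p_value": fit.p_value, "sigma": fit.sigma, "n_pairs": n_pairs}


def model_vs_control(seed: int, n_odorants: int = 112, n_ors: int = 30) -> dict:
    """Descriptor-model vs shuffled-control comparison on planted data."""
    cfg = SyntheticConfig(seed=seed, n_odorants=n_odorants, n_ors=n_ors)
    db = generate_database(cfg)
    rec = db.records
    en = rec[(rec["data_type"] == "OR") & (rec["technique"] == "empty_neuron")]
    responses = en.pivot_table(
        index="receptor_or_sensillum", columns="odorant_canonical",
        values="response_value",
    )
    result = predict_or_responses(db.descriptors, responses, seed=seed)
    maes_m = [v["mean_abs_error"] for v in result.per_or.values()]
    maes_c = [v["mean_abs_error"] for v in result.control_per_or.values()]
    return {
        "median_r_model": result.median_r(),
        "median_r_control": result.median_r(control=True),
        "sign_rank_p": result.comparison_p,
        "mean_abs_error_model": float(np.mean(maes_m)),
        "mean_abs_error_control": float(np.mean(maes_c)),
        "n_ors": n_ors,
        "n_odorants": n_odorants,
    }


def slope_recovery(seed: int, beta: float = 0.2, n_odorants: int = 200) -> dict:
    """Recovery of the planted PI decline per 10-fold concentration step.

    Uses an isolation config: assay offsets and the OR-count loading are
    zeroed so the adjacent-decade deltas estimate the slope alone (the
    full-default config exercises the joint setting elsewhere).
    """
    cfg = SyntheticConfig(
        seed=seed, n_odorants=n_odorants, concentration_slope=beta,
        assay_offsets={}, or_count_loading=0.0,
    )
    db = generate_database(cfg)
    beh = db.records[
        (db.records["data_type"] == "BEHAVIOR")
        & (db.records["behavioral_context"] == "host_seeking_foraging")
    ]
    pc = cmp.concentration_pair_deltas(beh)
    se = float(pc.pairs["delta"].std(ddof=1) / np.sqrt(pc.n))
    return {
        "mean_delta": pc.mean_delta,
        "se": se,
        "n_pairs": pc.n,
        "p_value": pc.p_value,
        "planted_beta": beta,
    }


def assay_offset_recovery(seed: int, delta: float = -0.3) -> dict:
    """Recovery of the planted landing-assay PI offset."""
    cfg = SyntheticConfig(seed=seed, assay_offsets={"landing": delta})
    db = generate_database(cfg)
    beh = db.records.query(
        "data_type == 'BEHAVIOR' and species == 'Aedes_aegypti' "
        "and behavioral_context == 'host_seeking_foraging'"
    )
    pc = cmp.pair_by_assay_category(beh, cmp.ASSAY_SPLIT_PRESETS["mosquito"])
    return {"mean_delta": pc.mean_delta, "n_pairs": pc.n,
            "planted_delta": delta}


def technique_sensitivity(seed: int, thetas=(0.0, 10.0, 20.0, 40.0)) -> dict:
    """Empty-neuron-responds / oocyte-silent counts vs planted threshold."""
    counts, fractions = [], []
    for theta in thetas:
        cfg = SyntheticConfig(seed=seed, n_odorants=80, n_ors=10,
                              oocyte_threshold=theta)
        db = generate_database(cfg)
        rec = db.records
        en = rec[(rec["data_type"] == "OR")
                 & (rec["technique"] == "empty_neuron")
                 & (rec["species"] == "Aedes_aegypti")]
        oo = rec[(rec["data_type"] == "OR") & (rec["technique"] == "oocyte")]
        ct = cmp.crosstab_techniques(en, oo)
        counts.append(ct.en_nonzero_oo_zero)
        fractions.append(ct.en_nonzero_oo_zero / ct.n_pairs)
    return {
        "thetas": list(thetas),
        "en_nonzero_oo_zero": counts,
        "fractions": fractions,
    }


def oviposition_null(seed: int) -> dict:
    """PI vs independent oviposition correlation on a default database."""
    db = generate_database(SyntheticConfig(seed=seed))
    res = cmp.correlate_pi_oviposition(db.records, "Aedes_aegypti")
    return {"pearson_r": res.pearson_r, "n": res.n, "p_value": res.p_value}


def activation_count_correlation(seed: int) -> dict:
    """OR-activation-count vs PI correlation on a default database."""
    db = generate_database(SyntheticConfig(seed=seed))
    rec = db.records
    sp = "Drosophila_melanogaster"
    en = rec[(rec["data_type"] == "OR") & (rec["technique"] == "empty_neuron")
             & (rec["species"] == sp)]
    beh = rec[(rec["data_type"] == "BEHAVIOR") & (rec["species"] == sp)
              & (rec["behavioral_context"] == "host_seeking_foraging")]
    res = cmp.or_activation_vs_pi(en, beh)
    return {"pearson_r": res.pearson_r, "n": res.n, "p_value": res.p_value}
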