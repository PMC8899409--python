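"""Gaussian tuning of OR responses to physicochemical properties.

Insect ORs tend to respond most strongly to odorants whose molecular
properties (volume, weight, hydrophobicity, ...) lie in a preferred
range.  Tuning to a property x is quantified by fitting

    r(x) = a * exp(-(x - b)^2 / (2 * sigma^2))

to the scatter of (property value, response) pairs — one pair per
OR-odor measurement at a fixed concentration decade — and reading off
sigma, the standard deviation of the fitted Gaussian: smaller sigma
means sharper tuning.  Reliability is assessed with a shuffle null:
responses are permuted against the fixed property values and the
p-value is the fraction of shuffles whose fitted sigma is at most the
observed sigma (a narrow fitted width arising by chance would make the
observed tuning unremarkable).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, EmptySelectionError, FitFailureError
from .records import concentration_decade

#: Decade most frequently used across source studies; the default slice
#: for tuning analyses.
DEFAULT_DECADE = 1e-2


@dataclass(frozen=True)
class TuningFit:
    """Gaussian fit plus permutation p-value for one property."""

    property_name: str
    n: int
    a: float
    b: float
    sigma: float
    p_value: float | None = None
    n_shuffles: int = 0
    seed: int | None = None
    n_shuffle_failures: int = 0

    def __post_init__(self):
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("sigma must be positive for a successful fit")
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "property_name": self.property_name,
            "n": self.n,
            "a": self.a,
            "b": self.b,
            "sigma": self.sigma,
            "p_value": self.p_value,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
            "n_shuffle_failures": self.n_shuffle_failures,
        }


def select_tuning_pairs(
    records: pd.DataFrame,
    properties: pd.DataFrame,
    property_name: str,
    decade: float = DEFAULT_DECADE,
) -> np.ndarray:
    """Collect (property value, response) pairs for one property.

    Keeps empty-neuron OR records (the spikes/s scale; oocyte currents
    live on a different scale and are excluded) whose concentration
    rounds to ``decade`` (fractions or g/mL; dry amounts never match)
    and whose odorant has a value for the property; each OR-odor
    measurement contributes one pair.  Returns an (n, 2) array
    [x, response].
    """
    df = records[
        (records["data_type"] == "OR")
        & (records["technique"] == "empty_neuron")
    ]
    dec = concentration_decade(df["concentration_value"], df["concentration_unit"])
    df = df[np.isclose(10.0 ** dec, decade)]
    if property_name not in properties.columns:
        raise KeyError(f"unknown property {property_name!r}")
    prop = properties[property_name]
    x = df["odorant_canonical"].map(prop)
    keep = x.notna()
    pairs = np.column_stack(
        [x[keep].to_numpy(float), df.loc[keep, "response_value"].to_numpy(float)]
    )
    if len(pairs) == 0:
        raise EmptySelectionError(
            f"no OR-odor pairs at decade {decade:g} with property {property_name!r}"
        )
    return pairs


def eligible_properties(
    properties: pd.DataFrame, odorant_set: set[str] | None = None,
    min_distinct: int = 10,
) -> list[str]:
    """Properties taking at least ``min_distinct`` distinct numeric values.

    Curve fitting on a property with few distinct values (binary flags,
    small counts) is unreliable, so such properties are excluded.  Column
    order is preserved.
    """
    table = properties
    if odorant_set is not None:
        table = table.loc[table.index.intersection(list(odorant_set))]
    out = []
    for name in table.columns:
        values = table[name].dropna()
        if values.nunique() >= min_distinct:
            out.append(name)
    return out


def gaussian_curve(x, a, b, sigma):
    """The tuning-curve model a * exp(-(x-b)^2 / (2 sigma^2))."""
    return a * np.exp(-((x - b) ** 2) / (2.0 * sigma**2))


def fit_gaussian_batch(
    x: np.ndarray,
    responses: np.ndarray,
    max_iter: int = 200,
    xtol: float = 1.49e-8,
    ftol: float = 1.49e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit the Gaussian model to many response vectors sharing one x.

    A damped (Levenberg-Marquardt) Gauss-Newton solver vectorized over
    the batch dimension, so the permutation test's hundreds of shuffle
    fits cost one array pipeline instead of hundreds of solver calls.
    Every fit — observed and shuffled — goes through this same routine,
    which keeps the permutation p-value exchangeable under the null.

    Each problem b minimizes sum_i (a exp(-(x_i-c)^2/(2 s^2)) - r_bi)^2
    from the deterministic, scale-aware start a0 = max r, b0 = x at the
    max, sigma0 = IQR(x)/2.  The parameterization is unconstrained with
    |sigma| reported (the model is even in sigma, so this equals a
    sigma > 0 constraint).  Termination, per problem: relative step
    below ``xtol``, relative cost improvement below ``ftol``, no damped
    step improving the cost (a local minimum), or the ``max_iter``
    budget.  The iteration budget matters for structureless (null) data,
    where the Gaussian family has a flat valley (amplitude drifting up
    while the center leaves the data range) and tolerance-based
    termination alone can walk arbitrarily far; the budget makes the
    procedure total and still deterministic.

    Returns (a, b, sigma, ok) arrays over the batch; ``ok`` is False
    only where the solver produced non-finite or zero-width parameters.
    """
    x = np.asarray(x, float)
    R = np.atleast_2d(np.asarray(responses, float))
    B, N = R.shape
    a0 = R.max(axis=1)
    a0 = np.where(a0 == 0, 1.0, a0)
    b0 = x[R.argmax(axis=1)]
    q75, q25 = np.percentile(x, [75, 25])
    s0 = (q75 - q25) / 2.0
    if s0 <= 0:
        s0 = np.ptp(x) / 10.0
    p = np.stack([a0, b0, np.full(B, s0)], axis=1)
    lam = np.full(B, 1e-3)

    def eval_model(p_sub):
        a = p_sub[:, 0:1]
        b = p_sub[:, 1:2]
        s = p_sub[:, 2:3]
        s = np.where(np.abs(s) < 1e-300, 1e-300, s)
        z = (x[None, :] - b) / s
        with np.errstate(over="ignore", under="ignore"):
            e = np.exp(np.clip(-0.5 * z * z, -745.0, 0.0))
        return a * e, e, z, s[:, 0]

    f, e, z, s = eval_model(p)
    res = f - R
    cost = np.einsum("bn,bn->b", res, res)
    active = np.ones(B, bool)
    eye = np.eye(3)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        aa = p[idx, 0:1]
        ei, zi, si = e[idx], z[idx], s[idx, None]
        J = np.empty((idx.size, N, 3))
        J[:, :, 0] = ei
        J[:, :, 1] = aa * ei * zi / si
        J[:, :, 2] = aa * ei * zi * zi / si
        JTJ = np.einsum("bni,bnj->bij", J, J)
        JTr = np.einsum("bni,bn->bi", J, res[idx])
        diag = np.einsum("bii->bi", JTJ)
        diag = np.where(diag <= 1e-30, 1e-30, diag)
        pend = np.arange(idx.size)
        stepped = np.zeros(idx.size, bool)
        for _attempt in range(30):
            if pend.size == 0:
                break
            gi = idx[pend]
            A = JTJ[pend] + lam[gi, None, None] * (diag[pend][:, :, None] * eye)
            try:
                delta = np.linalg.solve(A, -JTr[pend][..., None])[..., 0]
            except np.linalg.LinAlgError:
                delta = np.linalg.solve(A + 1e-9 * eye, -JTr[pend][..., None])[..., 0]
            p_try = p[gi] + delta
            f_t, e_t, z_t, s_t = eval_model(p_try)
            res_t = f_t - R[gi]
            cost_t = np.einsum("bn,bn->b", res_t, res_t)
            better = cost_t <= cost[gi]
            acc = pend[better]
            ga = idx[acc]
            if ga.size:
                rel_step = np.max(
                    np.abs(delta[better]) / (np.abs(p[ga]) + 1e-12), axis=1
                )
                conv = (rel_step < xtol) | (
                    (cost[ga] - cost_t[better]) <= ftol * (cost[ga] + 1e-30)
                )
                p[ga] = p_try[better]
                e[ga] = e_t[better]
                z[ga] = z_t[better]
                s[ga] = s_t[better]
                res[ga] = res_t[better]
                cost[ga] = cost_t[better]
                lam[ga] = np.maximum(lam[ga] / 3.0, 1e-12)
                stepped[acc] = True
                active[ga[conv]] = False
            rej = pend[~better]
            lam[idx[rej]] *= 4.0
            pend = rej[lam[idx[rej]] <= 1e12]
        active[idx[~stepped]] = False  # no damped step improves: at a minimum
    sigma = np.abs(p[:, 2])
    ok = np.isfinite(p).all(axis=1) & (sigma > 0)
    return p[:, 0], p[:, 1], sigma, ok


def _check_pairs(pairs: np.ndarray) -> np.ndarray:
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 4:
        raise DegenerateFitError("need at least 4 (x, response) pairs")
    if np.ptp(pairs[:, 0]) == 0:
        raise DegenerateFitError("all property values identical")
    return pairs


def fit_gaussian_tuning(pairs: np.ndarray) -> tuple[float, float, float]:
    """Least-squares Gaussian fit; returns (a, b, sigma).

    sigma is the standard deviation of the fitted Gaussian (not the
    sqrt(2)-scaled width some toolboxes use).  Deterministic given the
    data; see :func:`fit_gaussian_batch` for the solver and its
    initialization.
    """
    pairs = _check_pairs(pairs)
    a, b, sigma, ok = fit_gaussian_batch(pairs[:, 0], pairs[None, :, 1])
    a, b, sigma = float(a[0]), float(b[0]), float(sigma[0])
    if not ok[0]:
        raise FitFailureError(
            f"Gaussian fit failed (n={len(pairs)}, a={a}, b={b}, sigma={sigma})"
        )
    return a, b, sigma


def property_seed(global_seed: int, property_name: str) -> int:
    """Per-property shuffle seed derived by hashing the property name.

    Lets properties be tested in any order, or individually, with
    identical shuffle streams.
    """
    return (int(global_seed) ^ zlib.crc32(property_name.encode("utf-8"))) % (2**31)


def _sigmas_for_permutations(x, r, perm_matrix):
    """Fitted sigma for each row of permuted responses; failures -> +inf.

    A failed shuffle fit has no width to compare, so it is scored +inf —
    it can never undercut the observed width, which is the conservative
    choice for the null.  The batch is processed in chunks sized to keep
    the Jacobian workspace around ~100 MB.
    """
    chunk = max(1, int(2e7 / max(1, len(x))))
    sigmas_parts, failures = [], 0
    for start in range(0, len(perm_matrix), chunk):
        _, _, sig, ok = fit_gaussian_batch(x, r[perm_matrix[start:start + chunk]])
        sigmas_parts.append(np.where(ok, sig, np.inf))
        failures += int((~ok).sum())
    return np.concatenate(sigmas_parts), failures


def permutation_test_sigma(
    pairs: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
    property_name: str = "",
    exhaustive: bool = False,
) -> TuningFit:
    """Shuffle test for tuning sharpness.

    Permutes the responses against the fixed property values
    ``n_shuffles`` times and reports p = (# shuffles with sigma_shuffle
    <= sigma_actual) / n_shuffles.  Shuffle fits that fail contribute
    sigma = +inf (they can never undercut the observed width).  With
    ``exhaustive=True`` all n! permutations are enumerated instead of
    sampled (only sensible for tiny n); ``n_shuffles`` is then the
    number of permutations.
    """
    pairs = np.asarray(pairs, dtype=float)
    a, b, sigma_actual = fit_gaussian_tuning(pairs)
    x, r = pairs[:, 0], pairs[:, 1]
    if exhaustive:
        perm_matrix = np.array(list(permutations(range(len(r)))))
        n_shuffles = len(perm_matrix)
    else:
        rng = np.random.default_rng(
            property_seed(seed, property_name) if property_name else seed
        )
        perm_matrix = np.array(
            [rng.permutation(len(r)) for _ in range(n_shuffles)]
        )
    sigmas, failures = _sigmas_for_permutations(x, r, perm_matrix)
    p = float(np.sum(sigmas <= sigma_actual)) / n_shuffles
    return TuningFit(
        property_name=property_name, n=len(pairs), a=a, b=b, sigma=sigma_actual,
        p_value=p, n_shuffles=n_shuffles, seed=seed, n_shuffle_failures=failures,
    )


def tuning_analysis(
    records: pd.DataFrame,
    properties: pd.DataFrame,
    decade: float = DEFAULT_DECADE,
    n_shuffles: int = 1000,
    seed: int = 0,
    property_names: list[str] | None = None,
) -> list[TuningFit]:
    """Run the full per-property tuning analysis.

    Restricts to properties with enough distinct values over the odorants
    actually measured, then fits and permutation-tests each.  Properties
    whose observed fit fails are skipped (they would have no sigma to
    test).
    """
    odorants = set(records.loc[records["data_type"] == "OR", "odorant_canonical"])
    names = property_names or eligible_properties(properties, odorants)
    fits = []
    for name in names:
        try:
            pairs = select_tuning_pairs(records, properties, name, decade)
            fits.append(
                permutation_test_sigma(
                    pairs, n_shuffles=n_shuffles, seed=seed, property_name=name
                )
            )
        except (EmptySelectionError, FitFailureError, DegenerateFitError):
            continue
    return fits
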