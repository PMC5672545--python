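"""Dose/response series construction and statistical-flag decision logic.

For every gene x chemical pair the pipeline builds a dose vector on the
log10 uM scale (vehicle controls get a pseudo-dose one average log10 spacing
below the lowest tested concentration) and a response vector of
log2(normalized count + 0.5) values mean-centered to the vehicle controls.

Three flags decide what happens next:

* overall trend: permutation test of the Pearson correlation between dose
  and response over all points (a moment-corrected approximation of the
  permutation distribution is available as an accelerator);
* control-vs-treatment difference: two-sided Wilcoxon rank-sum;
* treatment-only trend: the same permutation trend test on treatment points.

q-values (BH by default) are computed across genes within each chemical and
flag family, and a fixed decision tree routes each pair to curve fitting,
a maximum-dose POD, or manual review.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc_normalize import PSEUDOCOUNT

ROUTE_POD_MAX = "no_trend_pod_max"
ROUTE_FIT_WILCOXON = "fit_wilcoxon"
ROUTE_FIT_TREND = "fit_trend"
ROUTE_MANUAL = "manual_review"

_EXACT_N_MAX = 8  # full enumeration up to 8! = 40,320 permutations


@dataclass
class DoseResponseSeries:
    """Per gene x chemical dose/response vectors ready for testing/fitting.

    ``dose`` and ``response`` are aligned; controls come first (all at the
    pseudo-dose), then treatments by increasing concentration.  ``response``
    is centered so the control mean is 0; ``control_sd`` is the sample SD of
    the centered control responses (the unit of the POD baseline deviation).
    """

    gene: str
    chemical: str
    dose: np.ndarray
    response: np.ndarray
    is_control: np.ndarray
    n_control: int
    control_sd: float
    pseudo_dose: float
    max_dose: float


def vehicle_pseudo_dose(concentrations_uM: np.ndarray) -> float:
    """Pseudo-dose for vehicle controls: one mean log10 spacing below the
    lowest tested concentration (the lone-dose spacing defaults to 1)."""
    logd = np.log10(np.unique(concentrations_uM))
    spacing = float(np.diff(logd).mean()) if logd.size > 1 else 1.0
    return float(logd.min() - spacing)


def build_series(
    normalized: pd.DataFrame,
    layout: pd.DataFrame,
    gene: str,
    chemical: str,
) -> DoseResponseSeries:
    """Assemble the dose/response series for one gene under one chemical."""
    lay = layout.set_index("sample_id")
    lay = lay.loc[[s for s in normalized.columns if s in lay.index]]
    ctrl_ids = lay.index[lay["is_vehicle"].astype(bool)].tolist()
    trt = lay[(lay["chemical"] == chemical) & ~lay["is_vehicle"].astype(bool)]
    conc = trt["conc_uM"].astype(float)
    if (conc <= 0).any():
        bad = trt.index[conc <= 0].tolist()
        raise ValueError(f"non-positive concentration for treated sample(s) {bad[:5]}")
    if conc.nunique() < 2:
        raise ValueError(f"chemical {chemical!r} has fewer than 2 distinct concentrations")
    if len(ctrl_ids) < 2:
        raise ValueError("need at least 2 vehicle controls")
    pseudo = vehicle_pseudo_dose(conc.to_numpy())
    trt_ids = conc.sort_values(kind="stable").index.tolist()
    ids = ctrl_ids + trt_ids
    dose = np.concatenate(
        [np.full(len(ctrl_ids), pseudo), np.log10(conc.loc[trt_ids].to_numpy())]
    )
    y = np.log2(normalized.loc[gene, ids].to_numpy(dtype=float) + PSEUDOCOUNT)
    ctrl_mean = y[: len(ctrl_ids)].mean()
    y = y - ctrl_mean
    control_sd = float(np.std(y[: len(ctrl_ids)], ddof=1))
    is_control = np.arange(len(ids)) < len(ctrl_ids)
    return DoseResponseSeries(
        gene=gene,
        chemical=chemical,
        dose=dose,
        response=y,
        is_control=is_control,
        n_control=len(ctrl_ids),
        control_sd=control_sd,
        pseudo_dose=pseudo,
        max_dose=float(dose.max()),
    )


# ---------------------------------------------------------------------------
# permutation trend test


def _perm_moments(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Exact permutation moments (var, skew, kurtosis) of the Pearson r
    between ``a`` and a uniformly permuted ``b`` (mean is 0).

    Derived from the combinatorial moments of the linear permutation
    statistic T = sum a_i b_pi(i) with both vectors centered.
    """
    n = a.size
    a = a - a.mean()
    b = b - b.mean()
    A2, A3, A4 = (a**2).sum(), (a**3).sum(), (a**4).sum()
    B2, B3, B4 = (b**2).sum(), (b**3).sum(), (b**4).sum()
    m2 = A2 * B2 / (n - 1)
    m3 = A3 * B3 * n / ((n - 1) * (n - 2))
    m4 = (
        A4 * B4 / n
        + 4 * A4 * B4 / (n * (n - 1))
        + 3 * (A2**2 - A4) * (B2**2 - B4) / (n * (n - 1))
        + 6 * (2 * A4 - A2**2) * (2 * B4 - B2**2) / (n * (n - 1) * (n - 2))
        + (3 * A2**2 - 6 * A4) * (3 * B2**2 - 6 * B4) / (n * (n - 1) * (n - 2) * (n - 3))
    )
    scale = A2 * B2
    var = m2 / scale
    skew = (m3 / scale**1.5) / var**1.5
    kurt = (m4 / scale**2) / var**2
    return var, skew, kurt


def _beta_from_moments(var: float, skew: float, kurt: float):
    """Shifted/scaled beta (Pearson type I) with mean 0 and the given
    variance, skewness and kurtosis; None when outside the beta region."""
    b1 = skew**2
    denom = 6.0 + 3.0 * b1 - 2.0 * kurt
    if denom <= 0:
        return None
    s = 6.0 * (kurt - b1 - 1.0) / denom
    if s <= 0:
        return None
    d2_den = 16.0 * (s + 1.0) + b1 * (s + 2.0) ** 2
    d = math.copysign(math.sqrt(b1 * s**2 * (s + 2.0) ** 2 / d2_den), skew)
    p_shape = (s - d) / 2.0
    q_shape = (s + d) / 2.0
    if p_shape <= 0 or q_shape <= 0:
        return None
    mean0 = p_shape / s
    var0 = p_shape * q_shape / (s**2 * (s + 1.0))
    c = math.sqrt(var / var0)
    return stats.beta(p_shape, q_shape, loc=-c * mean0, scale=c)


def _pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


_COSET_MAX = 3_000_000  # cap on enumerated distinct assignments


def _coset_plan(a: np.ndarray) -> np.ndarray | None:
    """Centered weights for singleton-dose slots when the dose vector is one
    tied block (e.g. shared vehicle controls) plus <=4 singleton doses.

    In that design the permutation statistic depends only on which responses
    occupy the singleton slots, so the null has just n(n-1)...(n-k+1)
    distinct assignments and can be enumerated exactly.  Returns the slot
    weights (w_t - c0) or None when the design does not decompose.
    """
    ac = a - a.mean()
    vals, counts = np.unique(ac, return_counts=True)
    singles = vals[counts == 1]
    tied = vals[counts > 1]
    k = singles.size
    if tied.size > 1 or k == 0 or k > 4 or a.size**k > _COSET_MAX:
        return None
    c0 = float(tied[0]) if tied.size else 0.0
    if tied.size == 0 and k != a.size:
        return None
    return singles - c0


def _coset_stats(alphas: np.ndarray, bc: np.ndarray) -> np.ndarray:
    """|T| over all distinct assignments of responses to singleton slots."""
    n = bc.size
    k = alphas.size
    shape = [1] * k
    t = np.zeros((1,) * k)
    for axis in range(k):
        s = shape.copy()
        s[axis] = n
        t = t + (alphas[axis] * bc).reshape(s)
    if k > 1:  # mask tuples that reuse a response
        idx = np.arange(n)
        distinct = np.ones((n,) * k, dtype=bool)
        for i in range(k):
            for j in range(i + 1, k):
                si, sj = [1] * k, [1] * k
                si[i] = n
                sj[j] = n
                distinct &= idx.reshape(si) != idx.reshape(sj)
        return np.abs(t[distinct])
    return np.abs(t).ravel()


def trend_test(
    dose: np.ndarray,
    response: np.ndarray,
    mode: str = "auto",
    n_mc: int = 10_000,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Two-sided permutation p-value for a dose-response trend.

    The statistic is the Pearson correlation between dose and response; the
    null is the uniform permutation of the response vector.  Modes:

    * ``permutation_exact`` — exact null: full enumeration for n <= 8, or
      enumeration over the distinct response-to-slot assignments when the
      dose vector is one tied block plus a few singleton doses (the shared
      vehicle-control design), which stays exact at any n;
    * ``permutation_mc`` — seeded Monte Carlo (``n_mc`` draws, add-one p);
    * ``moment_approx`` — moment-corrected approximation: the permutation
      distribution's first four moments are matched by a shifted/scaled
      beta; falls back to enumeration below n = 5;
    * ``auto`` — exact whenever feasible, Monte Carlo otherwise.

    A constant response returns p = 1 by convention.
    """
    a = np.asarray(dose, dtype=float)
    b = np.asarray(response, dtype=float)
    n = a.size
    if n < 3 or b.size != n:
        raise ValueError("need >=3 aligned points")
    if np.ptp(a) == 0:
        raise ValueError("dose vector is constant")
    if np.ptp(b) == 0:
        return 1.0
    ac = a - a.mean()
    bc = b - b.mean()
    t_obs = abs(float(ac @ bc))
    tol = 1e-9 * math.sqrt((ac**2).sum() * (bc**2).sum())

    alphas = _coset_plan(a) if mode in ("auto", "permutation_exact") else None
    if mode == "auto":
        mode = (
            "permutation_exact"
            if (n <= _EXACT_N_MAX or alphas is not None)
            else "permutation_mc"
        )
    if mode == "moment_approx" and n < 5:
        mode = "permutation_exact"
        alphas = _coset_plan(a)

    if mode == "permutation_exact":
        if alphas is not None and n > _EXACT_N_MAX:
            t_all = _coset_stats(alphas, bc)
            return float(np.mean(t_all >= t_obs - tol))
        if n > _EXACT_N_MAX:
            raise ValueError(
                f"exact enumeration limited to n <= {_EXACT_N_MAX} "
                "unless the dose vector decomposes into a tied block plus singletons"
            )
        perms = np.array(list(permutations(range(n))))
        t_all = np.abs(bc[perms] @ ac)
        return float(np.mean(t_all >= t_obs - tol))
    if mode == "permutation_mc":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        order = np.argsort(rng.random((n_mc, n)), axis=1)
        t_all = np.abs(bc[order] @ ac)
        return float((1 + (t_all >= t_obs - tol).sum()) / (n_mc + 1))
    if mode == "moment_approx":
        var, skew, kurt = _perm_moments(a, b)
        r_obs = abs(_pearson_r(a, b))
        dist = _beta_from_moments(var, skew, kurt)
        if dist is None:  # outside beta region: normal approximation
            dist = stats.norm(0.0, math.sqrt(var))
        return float(min(1.0, dist.sf(r_obs) + dist.cdf(-r_obs)))
    raise ValueError(f"unknown trend-test mode {mode!r}")


def wilcoxon_test(control: np.ndarray, treatment: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for controls vs treatments.

    Exact enumeration when min(n, m) <= 10 and there are no ties; normal
    approximation with midranks, tie correction and continuity correction
    otherwise.
    """
    x = np.asarray(control, dtype=float)
    y = np.asarray(treatment, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def qvalues(p: np.ndarray | pd.Series, method: str = "bh") -> np.ndarray:
    """FDR q-values: BH step-up by default, Storey's pi0-scaled BH optionally.

    NA p-values propagate and are excluded from the adjustment family.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        return q
    q_ok = multipletests(p[ok], method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, float((p[ok] > 0.5).mean()) / 0.5) if ok.sum() else 1.0
        q_ok = np.minimum(q_ok * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown q-value method {method!r}")
    q[ok] = q_ok
    return q


def route(q_overall: float, q_wilcox: float, q_trt: float, threshold: float = 0.05) -> str:
    """Decision tree for one gene x chemical pair.

    No overall trend -> POD is the maximum tested dose.  Otherwise fit if
    controls differ from treatments (Wilcoxon), else fit if the
    treatment-only trend is significant, else send to manual review.
    """
    if not (q_overall < threshold):
        return ROUTE_POD_MAX
    if q_wilcox < threshold:
        return ROUTE_FIT_WILCOXON
    if q_trt < threshold:
        return ROUTE_FIT_TREND
    return ROUTE_MANUAL


def compute_flags(
    normalized: pd.DataFrame,
    layout: pd.DataFrame,
    chemical: str,
    genes: list[str] | None = None,
    q_threshold: float = 0.05,
    trend_mode: str = "auto",
    n_mc: int = 10_000,
    seed: int = 0,
    q_method: str = "bh",
    family: str = "hierarchical",
) -> pd.DataFrame:
    """Flag table for every gene under one chemical.

    Trend and Wilcoxon p-values are computed per gene and FDR-adjusted
    across genes within each flag family, then routed through the decision
    tree.  With the default ``hierarchical`` family the adjustment follows
    the tree: q_overall over all genes, q_wilcox over the genes whose
    overall trend passed, q_trt over the genes the Wilcoxon stage did not
    settle.  This matters for small single-replicate designs, where the
    exact Wilcoxon p-value has a hard floor (2/C(n+m, m)) that a
    genome-wide adjustment could never push below the threshold.
    ``family="flat"`` adjusts each family over all genes instead.
    """
    if genes is None:
        genes = normalized.index.tolist()
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        s = build_series(normalized, layout, gene, chemical)
        trt = ~s.is_control
        p_overall = trend_test(s.dose, s.response, trend_mode, n_mc, rng)
        # treatment-only trend needs >=3 points and a nonconstant dose
        if trt.sum() >= 3 and np.ptp(s.dose[trt]) > 0:
            p_trt = trend_test(s.dose[trt], s.response[trt], trend_mode, n_mc, rng)
        else:
            p_trt = np.nan
        p_wilcox = wilcoxon_test(s.response[s.is_control], s.response[trt])
        rows.append(
            {"gene": gene, "p_overall": p_overall, "p_trt": p_trt, "p_wilcox": p_wilcox}
        )
    out = pd.DataFrame(rows).set_index("gene")
    out["q_overall"] = qvalues(out["p_overall"], method=q_method)
    if family == "hierarchical":
        passed = out["q_overall"] < q_threshold
        for fam in ("wilcox", "trt"):
            q = np.full(len(out), np.nan)
            if fam == "trt":
                stage = passed & ~(out["q_wilcox"] < q_threshold)
            else:
                stage = passed
            q[stage.to_numpy()] = qvalues(out.loc[stage, f"p_{fam}"], method=q_method)
            out[f"q_{fam}"] = q
    elif family == "flat":
        for fam in ("wilcox", "trt"):
            out[f"q_{fam}"] = qvalues(out[f"p_{fam}"], method=q_method)
    else:
        raise ValueError(f"unknown q-value family {family!r}")
    out["route"] = [
        route(
            r.q_overall,
            r.q_wilcox if np.isfinite(r.q_wilcox) else 1.0,
            r.q_trt if np.isfinite(r.q_trt) else 1.0,
            q_threshold,
        )
        for r in out.itertuples()
    ]
    out.insert(0, "chemical", chemical)
    return out
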