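"""Survival analysis of mitochondrial mutational features.

Univariate Cox scans over binary region features, multivariable adjustment
for clinical covariates, nuclear×mitochondrial synergy grouping, and the
leave-one-out cross-validated three-class mtSNV risk signature.

The log-rank test and single-binary-covariate Cox model are implemented
directly on risk-table arrays: the LOOCV signature refits a univariate scan
for every held-out patient, which calls these primitives thousands of times.
They are cross-checked against lifelines in the test suite; multivariable
models and Kaplan–Meier estimates go through lifelines itself.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats as sps

CONFLICT_RULES = ("high_dominates", "low_dominates", "exclude")


@dataclass(frozen=True)
class CoxResult:
    """Hazard ratio with Wald confidence interval and test p-values."""

    feature: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float          # Wald
    logrank_p: float | None = None
    ten_year_survival_change: float | None = None  # percentage points
    n_mutated: int | None = None
    flags: tuple[str, ...] = ()


@dataclass
class SignatureResult:
    """Three-class risk assignment plus the Cox contrasts that describe it."""

    classes: pd.Series  # patient_id -> {low, intermediate, high}
    low_vs_intermediate: CoxResult | None
    high_vs_intermediate: CoxResult | None
    low_features: dict[str, int] = field(default_factory=dict)   # selection counts
    high_features: dict[str, int] = field(default_factory=dict)
    n_folds: int = 0
    empty_folds: int = 0

    @property
    def consensus_low(self) -> set[str]:
        cut = max(1, self.n_folds) / 2
        return {f for f, c in self.low_features.items() if c > cut}

    @property
    def consensus_high(self) -> set[str]:
        cut = max(1, self.n_folds) / 2
        return {f for f, c in self.high_features.items() if c > cut}


# ---------------------------------------------------------------------------
# risk-table primitives


def _risk_table(time: np.ndarray, event: np.ndarray, x: np.ndarray):
    """Per-distinct-event-time risk counts (n, n1, d, d1) for binary *x*."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order].astype(bool)
    xs = x[order].astype(float)
    n_total = len(t)
    # suffix counts: number (and group-1 number) at risk just before index i
    suffix_n1 = np.cumsum(xs[::-1])[::-1]
    first = np.r_[True, t[1:] != t[:-1]]
    starts = np.flatnonzero(first)
    d = np.add.reduceat(e.astype(float), starts)
    d1 = np.add.reduceat(e * xs, starts)
    keep = d > 0
    n_at_risk = (n_total - starts)[keep]
    n1_at_risk = suffix_n1[starts][keep]
    return n_at_risk.astype(float), n1_at_risk, d[keep], d1[keep]


def logrank_binary(time, event, x) -> tuple[float, float]:
    """Two-group log-rank test; returns (signed z, p).

    z > 0 means the x = 1 group has more events than expected (HR > 1).
    """
    n, n1, d, d1 = _risk_table(np.asarray(time, float), np.asarray(event),
                               np.asarray(x))
    o_minus_e = float(np.sum(d1 - d * n1 / n))
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * (n1 / n) * (1 - n1 / n) * np.where(n > 1, (n - d) / (n - 1), 0.0)
    var = float(np.sum(v))
    if var <= 0:
        return 0.0, 1.0
    z = o_minus_e / np.sqrt(var)
    return z, float(sps.chi2.sf(z * z, 1))


def logrank_many(time, event, X) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized log-rank over the columns of binary matrix *X* (n × k)."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    X = np.asarray(X, float)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order].astype(bool)
    Xs = X[order]
    n_total = len(t)
    suffix_n1 = np.cumsum(Xs[::-1], axis=0)[::-1]
    first = np.r_[True, t[1:] != t[:-1]]
    starts = np.flatnonzero(first)
    d = np.add.reduceat(e.astype(float), starts)
    d1 = np.add.reduceat(e[:, None] * Xs, starts, axis=0)
    keep = d > 0
    n = (n_total - starts)[keep].astype(float)[:, None]
    n1 = suffix_n1[starts][keep]
    d_k = d[keep][:, None]
    d1_k = d1[keep]
    o_minus_e = np.sum(d1_k - d_k * n1 / n, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n > 1, (n - d_k) / np.maximum(n - 1, 1), 0.0)
    var = np.sum(d_k * (n1 / n) * (1 - n1 / n) * frac, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, o_minus_e / np.sqrt(var), 0.0)
    p = sps.chi2.sf(z * z, 1)
    return z, p


def cox_binary(time, event, x, max_iter: int = 50, tol: float = 1e-9):
    """Univariate Cox PH fit for a single binary covariate (Breslow ties).

    Returns (beta, se, flags).  A monotone partial likelihood (no events in
    one group) is capped at |beta| = 20 and flagged ``separated``.
    """
    n, n1, d, d1 = _risk_table(np.asarray(time, float), np.asarray(event),
                               np.asarray(x))
    n0 = n - n1
    beta, flags = 0.0, []
    for _ in range(max_iter):
        eb = np.exp(beta)
        s0 = n0 + n1 * eb
        mu = n1 * eb / s0
        grad = float(np.sum(d1 - d * mu))
        hess = float(-np.sum(d * mu * (1 - mu)))
        if hess == 0:
            flags.append("degenerate")
            break
        step = -grad / hess
        beta += np.clip(step, -5.0, 5.0)
        if abs(beta) > 20.0:
            beta = np.sign(beta) * 20.0
            flags.append("separated")
            break
        if abs(step) < tol:
            break
    eb = np.exp(beta)
    mu = n1 * eb / (n0 + n1 * eb)
    info = float(np.sum(d * mu * (1 - mu)))
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    return beta, se, tuple(flags)


def _cox_result(feature: str, time, event, x,
                horizon: float | None = None,
                with_logrank: bool = True) -> CoxResult:
    beta, se, flags = cox_binary(time, event, x)
    hr = float(np.exp(beta))
    if np.isfinite(se):
        with np.errstate(over="ignore"):
            ci_low = float(np.exp(beta - 1.959963984540054 * se))
            ci_high = float(np.exp(beta + 1.959963984540054 * se))
        p = float(2 * sps.norm.sf(abs(beta) / se))
    else:
        ci_low, ci_high, p = 0.0, float("inf"), 1.0
    lr_p = logrank_binary(time, event, x)[1] if with_logrank else None
    change = None
    if horizon is not None:
        change = ten_year_survival_change(time, event, x, horizon)
    return CoxResult(feature=feature, hazard_ratio=hr, ci_low=ci_low,
                     ci_high=ci_high, p_value=p, logrank_p=lr_p,
                     ten_year_survival_change=change,
                     n_mutated=int(np.sum(np.asarray(x) > 0)), flags=flags)


# ---------------------------------------------------------------------------
# Kaplan–Meier helpers


def km_table(time, event) -> pd.DataFrame:
    """Kaplan–Meier estimate as a (time, at_risk, survival) table."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    surv = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"]
    out = pd.DataFrame({
        "time": surv.index.values,
        "at_risk": at_risk.reindex(surv.index).ffill().values,
        "survival": surv.iloc[:, 0].values,
    })
    return out


def km_survival_at(time, event, horizon: float) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    return float(kmf.predict(horizon))


def ten_year_survival_change(time, event, x, horizon: float = 120.0) -> float:
    """KM survival difference (mutated − unmutated) at *horizon*, in points."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    x = np.asarray(x) > 0
    if x.all() or (~x).all():
        return float("nan")
    s1 = km_survival_at(time[x], event[x], horizon)
    s0 = km_survival_at(time[~x], event[~x], horizon)
    return 100.0 * (s1 - s0)


# ---------------------------------------------------------------------------
# operations


def _align(matrix: pd.DataFrame, outcomes: pd.DataFrame):
    out = outcomes.set_index("patient_id") if "patient_id" in outcomes else outcomes
    common = matrix.index.intersection(out.index)
    if len(common) == 0:
        raise ValueError("no patients shared between matrix and outcomes")
    out = out.loc[common]
    return (matrix.loc[common], out["time"].to_numpy(float),
            out["event"].to_numpy(int))


def scan_features(matrix: pd.DataFrame) -> list[str]:
    """Binary features scanned by default: regions plus derived dichotomies."""
    skip = {"mtSNV_count", "MCN"}
    feats = [c for c in matrix.columns
             if c not in skip and set(pd.unique(matrix[c].dropna())) <= {0, 1}]
    return feats


def feature_cox_scan(matrix: pd.DataFrame, outcomes: pd.DataFrame,
                     features: list[str] | None = None,
                     min_mutated: int = 2,
                     horizon: float = 120.0,
                     include_derived: bool = True) -> list[CoxResult]:
    """Univariate Cox scan over binary mitochondrial features.

    With *include_derived*, MCN (median-dichotomized as ``MCN_high``) and
    mtSNV burden (0 vs ≥1 as ``mtSNV_any``) are appended when the numeric
    columns are present.  Features mutated in fewer than *min_mutated*
    patients (or in all patients) are dropped.
    """
    m, time, event = _align(matrix, outcomes)
    if event.sum() == 0:
        raise ValueError("no events in cohort")
    m = m.copy()
    if features is None:
        features = scan_features(m)
    else:
        features = list(features)
    if include_derived:
        if "MCN" in m.columns and m["MCN"].notna().any() and \
                "MCN_high" not in features:
            m["MCN_high"] = (m["MCN"] > m["MCN"].median()).astype(int)
            features.append("MCN_high")
        if "mtSNV_count" in m.columns and "mtSNV_any" not in features:
            m["mtSNV_any"] = (m["mtSNV_count"] >= 1).astype(int)
            features.append("mtSNV_any")
    results = []
    for feat in features:
        x = m[feat].to_numpy(float)
        n1 = int(np.sum(x > 0))
        if n1 < min_mutated or n1 > len(x) - 1:
            continue
        results.append(_cox_result(feat, time, event, x, horizon=horizon))
    return results


_T_ORDER = {"T1": 1, "T2": 2, "T3": 3, "T4": 4}


def multivariable_cox(feature: str, matrix: pd.DataFrame,
                      outcomes: pd.DataFrame,
                      adjusters: tuple[str, ...] = ("age", "psa", "t_category",
                                                    "gleason")) -> CoxResult:
    """Adjusted HR for *feature*, controlling for clinical covariates.

    T-category and Gleason Score enter as ordered numeric codes.  Adjusters
    with a single observed level are dropped with a warning.
    """
    m, time, event = _align(matrix, outcomes)
    df = pd.DataFrame({"time": time, "event": event,
                       feature: m[feature].to_numpy(float)}, index=m.index)
    kept = []
    for adj in adjusters:
        if adj not in m.columns:
            raise ValueError(f"adjuster {adj!r} missing from matrix")
        col = m[adj]
        if adj == "t_category":
            col = col.map(_T_ORDER)
        col = pd.to_numeric(col)
        if col.nunique(dropna=True) < 2:
            warnings.warn(f"adjuster {adj!r} has a single level; dropped")
            continue
        df[adj] = col
        kept.append(adj)
    df = df.dropna()
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    flags = []
    corr = df[kept].corr().abs() if len(kept) > 1 else None
    if corr is not None and (corr.where(~np.eye(len(kept), dtype=bool)) > 0.95).any().any():
        flags.append("collinear_adjusters")
    s = cph.summary.loc[feature]
    return CoxResult(feature=feature,
                     hazard_ratio=float(s["exp(coef)"]),
                     ci_low=float(s["exp(coef) lower 95%"]),
                     ci_high=float(s["exp(coef) upper 95%"]),
                     p_value=float(s["p"]),
                     n_mutated=int((df[feature] > 0).sum()),
                     flags=tuple(flags))


def synergy_groups(matrix: pd.DataFrame, outcomes: pd.DataFrame,
                   nuclear_feature: str = "MYC_gain",
                   mito_feature: str = "OHR") -> dict:
    """Partition patients by joint nuclear/mito carriage and compare survival.

    Groups: *neither*, *either* (exactly one of the two), *both*.  Returns
    the assignment, per-group KM tables, and pairwise log-rank p-values.
    Empty groups are reported without a curve.
    """
    for f in (nuclear_feature, mito_feature):
        if f not in matrix.columns:
            raise ValueError(f"feature {f!r} not in matrix")
    m, time, event = _align(matrix, outcomes)
    a = m[nuclear_feature].to_numpy(float) > 0
    b = m[mito_feature].to_numpy(float) > 0
    labels = np.where(a & b, "both", np.where(a | b, "either", "neither"))
    groups = pd.Series(labels, index=m.index, name="group")
    km = {}
    for g in ("neither", "either", "both"):
        mask = labels == g
        km[g] = km_table(time[mask], event[mask]) if mask.any() else None
    pairwise = {}
    for g1, g2 in (("neither", "either"), ("neither", "both"), ("either", "both")):
        mask = (labels == g1) | (labels == g2)
        if (labels == g1).any() and (labels == g2).any():
            _, p = logrank_binary(time[mask], event[mask],
                                  (labels[mask] == g2).astype(float))
        else:
            p = None
        pairwise[(g1, g2)] = p
    return {"groups": groups, "km": km, "pairwise_logrank_p": pairwise}


def _classify(carries_low: bool, carries_high: bool, conflict_rule: str) -> str:
    if conflict_rule not in CONFLICT_RULES:
        raise ValueError(f"unknown conflict rule {conflict_rule!r}")
    if carries_low and carries_high:
        return {"high_dominates": "high", "low_dominates": "low",
                "exclude": "intermediate"}[conflict_rule]
    if carries_high:
        return "high"
    if carries_low:
        return "low"
    return "intermediate"


def _class_contrasts(classes: pd.Series, time, event):
    res = {}
    for side in ("low", "high"):
        mask = (classes == side) | (classes == "intermediate")
        if (classes == side).sum() == 0 or (classes == "intermediate").sum() == 0:
            res[side] = None
            continue
        x = (classes[mask] == side).astype(float).to_numpy()
        res[side] = _cox_result(f"{side}_vs_intermediate", time[mask.to_numpy()],
                                event[mask.to_numpy()], x, with_logrank=True)
    return res["low"], res["high"]


def loocv_signature(matrix: pd.DataFrame, outcomes: pd.DataFrame,
                    features: list[str] | None = None,
                    selection_p_threshold: float = 0.05,
                    conflict_rule: str = "high_dominates",
                    min_mutated: int = 2) -> SignatureResult:
    """Leave-one-out cross-validated three-class mtSNV risk signature.

    For each held-out patient the remaining n−1 patients are scanned with a
    univariate log-rank selection (p < threshold); selected features split by
    hazard direction into protective and adverse sets, and the held-out
    patient is classified by carriage (low / intermediate / high,
    *conflict_rule* governing mixed carriage).  The procedure is
    deterministic: no randomness beyond the data.
    """
    m, time, event = _align(matrix, outcomes)
    if features is None:
        features = scan_features(m)
    X = m[features].to_numpy(float)
    n = len(m)
    classes = []
    low_counts: dict[str, int] = {}
    high_counts: dict[str, int] = {}
    empty_folds = 0
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xt = X[tr]
        n1 = Xt.sum(axis=0)
        ok = (n1 >= min_mutated) & (n1 <= tr.sum() - 1)
        if not ok.any():
            empty_folds += 1
            classes.append("intermediate")
            continue
        z, p = logrank_many(time[tr], event[tr], Xt[:, ok])
        names = [f for f, k in zip(features, ok) if k]
        sel_low = {f for f, zz, pp in zip(names, z, p)
                   if pp < selection_p_threshold and zz < 0}
        sel_high = {f for f, zz, pp in zip(names, z, p)
                    if pp < selection_p_threshold and zz > 0}
        for f in sel_low:
            low_counts[f] = low_counts.get(f, 0) + 1
        for f in sel_high:
            high_counts[f] = high_counts.get(f, 0) + 1
        if not sel_low and not sel_high:
            empty_folds += 1
            classes.append("intermediate")
            continue
        carried = {f for f, v in zip(features, X[i]) if v > 0}
        classes.append(_classify(bool(carried & sel_low),
                                 bool(carried & sel_high), conflict_rule))
    classes = pd.Series(classes, index=m.index, name="risk_class")
    low_res, high_res = _class_contrasts(classes, time, event)
    return SignatureResult(classes=classes, low_vs_intermediate=low_res,
                           high_vs_intermediate=high_res,
                           low_features=low_counts, high_features=high_counts,
                           n_folds=n, empty_folds=empty_folds)


def fixed_signature(matrix: pd.DataFrame, outcomes: pd.DataFrame,
                    low: set[str] = frozenset({"CO3", "HV1"}),
                    high: set[str] = frozenset({"OHR"}),
                    conflict_rule: str = "high_dominates") -> SignatureResult:
    """Three-class assignment from a fixed protective/adverse feature split."""
    m, time, event = _align(matrix, outcomes)
    unknown = (set(low) | set(high)) - set(m.columns)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    classes = []
    for _, row in m.iterrows():
        carried = {f for f in set(low) | set(high) if row[f] > 0}
        classes.append(_classify(bool(carried & set(low)),
                                 bool(carried & set(high)), conflict_rule))
    classes = pd.Series(classes, index=m.index, name="risk_class")
    low_res, high_res = _class_contrasts(classes, time, event)
    return SignatureResult(classes=classes, low_vs_intermediate=low_res,
                           high_vs_intermediate=high_res,
                           low_features={f: 1 for f in low},
                           high_features={f: 1 for f in high}, n_folds=1)
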