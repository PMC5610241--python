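"""Cohort-level statistics on somatic mitochondrial variation.

Builds the patients × features matrix (22 mitochondrial mutational features:
13 protein-coding genes, 2 rRNAs, the tRNAs as one group, the control region,
three control subregions, mtSNV count and MCN), and provides the cohort
tests: a permutation test for excess zero-burden patients, the
continuity-corrected two-proportion test, binomial-family burden association
fits, the nuclear×mitochondrial Spearman association matrix with
Benjamini–Hochberg q-values, and the ΔHF-threshold sensitivity sweep.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .calling import MtSNV, call_mtsnvs, HeteroplasmyRecord
from .reference import MitoAnnotation, PROTEIN_GENES, RRNA_GENES

DEFAULT_SUBREGION_FEATURES = ("HV1", "OHR", "CSB1")


def mito_feature_names(subregions: Sequence[str] = DEFAULT_SUBREGION_FEATURES,
                       ) -> list[str]:
    """The 22 mitochondrial mutational features, in reporting order."""
    return (list(PROTEIN_GENES) + list(RRNA_GENES) + ["tRNA", "control_region"]
            + list(subregions) + ["mtSNV_count", "MCN"])


def build_feature_matrix(calls_by_patient: Mapping[str, Sequence[MtSNV]],
                         annotation: MitoAnnotation,
                         nuclear: pd.DataFrame | None = None,
                         clinical: pd.DataFrame | None = None,
                         mcn_by_patient: Mapping[str, float] | None = None,
                         subregions: Sequence[str] = DEFAULT_SUBREGION_FEATURES,
                         ) -> pd.DataFrame:
    """Patients × (mito features + nuclear features + clinical) matrix.

    A gene/region feature is 1 iff ≥1 called mtSNV lies in that region;
    membership is positional, so a subregion hit automatically sets every
    enclosing region (a CSB1 mtSNV is an OHR and a control-region mtSNV).
    mtSNV count and MCN are numeric.  Patients present in the calls but
    absent from the clinical table are kept with missing clinical values
    (and a warning); clinical-only patients are kept with zero features.
    """
    features = mito_feature_names(subregions)
    region_feats = [f for f in features if f not in ("mtSNV_count", "MCN")]
    trna_names = {r.name for r in annotation.regions if r.region_class == "tRNA"}

    patient_ids = list(calls_by_patient)
    if clinical is not None:
        known = set(clinical["patient_id"])
        orphans = [p for p in patient_ids if p not in known]
        if orphans:
            warnings.warn(f"{len(orphans)} patients absent from clinical table "
                          "(kept; excluded from clinical analyses)")
        patient_ids += [p for p in clinical["patient_id"] if p not in calls_by_patient]

    rows = []
    for pid in patient_ids:
        calls = calls_by_patient.get(pid, ())
        hit: set[str] = set()
        for c in calls:
            hit |= c.regions
            if c.regions & trna_names:
                hit.add("tRNA")
        row = {f: int(f in hit) for f in region_feats}
        row["mtSNV_count"] = len(calls)
        row["MCN"] = (mcn_by_patient or {}).get(pid, np.nan)
        rows.append(row)
    matrix = pd.DataFrame(rows, index=pd.Index(patient_ids, name="patient_id"))
    matrix = matrix[features]

    if nuclear is not None:
        matrix = matrix.join(nuclear.set_index("patient_id"), how="left")
    if clinical is not None:
        matrix = matrix.join(
            clinical.set_index("patient_id").drop(columns=["cohort"],
                                                  errors="ignore"), how="left")
    return matrix


def zero_burden_permutation_test(burdens: Sequence[int],
                                 n_permutations: int = 100_000,
                                 seed: int | None = None,
                                 weighting: str = "uniform",
                                 mcn: Sequence[float] | None = None) -> float:
    """Permutation test for more zero-mtSNV patients than expected by chance.

    Null: the observed total number of mtSNVs is re-assigned to patients as a
    multinomial draw, uniformly or with probability ∝ MCN; the statistic is
    the number of burden-zero patients.  Returns
    ``(1 + #{null ≥ observed}) / (1 + n_permutations)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    burdens = np.asarray(burdens, dtype=int)
    if (burdens < 0).any():
        raise ValueError("burdens must be non-negative")
    total = int(burdens.sum())
    if total == 0:
        raise ValueError("total burden must be positive")
    n = len(burdens)
    if weighting == "uniform":
        probs = np.full(n, 1.0 / n)
    elif weighting == "mcn":
        if mcn is None:
            raise ValueError("weighting='mcn' requires mcn values")
        mcn = np.asarray(mcn, dtype=float)
        probs = mcn / mcn.sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    observed = int((burdens == 0).sum())
    rng = np.random.default_rng(seed)
    exceed = 0
    batch = max(1, min(n_permutations, 20_000_000 // max(n, 1)))
    remaining = n_permutations
    while remaining > 0:
        b = min(batch, remaining)
        draws = rng.multinomial(total, probs, size=b)
        exceed += int(((draws == 0).sum(axis=1) >= observed).sum())
        remaining -= b
    return (1 + exceed) / (1 + n_permutations)


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided test of equal proportions (chi-square, Yates continuity).

    Matches R's ``prop.test`` default, e.g. 117/164 vs 85/220 gives
    p = 4.22e-10.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group size must be positive")
        if not 0 <= x <= n:
            raise ValueError("successes must be within [0, n]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table.sum(axis=0).min() == 0:  # degenerate margin: proportions equal
        return 1.0
    res = sps.chi2_contingency(table, correction=True)
    return float(res.pvalue)


def burden_association(presence: Sequence[int], covariate: Sequence[float]):
    """Binomial-family GLM of mtSNV presence on a covariate.

    Returns (slope_sign, p_value, slope, separated).  Complete separation is
    flagged and the Wald p reported as the boundary value ``nan``.
    """
    y = np.asarray(presence, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("covariate must take >= 2 distinct values")
    if len(np.unique(y)) < 2:
        raise ValueError("presence is constant; association undefined")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    separated = abs(slope) > 15 or se > 100
    p = float("nan") if separated else float(fit.pvalues[1])
    return int(np.sign(slope)), p, slope, separated


def association_matrix(matrix: pd.DataFrame,
                       mito_features: Sequence[str],
                       nuclear_features: Sequence[str],
                       min_n: int = 3) -> pd.DataFrame:
    """Spearman correlation of every (mito, nuclear) feature pair.

    Pairwise-complete patients; Benjamini–Hochberg q-values across all
    defined pairs.  Zero-variance pairs are reported with missing rho.
    """
    rows = []
    for mf in mito_features:
        for nf in nuclear_features:
            sub = matrix[[mf, nf]].dropna()
            n = len(sub)
            if n < min_n or sub[mf].nunique() < 2 or sub[nf].nunique() < 2:
                rows.append((mf, nf, np.nan, np.nan, n))
                continue
            rho, p = sps.spearmanr(sub[mf], sub[nf])
            rows.append((mf, nf, float(rho), float(p), n))
    out = pd.DataFrame(rows, columns=["mito_feature", "nuclear_feature",
                                      "rho", "p_value", "n"])
    out["q_value"] = np.nan
    defined = out["p_value"].notna()
    if defined.any():
        out.loc[defined, "q_value"] = multipletests(
            out.loc[defined, "p_value"], method="fdr_bh")[1]
    return out


def threshold_sensitivity(tumor_records: Mapping[str, Sequence[HeteroplasmyRecord]],
                          normal_records: Mapping[str, Sequence[HeteroplasmyRecord]],
                          cellularity: Mapping[str, float],
                          annotation: MitoAnnotation,
                          pairs: Sequence[tuple[str, str]],
                          nuclear: pd.DataFrame,
                          thresholds: Sequence[float] = (0.1, 0.2, 0.3, 0.4,
                                                         0.5, 0.6),
                          mcn_by_patient: Mapping[str, float] | None = None,
                          min_depth: int = 100) -> pd.DataFrame:
    """Re-call variants at increasing ΔHF cutoffs and track selected correlations.

    Calls once at the lowest threshold and filters by ΔHF for the higher
    cutoffs (call sets are nested in the threshold), then rebuilds the
    feature matrix and recomputes the Spearman correlation for each selected
    (mito, nuclear) pair.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if any(t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    base_calls = {
        pid: call_mtsnvs(tumor_records[pid], normal_records[pid],
                         cellularity.get(pid, 1.0), annotation,
                         delta_hf_threshold=thresholds[0], min_depth=min_depth)
        for pid in tumor_records}
    rows = []
    for t in thresholds:
        calls_t = {pid: [c for c in calls if c.delta_hf >= t]
                   for pid, calls in base_calls.items()}
        matrix = build_feature_matrix(calls_t, annotation, nuclear=nuclear,
                                      mcn_by_patient=mcn_by_patient)
        for mf, nf in pairs:
            sub = matrix[[mf, nf]].dropna()
            if sub[mf].nunique() < 2 or sub[nf].nunique() < 2:
                rows.append((t, mf, nf, np.nan, np.nan))
                continue
            rho, p = sps.spearmanr(sub[mf], sub[nf])
            rows.append((t, mf, nf, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["threshold", "mito_feature",
                                       "nuclear_feature", "rho", "p_value"])
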