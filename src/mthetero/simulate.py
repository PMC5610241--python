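"""Synthetic tumor/normal mitochondrial cohort generator with known ground truth.

Emulates the structure of a localized prostate-cancer WGS cohort: paired
tumor/normal per-position heteroplasmy profiles with cellularity
contamination, an age-dependent somatic mtSNV burden, age-dependent tumor and
normal mitochondrial copy number, control-region mutational enrichment,
nuclear-feature co-occurrence (MYC gain with OHR mutation) and exponential
biochemical-recurrence times with multiplicative per-feature hazards.

The observed tumor allele fraction at a somatic site is

    AF_obs = cellularity · HF_true + (1 − cellularity) · HF_normal + ε,

the exact inverse of the caller's purity adjustment, so noise-free data
round-trips exactly.  Mitochondrial coverage is tied to the true MCN through
``mito = MCN / 2 × nuclear``, the inverse of the copy-number estimator.

Defaults emulate the printed study conditions: 384 patients of whom 164 are
early-onset (age ≤ 50), mean mitochondrial depth 13,577×, tumor cellularity
above 0.7, tumor MCN rising and normal MCN falling with age, a log-linear
age effect on burden calibrated to the printed zero-burden proportions
(71.3% of EOPC, 38.6% of LOPC), and protective HV1 / adverse OHR hazards.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import HETEROPLASMY_COLUMNS
from .reference import MitoAnnotation, load_annotation

DEFAULT_HOTSPOT_WEIGHTS = {
    # relative probability that a somatic mtSNV falls in each region class;
    # control-region enrichment: ~30% of hits in ~7% of the genome
    "control_region": 0.30,
    "protein_coding": 0.54,
    "rRNA": 0.08,
    "tRNA": 0.08,
}

DEFAULT_HAZARDS = {"HV1": 0.3, "OHR": 2.5, "MYC_gain": 2.0}


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 384
    fraction_eopc: float = 164 / 384
    seed: int = 0
    mean_depth: float = 13577.0
    cellularity_range: tuple[float, float] = (0.7, 1.0)
    #: log-linear model for expected somatic mtSNVs per patient:
    #: E[burden] = exp(intercept + slope × age); calibrated so that the
    #: expected zero-burden fractions match 71.3% (age 47) / 38.6% (age 63.5)
    burden_intercept: float = -4.03
    burden_slope: float = 0.063
    #: linear MCN-vs-age models (copies per cell)
    mcn_tumor_intercept: float = -336.0
    mcn_tumor_slope: float = 13.6
    mcn_normal_intercept: float = 600.0
    mcn_normal_slope: float = -5.2
    mcn_noise_sd: float = 0.15  # lognormal sd on the MCN mean
    hotspot_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HOTSPOT_WEIGHTS))
    noise_sd: float = 0.01  # Gaussian allele-fraction measurement noise
    hazard_by_feature: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARDS))
    baseline_hazard: float = -math.log(0.4) / 120.0  # per month; 60% events by 120 m
    censoring_rate: float = 0.2
    follow_up_months: float = 120.0
    germline_rate: float = 1.5   # mean shared heteroplasmies per patient
    normal_only_rate: float = 0.0  # tissue-specific confounders, off by default
    true_hf_range: tuple[float, float] = (0.05, 1.0)
    nuclear_background: tuple[str, ...] = ("TP53_loss", "PTEN_loss", "NKX3_1_loss")
    nuclear_background_rate: float = 0.15
    myc_base_rate: float = 0.10
    myc_ohr_odds_ratio: float = 4.0
    nuclear_coverage_mean: float = 40.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.fraction_eopc <= 1.0:
            raise ValueError("fraction_eopc must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        lo, hi = self.cellularity_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("cellularity_range must be within (0, 1]")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")
        total = sum(self.hotspot_weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"hotspot_weights must sum to 1 (got {total})")


@dataclass
class SimulatedPatient:
    patient_id: str
    age: float
    cohort: str  # EOPC (age <= 50) or LOPC
    cellularity: float
    true_mcn_tumor: float
    true_mcn_normal: float
    true_somatic_variants: list[tuple[int, str, float]]
    germline_heteroplasmies: list[tuple[int, str, float]]
    normal_only_heteroplasmies: list[tuple[int, str, float]]
    nuclear_features: dict[str, int]
    psa: float
    t_category: str
    gleason: int
    bcr_time: float | None = None
    bcr_event: int | None = None


@dataclass
class SimulatedCohort:
    patients: list[SimulatedPatient]
    tumor_tables: dict[str, pd.DataFrame]
    normal_tables: dict[str, pd.DataFrame]
    coverage: pd.DataFrame   # sample  mito_coverage  nuclear_coverage
    clinical: pd.DataFrame   # patient_id  age  cohort  psa  t_category  gleason
    nuclear: pd.DataFrame    # patient_id + one 0/1 column per nuclear feature
    cellularity: pd.DataFrame  # sample  cellularity
    truth: pd.DataFrame      # patient_id position alt true_hf kind

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "heteroplasmy").mkdir(parents=True, exist_ok=True)
        for pid in self.tumor_tables:
            self.tumor_tables[pid].to_csv(
                outdir / "heteroplasmy" / f"{pid}_T.tsv", sep="\t", index=False)
            self.normal_tables[pid].to_csv(
                outdir / "heteroplasmy" / f"{pid}_N.tsv", sep="\t", index=False)
        self.coverage.to_csv(outdir / "coverage.tsv", sep="\t", index=False)
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
        self.nuclear.to_csv(outdir / "nuclear.tsv", sep="\t", index=False)
        self.cellularity.to_csv(outdir / "cellularity.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _class_positions(annotation: MitoAnnotation) -> dict[str, np.ndarray]:
    """Callable positions per region class used for hotspot sampling."""
    out: dict[str, set[int]] = {k: set() for k in DEFAULT_HOTSPOT_WEIGHTS}
    for region in annotation.regions:
        if region.region_class in ("protein_coding", "rRNA", "tRNA"):
            out[region.region_class].update(region.positions())
        elif region.region_class == "control_region":
            out["control_region"].update(region.positions())
    excl = annotation.excluded_positions
    # coding/rRNA/tRNA positions that also sit in the control region never occur;
    # drop excluded sites everywhere
    return {k: np.array(sorted(v - excl), dtype=int) for k, v in out.items()}


def _draw_variants(rng: np.random.Generator, n: int,
                   class_pos: dict[str, np.ndarray],
                   weights: Mapping[str, float],
                   annotation: MitoAnnotation,
                   hf_lo: float, hf_hi: float,
                   taken: set[int]) -> list[tuple[int, str, float]]:
    classes = list(weights)
    probs = np.array([weights[c] for c in classes])
    out = []
    for _ in range(n):
        for _attempt in range(100):
            cls = classes[rng.choice(len(classes), p=probs)]
            pos = int(rng.choice(class_pos[cls]))
            if pos not in taken:
                break
        else:  # pragma: no cover - pathological saturation
            continue
        taken.add(pos)
        ref = annotation.ref_base(pos)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        hf = float(rng.uniform(hf_lo, hf_hi))
        out.append((pos, str(alt), hf))
    return out


def simulate_cohort(config: SimulationConfig | None = None,
                    annotation: MitoAnnotation | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config = config or SimulationConfig()
    annotation = annotation or load_annotation()
    rng = np.random.default_rng(config.seed)
    class_pos = _class_positions(annotation)

    n = config.n_patients
    n_eopc = int(round(config.fraction_eopc * n))
    ages = np.concatenate([
        rng.integers(42, 51, size=n_eopc),            # early-onset, age <= 50
        rng.integers(51, 77, size=n - n_eopc),        # late-onset
    ]).astype(float)

    patients: list[SimulatedPatient] = []
    tumor_tables: dict[str, pd.DataFrame] = {}
    normal_tables: dict[str, pd.DataFrame] = {}
    cov_rows, truth_rows, nuc_rows = [], [], []

    ohr = annotation.region("OHR")
    for i in range(n):
        pid = f"P{i:04d}"
        age = float(ages[i])
        cohort = "EOPC" if age <= 50 else "LOPC"
        cellularity = float(rng.uniform(*config.cellularity_range))

        mcn_t = (config.mcn_tumor_intercept + config.mcn_tumor_slope * age)
        mcn_n = (config.mcn_normal_intercept + config.mcn_normal_slope * age)
        if config.mcn_noise_sd > 0:
            mcn_t *= math.exp(rng.normal(0.0, config.mcn_noise_sd))
            mcn_n *= math.exp(rng.normal(0.0, config.mcn_noise_sd))
        mcn_t = max(mcn_t, 75.0)
        mcn_n = max(mcn_n, 75.0)

        lam = math.exp(config.burden_intercept + config.burden_slope * age)
        n_somatic = int(rng.poisson(lam))
        n_germline = int(rng.poisson(config.germline_rate))
        n_normal_only = int(rng.poisson(config.normal_only_rate))

        taken: set[int] = set()
        somatic = _draw_variants(rng, n_somatic, class_pos,
                                 config.hotspot_weights, annotation,
                                 *config.true_hf_range, taken)
        germline = _draw_variants(rng, n_germline, class_pos,
                                  config.hotspot_weights, annotation,
                                  0.1, 0.9, taken)
        normal_only = _draw_variants(rng, n_normal_only, class_pos,
                                     config.hotspot_weights, annotation,
                                     0.2, 0.9, taken)

        # nuclear features: MYC gain co-occurs with OHR somatic mutation
        has_ohr = any(p in ohr for p, _, hf in somatic if hf >= 0.2)
        p0 = config.myc_base_rate
        odds = p0 / (1 - p0) * (config.myc_ohr_odds_ratio if has_ohr else 1.0)
        nuclear = {"MYC_gain": int(rng.uniform() < odds / (1 + odds))}
        for name in config.nuclear_background:
            nuclear[name] = int(rng.uniform() < config.nuclear_background_rate)

        # observed allele-fraction tables over the union of involved positions
        rows_t, rows_n = [], []
        for pos, alt, hf in somatic:
            af_n = 0.0
            af_t = cellularity * hf + (1 - cellularity) * af_n
            rows_t.append((pos, alt, af_t))
            rows_n.append((pos, alt, af_n))
        for pos, alt, hf in germline:
            rows_t.append((pos, alt, hf))
            rows_n.append((pos, alt, hf))
        for pos, alt, hf in normal_only:
            rows_t.append((pos, alt, (1 - cellularity) * hf))
            rows_n.append((pos, alt, hf))

        def finish(rows):
            recs = []
            for pos, alt, af in rows:
                if config.noise_sd > 0:
                    af = af + rng.normal(0.0, config.noise_sd)
                af = min(1.0, max(0.0, af))
                depth = int(rng.poisson(config.mean_depth))
                recs.append((pos, annotation.ref_base(pos), alt, af, depth))
            df = pd.DataFrame(recs, columns=HETEROPLASMY_COLUMNS)
            return df.sort_values(["position", "alt"]).reset_index(drop=True)

        tumor_tables[pid] = finish(rows_t)
        normal_tables[pid] = finish(rows_n)

        nuc_cov = float(rng.normal(config.nuclear_coverage_mean,
                                   config.nuclear_coverage_mean / 20))
        nuc_cov = max(nuc_cov, 1.0)
        cov_rows.append((f"{pid}_T", mcn_t / 2 * nuc_cov, nuc_cov))
        cov_rows.append((f"{pid}_N", mcn_n / 2 * nuc_cov, nuc_cov))

        for pos, alt, hf in somatic:
            truth_rows.append((pid, pos, alt, hf, "somatic"))
        for pos, alt, hf in germline:
            truth_rows.append((pid, pos, alt, hf, "germline"))
        for pos, alt, hf in normal_only:
            truth_rows.append((pid, pos, alt, hf, "normal_only"))
        nuc_rows.append({"patient_id": pid, **nuclear})

        patients.append(SimulatedPatient(
            patient_id=pid, age=age, cohort=cohort, cellularity=cellularity,
            true_mcn_tumor=mcn_t, true_mcn_normal=mcn_n,
            true_somatic_variants=somatic, germline_heteroplasmies=germline,
            normal_only_heteroplasmies=normal_only, nuclear_features=nuclear,
            psa=float(rng.lognormal(math.log(8.0), 0.5)),
            t_category=str(rng.choice(["T1", "T2", "T3"], p=[0.2, 0.6, 0.2])),
            gleason=int(rng.choice([6, 7, 8, 9], p=[0.25, 0.55, 0.15, 0.05]))))

    clinical = pd.DataFrame(
        [(p.patient_id, p.age, p.cohort, p.psa, p.t_category, p.gleason)
         for p in patients],
        columns=["patient_id", "age", "cohort", "psa", "t_category", "gleason"])
    coverage = pd.DataFrame(
        cov_rows, columns=["sample", "mito_coverage", "nuclear_coverage"])
    cellularity_df = pd.DataFrame(
        [(p.patient_id, p.cellularity) for p in patients],
        columns=["sample", "cellularity"])
    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "position", "alt", "true_hf", "kind"])
    nuclear_df = pd.DataFrame(nuc_rows)

    cohort = SimulatedCohort(
        patients=patients, tumor_tables=tumor_tables,
        normal_tables=normal_tables, coverage=coverage, clinical=clinical,
        nuclear=nuclear_df, cellularity=cellularity_df, truth=truth)
    simulate_survival(cohort.patients, config.hazard_by_feature,
                      baseline_hazard=config.baseline_hazard,
                      censoring_rate=config.censoring_rate,
                      follow_up_months=config.follow_up_months,
                      annotation=annotation,
                      rng=np.random.default_rng(rng.integers(2**31)))
    return cohort


def true_feature_carriage(patient: SimulatedPatient,
                          annotation: MitoAnnotation,
                          threshold: float = 0.2) -> set[str]:
    """Region + nuclear features the patient truly carries (callable variants)."""
    features: set[str] = set()
    for pos, _alt, hf in patient.true_somatic_variants:
        if hf >= threshold:
            features |= annotation.regions_of(pos)
    features |= {k for k, v in patient.nuclear_features.items() if v}
    return features


def simulate_survival(patients: Sequence[SimulatedPatient],
                      hazard_by_feature: Mapping[str, float] | None = None,
                      baseline_hazard: float = -math.log(0.4) / 120.0,
                      censoring_rate: float = 0.2,
                      follow_up_months: float = 120.0,
                      annotation: MitoAnnotation | None = None,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """Draw exponential BCR times with multiplicative per-feature hazards.

    Mutates ``bcr_time`` / ``bcr_event`` on the patients and returns an
    outcomes table (``patient_id  time  event``).  A patient selected for
    censoring (probability ``censoring_rate``) is censored strictly before
    their event time; everyone else is administratively censored at the end
    of follow-up.
    """
    hazards = DEFAULT_HAZARDS if hazard_by_feature is None else hazard_by_feature
    for name, h in hazards.items():
        if h < 0:
            raise ValueError(f"negative hazard for {name}")
    if rng is None:
        rng = np.random.default_rng(seed)
    annotation = annotation or load_annotation()

    rows = []
    for p in patients:
        carried = true_feature_carriage(p, annotation)
        lam = baseline_hazard
        for name, h in hazards.items():
            if name in carried:
                lam *= h
        t_event = float(rng.exponential(1.0 / lam)) if lam > 0 else math.inf
        if rng.uniform() < censoring_rate:
            horizon = min(t_event, follow_up_months)
            time, event = float(rng.uniform(0, horizon)), 0
        elif t_event <= follow_up_months:
            time, event = t_event, 1
        else:
            time, event = follow_up_months, 0
        time = max(time, 1e-3)  # survival times must be positive
        p.bcr_time, p.bcr_event = time, event
        rows.append((p.patient_id, time, event))
    return pd.DataFrame(rows, columns=["patient_id", "time", "event"])


def outcomes_frame(patients: Sequence[SimulatedPatient]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.patient_id, p.bcr_time, p.bcr_event) for p in patients],
        columns=["patient_id", "time", "event"])
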