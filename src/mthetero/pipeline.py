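"""End-to-end pipeline driver: call → MCN → feature matrix → stats → survival.

The pipeline reads the per-sample heteroplasmy tables, coverage, cellularity,
clinical and nuclear-feature TSVs emitted by the simulator (or produced from
real data upstream), runs every analysis stage with a single configuration,
and writes all result tables plus a machine-readable run manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import calling, copynumber, stats, survival
from .reference import load_annotation

log = logging.getLogger("mthetero")


@dataclass
class PipelineConfig:
    delta_hf_threshold: float = 0.20
    min_depth: int = 100
    excluded_positions: tuple[int, ...] = (310, 523, 524, 3107)
    subregion_features: tuple[str, ...] = ("HV1", "OHR", "CSB1")
    n_permutations: int = 100_000
    permutation_seed: int = 17
    permutation_weighting: str = "uniform"
    selection_p_threshold: float = 0.05
    conflict_rule: str = "high_dominates"
    survival_horizon: float = 120.0
    min_mutated: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.delta_hf_threshold < 1.0:
            raise ValueError("delta_hf_threshold must be in (0, 1)")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if self.conflict_rule not in survival.CONFLICT_RULES:
            raise ValueError(f"unknown conflict rule {self.conflict_rule!r}")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                if isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = cls.__dataclass_fields__
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            f = types[key]
            if f.type.startswith("tuple[int"):
                kwargs[key] = tuple(int(v) for v in value.split(",") if v)
            elif f.type.startswith("tuple"):
                kwargs[key] = tuple(v for v in value.split(",") if v)
            elif f.type == "int":
                kwargs[key] = int(value)
            elif f.type == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list)
            .encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    calls: dict
    mcn: pd.DataFrame
    matrix: pd.DataFrame
    burden_p: float
    associations: pd.DataFrame
    cox_scan: list
    signature: survival.SignatureResult
    manifest: dict


def _find_pairs(het_dir: Path) -> list[str]:
    pids = sorted({p.name[:-6] for p in het_dir.glob("*_T.tsv")})
    missing = [p for p in pids if not (het_dir / f"{p}_N.tsv").exists()]
    if missing:
        raise ValueError(f"paired design is mandatory; missing normals: {missing}")
    return pids


def run_pipeline(indir: str | Path, outdir: str | Path,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on a cohort directory written by the simulator."""
    config = config or PipelineConfig()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "config_hash": config.config_hash,
                      "stages": {}}
    annotation = load_annotation(excluded_positions=config.excluded_positions)

    def stage(name):
        t0 = _time.time()

        def done(**counts):
            manifest["stages"][name] = {"seconds": round(_time.time() - t0, 3),
                                        **counts}
            log.info("stage %s: %s", name, counts)
        return done

    done = stage("call")
    het = indir / "heteroplasmy"
    cellularity = pd.read_csv(indir / "cellularity.tsv", sep="\t")
    cell_map = dict(zip(cellularity["sample"], cellularity["cellularity"]))
    calls = {}
    for pid in _find_pairs(het):
        tumor = calling.read_heteroplasmy_tsv(het / f"{pid}_T.tsv")
        normal = calling.read_heteroplasmy_tsv(het / f"{pid}_N.tsv")
        calls[pid] = calling.call_mtsnvs(
            tumor, normal, cell_map.get(pid, 1.0), annotation,
            delta_hf_threshold=config.delta_hf_threshold,
            min_depth=config.min_depth)
    all_calls = [c for cs in calls.values() for c in cs]
    calls_dir = outdir / "calls"
    calls_dir.mkdir(exist_ok=True)
    for pid, cs in calls.items():
        calling.write_calls_tsv(cs, calls_dir / f"{pid}.tsv")
        calling.write_calls_vcf(cs, calls_dir / f"{pid}.vcf")
    done(patients=len(calls), mtsnvs=len(all_calls))

    done = stage("mcn")
    coverage = copynumber.read_coverage_tsv(indir / "coverage.tsv")
    mcn_df = copynumber.mcn_table(coverage)
    tumor_mcn = {s[:-2]: v for s, v in zip(mcn_df["sample"], mcn_df["mcn"])
                 if s.endswith("_T")}
    mcn_df.to_csv(outdir / "mcn.tsv", sep="\t", index=False)
    done(samples=len(mcn_df))

    done = stage("matrix")
    clinical = pd.read_csv(indir / "clinical.tsv", sep="\t")
    nuclear = pd.read_csv(indir / "nuclear.tsv", sep="\t")
    matrix = stats.build_feature_matrix(
        calls, annotation, nuclear=nuclear, clinical=clinical,
        mcn_by_patient=tumor_mcn, subregions=config.subregion_features)
    matrix.to_csv(outdir / "feature_matrix.tsv", sep="\t")
    done(patients=len(matrix), columns=len(matrix.columns))

    done = stage("stats")
    burdens = matrix["mtSNV_count"].to_numpy(int)
    burden_p = float("nan")
    if burdens.sum() > 0:
        burden_p = stats.zero_burden_permutation_test(
            burdens, n_permutations=config.n_permutations,
            seed=config.permutation_seed,
            weighting=config.permutation_weighting,
            mcn=matrix["MCN"].to_numpy(float)
            if config.permutation_weighting == "mcn" else None)
    mito_feats = [f for f in stats.mito_feature_names(config.subregion_features)]
    nuclear_feats = [c for c in nuclear.columns if c != "patient_id"]
    assoc = stats.association_matrix(matrix, mito_feats, nuclear_feats)
    assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    done(pairs=len(assoc), burden_p=burden_p)

    done = stage("survival")
    outcomes_path = indir / "outcomes.tsv"
    scan, sig = [], None
    if outcomes_path.exists():
        outcomes = pd.read_csv(outcomes_path, sep="\t")
        if outcomes["event"].sum() > 0 and matrix["mtSNV_count"].sum() > 0:
            # scan/signature act on the mitochondrial region features only
            region_feats = [f for f in mito_feats
                            if f not in ("mtSNV_count", "MCN")]
            scan = survival.feature_cox_scan(
                matrix, outcomes, features=region_feats,
                min_mutated=config.min_mutated,
                horizon=config.survival_horizon)
            pd.DataFrame([asdict(r) for r in scan]).to_csv(
                outdir / "cox_scan.tsv", sep="\t", index=False)
            sig = survival.loocv_signature(
                matrix, outcomes, features=region_feats,
                selection_p_threshold=config.selection_p_threshold,
                conflict_rule=config.conflict_rule,
                min_mutated=config.min_mutated)
            sig.classes.to_frame().to_csv(outdir / "signature_classes.tsv",
                                          sep="\t")
    done(scanned=len(scan))

    config.to_file(outdir / "config.txt")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(calls=calls, mcn=mcn_df, matrix=matrix,
                          burden_p=burden_p, associations=assoc,
                          cox_scan=scan, signature=sig, manifest=manifest)
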