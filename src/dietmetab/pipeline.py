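"""End-to-end orchestration: simulate -> zscore -> test -> annotate ->
foldchange -> enrich -> cluster -> status, with one config and one seed.

Every tabular artifact carries a comment header (tool version, master seed,
config hash) and is listed with its SHA-256 in ``manifest.json``; re-running
with the same config and seed reproduces every byte. Benjamini-Hochberg
correction is applied within each reported panel (anthropometrics,
biomarkers, per-ion untargeted tests, enrichment sets) and never pooled
across panels, matching how each family of outcomes is reported together.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import anthro, clustering, enrichment, metabolomics, simulate, stats, status
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate", "zscore", "test", "annotate", "foldchange",
    "enrich", "cluster", "status",
)

#: group pairs tested, primary comparison first
DEFAULT_PAIRS = (("VGN", "OMN"), ("VGTR", "OMN"), ("VGTR", "VGN"))

#: analytes summarized only through their censored fraction (mass at the
#: assay limit would make a probability-index test an artifact of the assay)
CENSOR_ONLY_ANALYTES = ("b12_tc",)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "dietmetab_run"
    stages: tuple = ALL_STAGES
    pairs: tuple = DEFAULT_PAIRS
    n_perm: int = stats.DEFAULT_N_PERM
    enrich_n_perm: int = 999
    k_clusters: int = 4
    n_ions: int = 872
    adjust: bool = True
    scheme: str = "residualize"
    ward_convention: str = "squared_euclidean"
    n_synthetic_compounds: int = 60
    vitamin_a_model: status.VitaminAModel | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")
        for a, b in self.pairs:
            for g in (a, b):
                if g not in simulate.DIET_GROUPS:
                    raise ConfigurationError(f"unknown diet group {g!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model = raw.pop("vitamin_a_model", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if model is not None:
            cfg.vitamin_a_model = status.VitaminAModel(**model)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # where a run lands is not part of its science
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig, sep=",") -> None:
    with open(path, "w") as fh:
        fh.write(f"# dietmetab {__version__}\n")
        fh.write(f"# seed={config.seed}\n")
        fh.write(f"# config_hash={config.hash()}\n")
        df.to_csv(fh, index=False, sep=sep)


def _seed_stream(config: RunConfig) -> "np.random.Generator":
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(99,))
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in dependency order; returns the run dir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config_hash": config.hash(), "stages": [], "artifacts": {}}
    seeds = _seed_stream(config)

    sim_cfg = simulate.default_config(seed=config.seed, n_ions=config.n_ions)
    cohort = simulate.simulate_cohort(sim_cfg)
    cohort = simulate.simulate_biomarkers(cohort, sim_cfg)
    matrix = simulate.simulate_metabolome(cohort, sim_cfg)

    def record(stage: str, name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": path.name, "stage": stage,
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }

    def stage_enabled(stage: str) -> bool:
        return stage in config.stages

    try:
        if stage_enabled("simulate"):
            manifest["stages"].append("simulate")
            _write_table(cohort.participants, outdir / "cohort.csv", config)
            _write_table(cohort.biomarkers, outdir / "biomarkers.csv", config)
            _write_table(
                matrix.intensities.reset_index(), outdir / "matrix.tsv", config, sep="\t"
            )
            # synthetic compound database: [M-H]- identities for the first ions
            n_cmpd = min(config.n_synthetic_compounds, config.n_ions)
            compounds = pd.DataFrame(
                {
                    "id": [f"CMPD{i + 1:04d}" for i in range(n_cmpd)],
                    "monoisotopic_mass": matrix.ions["mz"].to_numpy()[:n_cmpd]
                    + metabolomics.PROTON_MASS,
                }
            )
            _write_table(compounds, outdir / "compounds.csv", config)
            enrichment.write_gmt(
                {name: {"description": "synthetic pathway", "members": m}
                 for name, m in sim_cfg.pathway_spec.items()},
                outdir / "pathways.gmt",
            )
            for name in ("cohort.csv", "biomarkers.csv", "matrix.tsv",
                         "compounds.csv", "pathways.gmt"):
                record("simulate", name, outdir / name)

        zscores = None
        if stage_enabled("zscore"):
            manifest["stages"].append("zscore")
            tables = {m: anthro.synthetic_growth_reference(m)
                      for m in ("height", "bmi", "muac")}
            zscores = anthro.zscore_cohort(cohort, tables)
            _write_table(zscores.reset_index(), outdir / "zscores.csv", config)
            record("zscore", "zscores.csv", outdir / "zscores.csv")

        if stage_enabled("test"):
            manifest["stages"].append("test")
            panels: dict[str, pd.DataFrame] = {}
            if zscores is not None:
                panels["anthropometrics"] = zscores
            bio_wide = cohort.biomarkers.pivot_table(
                index="id", columns="analyte", values="value"
            )
            bio_wide = bio_wide.drop(columns=list(CENSOR_ONLY_ANALYTES), errors="ignore")
            panels["biomarkers"] = bio_wide
            parts = cohort.participants.set_index("id")
            rows = []
            for panel, table in panels.items():
                for a, b in config.pairs:
                    ids = cohort.ids_in_group(a) + cohort.ids_in_group(b)
                    sub = table.loc[[i for i in ids if i in table.index]]
                    pvals, results = [], []
                    for col in sub.columns:
                        res = stats.perm_test(
                            sub[col].to_numpy(dtype=float),
                            parts.loc[sub.index, "diet"].to_numpy(),
                            age=parts.loc[sub.index, "age_years"].to_numpy(),
                            sex=parts.loc[sub.index, "sex"].to_numpy(),
                            n_perm=config.n_perm,
                            seed=int(seeds.integers(2**31)),
                            adjust=config.adjust,
                            scheme=config.scheme,
                        )
                        results.append((col, res))
                        pvals.append(res.p_raw)
                    qvals = stats.bh_adjust(pvals)
                    for (col, res), q in zip(results, qvals):
                        rows.append(
                            {"panel": panel, "outcome": col, "pair": f"{a}-{b}",
                             "PI": res.statistic, "p_raw": res.p_raw, "q": q,
                             "n_perm": res.n_perm, "mode": res.mode,
                             "n1": res.n1, "n2": res.n2, "adjusted": res.adjusted}
                        )
            _write_table(pd.DataFrame(rows), outdir / "tests.csv", config)
            record("test", "tests.csv", outdir / "tests.csv")

        if stage_enabled("annotate"):
            manifest["stages"].append("annotate")
            compounds = metabolomics.load_compounds(outdir / "compounds.csv")
            metabolomics.annotate_peaks(matrix, compounds, tol=0.001)
            metabolomics.write_matrix(
                matrix, outdir / "matrix_annotated.tsv", outdir / "ions.csv"
            )
            record("annotate", "ions.csv", outdir / "ions.csv")

        fc = None
        if stage_enabled("foldchange"):
            manifest["stages"].append("foldchange")
            positive = metabolomics.handle_zeros(matrix)
            fc = metabolomics.log2_fold_changes(positive, cohort, reference="OMN")
            _write_table(fc.reset_index(), outdir / "fold_changes.tsv", config, sep="\t")
            ids_a = cohort.ids_in_group("VGN")
            ids_b = cohort.ids_in_group("OMN")
            log = np.log10(positive.intensities)
            t = enrichment._welch_t_matrix(
                log[ids_a].to_numpy(), log[ids_b].to_numpy()
            )
            # two-sided p from Welch-Satterthwaite df, per ion
            welch = pd.DataFrame(
                [
                    {"ion_id": ion,
                     "t": tv,
                     "p": stats.welch_t(
                         log.loc[ion, ids_a].to_numpy(),
                         log.loc[ion, ids_b].to_numpy())[2]}
                    for ion, tv in zip(positive.ion_ids, t)
                ]
            )
            welch["q"] = stats.bh_adjust(welch["p"].to_numpy())
            _write_table(welch, outdir / "untargeted_welch.csv", config)
            record("foldchange", "fold_changes.tsv", outdir / "fold_changes.tsv")
            record("foldchange", "untargeted_welch.csv", outdir / "untargeted_welch.csv")

        if stage_enabled("enrich"):
            manifest["stages"].append("enrich")
            sets = enrichment.read_gmt(outdir / "pathways.gmt")
            enr = enrichment.pathway_permutation_test(
                matrix, cohort, sets, group_a="VGN", group_b="OMN",
                n_perm=config.enrich_n_perm, seed=int(seeds.integers(2**31)),
            )
            _write_table(enr, outdir / "enrichment.csv", config)
            record("enrich", "enrichment.csv", outdir / "enrichment.csv")

        if stage_enabled("cluster"):
            manifest["stages"].append("cluster")
            standardized = clustering.preprocess_matrix(matrix)
            linkage = clustering.ward_cluster(
                standardized, convention=config.ward_convention
            )
            assign = clustering.cut_clusters(
                linkage, k=config.k_clusters, ids=standardized.index
            )
            by_cluster, by_diet = clustering.cluster_composition(assign, cohort)
            _write_table(
                pd.DataFrame(
                    {"id": list(assign.labels), "cluster": list(assign.labels.values())}
                ),
                outdir / "clusters.csv", config,
            )
            _write_table(by_cluster, outdir / "cluster_composition.csv", config)
            _write_table(by_diet, outdir / "cluster_by_diet.csv", config)
            (outdir / "dendrogram.nwk").write_text(
                clustering.to_newick(linkage, list(standardized.index)) + "\n"
            )
            for name in ("clusters.csv", "cluster_composition.csv",
                         "cluster_by_diet.csv", "dendrogram.nwk"):
                record("cluster", name, outdir / name)

        if stage_enabled("status"):
            manifest["stages"].append("status")
            calls = status.classify_cohort(cohort, config.vitamin_a_model)
            _write_table(calls, outdir / "status_calls.csv", config)
            cens_rows = []
            for analyte in CENSOR_ONLY_ANALYTES:
                sub = cohort.biomarkers[cohort.biomarkers["analyte"] == analyte]
                if sub.empty:
                    continue
                limit = float(sub.loc[sub["censored"], "value"].max()) if sub["censored"].any() else float("inf")
                for g in cohort.groups:
                    ids = cohort.ids_in_group(g)
                    grp = sub[sub["id"].isin(ids)]
                    frac = status.censored_fraction(
                        grp["value"].to_numpy(), grp["censored"].to_numpy(), limit
                    )
                    cens_rows.append(
                        {"analyte": analyte, "diet": g, "n": len(grp),
                         "n_censored": int(grp["censored"].sum()),
                         "censored_fraction": frac, "limit": limit}
                    )
            _write_table(pd.DataFrame(cens_rows), outdir / "censoring.csv", config)
            record("status", "status_calls.csv", outdir / "status_calls.csv")
            record("status", "censoring.csv", outdir / "censoring.csv")
    except Exception as exc:
        logger.error("pipeline halted in stage processing: %s", exc)
        raise

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return outdir


def summarize_run(run_dir) -> pd.DataFrame:
    """Join test results with Table-1 style group summaries and status counts."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise InputError(f"no manifest.json in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    if "tests.csv" not in manifest["artifacts"]:
        return pd.DataFrame(columns=["panel", "outcome", "pair", "PI", "p_raw", "q"])
    tests = pd.read_csv(run_dir / "tests.csv", comment="#")
    cohort = simulate.read_cohort(run_dir / "cohort.csv", run_dir / "biomarkers.csv")
    zpath = run_dir / "zscores.csv"
    zscores = pd.read_csv(zpath, comment="#").set_index("id") if zpath.exists() else None

    def describe(values) -> str:
        v = np.asarray(values, dtype=float)
        return f"{np.median(v):.3g} [{v.min():.3g} to {v.max():.3g}]"

    summary_cols = {}
    for g in cohort.groups:
        ids = set(cohort.ids_in_group(g))
        col = []
        for row in tests.itertuples():
            if zscores is not None and row.outcome in zscores.columns:
                vals = zscores.loc[[i for i in zscores.index if i in ids], row.outcome]
            else:
                sub = cohort.biomarkers
                vals = sub[(sub["analyte"] == row.outcome) & sub["id"].isin(ids)]["value"]
            col.append(describe(vals) if len(vals) else "")
        summary_cols[g] = col
    out = tests[["panel", "outcome", "pair", "PI", "p_raw", "q"]].copy()
    for g, col in summary_cols.items():
        out[g] = col

    calls_path = run_dir / "status_calls.csv"
    if calls_path.exists():
        calls = pd.read_csv(calls_path, comment="#")
        diet = cohort.participants.set_index("id")["diet"]
        calls["diet"] = calls["participant"].map(diet)
        counts = (
            calls.groupby(["analyte", "diet"])["status"]
            .apply(lambda s: ";".join(f"{k}:{v}" for k, v in s.value_counts().items()))
            .rename("status_counts")
            .reset_index()
        )
        status_map = {
            (r.analyte, r.diet): r.status_counts for r in counts.itertuples()
        }
        out["status_counts"] = [
            " | ".join(
                f"{g}={status_map[(row.outcome, g)]}"
                for g in cohort.groups
                if (row.outcome, g) in status_map
            )
            for row in out.itertuples()
        ]
    return out
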