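"""Synthetic cohort, biomarker, and metabolome generator.

The study design being emulated: three diet groups of preschool children —
24 omnivores (OMN), 10 vegetarians (VGTR), 6 vegans (VGN) — ages roughly
1.4-7.1 years, balanced sex. Ion intensities are log-normal with
exchangeable within-pathway correlation and additive group shifts on the
log2 scale; the vegetarian shift is the vegan shift times an attenuation
factor (default 0.5), reflecting the intermediate vegetarian phenotype.
Biomarkers are Gaussian (or log-normal) per group with optional right
censoring at an assay detection limit: censored draws are stored AT the
limit with a flag so downstream censoring logic is exercised, never
dropped. One master seed is split into named substreams (cohort /
metabolome / biomarkers), so adding a stage never perturbs earlier draws.

The default parameterization is fixed: it is the study condition every
downstream test assumes, not a tuning knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import anthro
from .errors import ConfigurationError, InputError
from .metabolomics import PROTON_MASS, MetaboliteMatrix, write_matrix

DIET_GROUPS = ("OMN", "VGTR", "VGN")

_SUBSTREAMS = {"cohort": 0, "metabolome": 1, "biomarkers": 2}


@dataclass(frozen=True)
class BiomarkerSpec:
    """Group-level distribution of one analyte."""

    unit: str
    means: dict  # diet group -> mean (normal) or log-mean (lognormal)
    sds: dict  # diet group -> SD on the same scale
    dist: str = "normal"
    censor_limit: float = math.inf

    def validate(self, name: str) -> None:
        if self.dist not in ("normal", "lognormal"):
            raise ConfigurationError(f"biomarker {name}: unknown dist {self.dist!r}")
        for g in DIET_GROUPS:
            if g not in self.means or g not in self.sds:
                raise ConfigurationError(f"biomarker {name}: missing group {g}")
            if self.sds[g] < 0:
                raise ConfigurationError(f"biomarker {name}: negative SD for {g}")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic study."""

    group_sizes: tuple = (24, 10, 6)  # OMN, VGTR, VGN
    age_range: tuple = (1.42, 7.07)  # years
    sex_balance: float = 0.5  # P(female)
    n_ions: int = 872
    pathway_spec: dict = field(default_factory=dict)  # name -> member ion ids
    effect_table: dict = field(default_factory=dict)  # name -> (vegan log2 shift, attenuation)
    block_correlation: float = 0.3
    age_slope: float = 0.0  # log10 intensity units per year
    biomarker_spec: dict = field(default_factory=dict)  # analyte -> BiomarkerSpec
    log10_sd: float = 0.25  # residual SD of log10 intensities
    baseline_range: tuple = (3.0, 6.0)  # log10 baseline abundance span
    seed: int = 0

    def validate(self) -> None:
        if len(self.group_sizes) != 3 or any(g < 1 for g in self.group_sizes):
            raise ConfigurationError("group_sizes: three integers >= 1 required")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigurationError("age_range: min must be < max")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ConfigurationError("sex_balance: must lie in [0, 1]")
        if self.n_ions < 1:
            raise ConfigurationError("n_ions: must be >= 1")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ConfigurationError("block_correlation: must lie in [0, 1)")
        for name, (shift, atten) in self.effect_table.items():
            if name not in self.pathway_spec:
                raise ConfigurationError(
                    f"effect_table: pathway {name!r} not in pathway_spec"
                )
            if not 0.0 <= atten <= 1.0:
                raise ConfigurationError(
                    f"effect_table: attenuation for {name!r} outside [0, 1]"
                )
        for name, spec in self.biomarker_spec.items():
            spec.validate(name)


@dataclass
class Cohort:
    """Participants plus their (possibly empty) biomarker records."""

    participants: pd.DataFrame  # id, diet, age_years, sex, height_cm, weight_kg, muac_cm
    biomarkers: pd.DataFrame  # id, analyte, value, unit, censored

    def __post_init__(self) -> None:
        if self.participants["id"].duplicated().any():
            raise InputError("participant ids must be unique")

    @property
    def groups(self) -> list[str]:
        seen = dict.fromkeys(self.participants["diet"])
        return list(seen)

    def ids_in_group(self, group: str) -> list[str]:
        sel = self.participants["diet"] == group
        return self.participants.loc[sel, "id"].tolist()

    def biomarker_values(self, analyte: str, include_censored: bool = True):
        sub = self.biomarkers[self.biomarkers["analyte"] == analyte]
        if not include_censored:
            sub = sub[~sub["censored"]]
        return sub.set_index("id")[["value", "censored"]]

    @property
    def n(self) -> int:
        return len(self.participants)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_SUBSTREAMS[stream],))
    return np.random.default_rng(ss)


def default_pathways(n_ions: int, n_pathways: int = 8, size: int = 20) -> dict:
    """Disjoint ion blocks standing in for metabolic pathways.

    With few ions the block size shrinks (minimum 3) so small test matrices
    still carry the full pathway structure.
    """
    size = min(size, max(3, n_ions // n_pathways))
    if n_pathways * size > n_ions:
        n_pathways = max(1, n_ions // size)
    if n_pathways * size > n_ions:
        raise ConfigurationError("not enough ions for the requested pathways")
    names = [
        "bile_acid_synthesis", "essential_amino_acids", "lcfa_vlcfa",
        "folate_metabolism", "mcfa", "tca_cycle", "purine_metabolism",
        "sphingolipids",
    ][:n_pathways]
    ids = [f"ion_{i + 1:04d}" for i in range(n_ions)]
    return {
        name: ids[k * size : (k + 1) * size] for k, name in enumerate(names)
    }


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The canonical synthetic study.

    Planted vegan effects (log2, attenuation 0.5 for vegetarians) mirror the
    qualitative direction of the reported group differences: bile-acid
    synthesis most perturbed, essential amino acids and long-chain fatty
    acids lower in vegans, folate and medium-chain species higher; three
    pathways are left null.
    """
    n_ions = overrides.pop("n_ions", 872)
    pathways = default_pathways(n_ions)
    effects = {
        name: eff
        for name, eff in {
            "bile_acid_synthesis": (1.2, 0.5),
            "essential_amino_acids": (-0.7, 0.5),
            "lcfa_vlcfa": (-0.5, 0.5),
            "folate_metabolism": (0.8, 0.5),
            "mcfa": (0.6, 0.5),
        }.items()
        if name in pathways
    }
    biomarkers = {
        "rbp": BiomarkerSpec("umol/l", {"OMN": 1.45, "VGTR": 1.30, "VGN": 0.95},
                             {"OMN": 0.18, "VGTR": 0.15, "VGN": 0.06}),
        "transthyretin": BiomarkerSpec("g/l", {"OMN": 0.22, "VGTR": 0.21, "VGN": 0.18},
                                       {"OMN": 0.03, "VGTR": 0.03, "VGN": 0.025}),
        "crp": BiomarkerSpec("mg/l", {g: math.log(0.4) for g in DIET_GROUPS},
                             {g: 0.8 for g in DIET_GROUPS}, dist="lognormal"),
        "b12_tc": BiomarkerSpec("pmol/l", {"OMN": 110.0, "VGTR": 120.0, "VGN": 140.0},
                                {g: 25.0 for g in DIET_GROUPS}, censor_limit=128.0),
        "vitd_25oh": BiomarkerSpec("nmol/l", {"OMN": 80.0, "VGTR": 72.0, "VGN": 60.0},
                                   {"OMN": 12.0, "VGTR": 10.0, "VGN": 3.5}),
        "folate_rbc": BiomarkerSpec("nmol/l", {"OMN": 650.0, "VGTR": 800.0, "VGN": 1050.0},
                                    {"OMN": 140.0, "VGTR": 160.0, "VGN": 120.0}),
        "zinc": BiomarkerSpec("umol/l", {g: 13.0 for g in DIET_GROUPS},
                              {g: 1.5 for g in DIET_GROUPS}),
    }
    config = SimConfig(
        n_ions=n_ions,
        pathway_spec=pathways,
        effect_table=effects,
        biomarker_spec=biomarkers,
        seed=seed,
        **overrides,
    )
    config.validate()
    return config


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw participants: diet blocks, uniform ages, Bernoulli sex.

    Anthropometrics come from the synthetic growth reference: each child
    draws independent N(0,1) height/BMI/MUAC z-scores which are inverted
    through the LMS curves at the child's age; weight is reconstructed from
    BMI and height.
    """
    config.validate()
    rng = _rng(config, "cohort")
    diets = np.repeat(DIET_GROUPS, config.group_sizes)
    n = diets.size
    ids = [f"P{i + 1:03d}" for i in range(n)]
    ages = rng.uniform(*config.age_range, size=n)
    sexes = np.where(rng.random(n) < config.sex_balance, "F", "M")

    href = anthro.synthetic_growth_reference("height")
    bref = anthro.synthetic_growth_reference("bmi")
    mref = anthro.synthetic_growth_reference("muac")
    z = rng.standard_normal((n, 3))
    heights, weights, muacs = [], [], []
    for i in range(n):
        h = anthro.lms_inverse(z[i, 0], *anthro.interpolate_lms(href, sexes[i], ages[i]))
        bmi = anthro.lms_inverse(z[i, 1], *anthro.interpolate_lms(bref, sexes[i], ages[i]))
        m = anthro.lms_inverse(z[i, 2], *anthro.interpolate_lms(mref, sexes[i], ages[i]))
        heights.append(h)
        weights.append(bmi * (h / 100.0) ** 2)
        muacs.append(m)

    parts = pd.DataFrame(
        {"id": ids, "diet": diets, "age_years": ages, "sex": sexes,
         "height_cm": heights, "weight_kg": weights, "muac_cm": muacs}
    )
    empty = pd.DataFrame(columns=["id", "analyte", "value", "unit", "censored"])
    return Cohort(parts, empty)


def simulate_metabolome(cohort: Cohort, config: SimConfig) -> MetaboliteMatrix:
    """Log-normal intensities with pathway-block correlation and diet shifts.

    log10 intensity of ion i in child j:
        baseline_i + sd * (sqrt(rho) u_pathway(i),j + sqrt(1-rho) e_ij)
                   + shift_i(diet_j) * log10(2) + age_slope * age_j
    where u is shared within a pathway block (exchangeable correlation rho)
    and shift is the planted vegan log2 effect, attenuated for vegetarians.
    """
    config.validate()
    if cohort.n == 0:
        raise InputError("cohort is empty")
    rng = _rng(config, "metabolome")
    n_ions, n = config.n_ions, cohort.n
    ids = [f"ion_{i + 1:04d}" for i in range(n_ions)]

    baseline = rng.uniform(*config.baseline_range, size=n_ions)
    mz = np.sort(rng.uniform(70.0, 1000.0, size=n_ions))

    shift_vgn = np.zeros(n_ions)
    atten = np.full(n_ions, 0.5)
    block = np.full(n_ions, -1)
    index = {ion: i for i, ion in enumerate(ids)}
    for b, (name, members) in enumerate(config.pathway_spec.items()):
        for ion in members:
            if ion not in index:
                raise ConfigurationError(f"pathway {name!r}: unknown ion {ion!r}")
            block[index[ion]] = b
        if name in config.effect_table:
            shift, a = config.effect_table[name]
            for ion in members:
                shift_vgn[index[ion]] = shift
                atten[index[ion]] = a

    rho = config.block_correlation
    eps = rng.standard_normal((n_ions, n))
    z = math.sqrt(1.0 - rho) * eps
    n_blocks = int(block.max()) + 1 if block.max() >= 0 else 0
    if n_blocks and rho > 0:
        shared = rng.standard_normal((n_blocks, n))
        in_block = block >= 0
        z[in_block] += math.sqrt(rho) * shared[block[in_block]]

    diet = cohort.participants["diet"].to_numpy()
    # vegans get the full planted shift, vegetarians the attenuated one
    per_cell_shift = np.outer(shift_vgn, (diet == "VGN").astype(float)) + np.outer(
        shift_vgn * atten, (diet == "VGTR").astype(float)
    )
    log10_int = (
        baseline[:, None]
        + config.log10_sd * z
        + per_cell_shift * math.log10(2.0)
        + config.age_slope * cohort.participants["age_years"].to_numpy()[None, :]
    )
    inten = pd.DataFrame(
        np.power(10.0, log10_int), index=pd.Index(ids, name="ion_id"),
        columns=cohort.participants["id"].tolist(),
    )
    ions = pd.DataFrame({"ion_id": ids, "mz": mz})
    return MetaboliteMatrix(ions, inten)


def simulate_biomarkers(cohort: Cohort, config: SimConfig) -> Cohort:
    """Fill the cohort's biomarker table from the per-analyte group specs."""
    config.validate()
    if not config.biomarker_spec:
        raise ConfigurationError("biomarker_spec is empty")
    rng = _rng(config, "biomarkers")
    rows = []
    for analyte in sorted(config.biomarker_spec):
        spec = config.biomarker_spec[analyte]
        for row in cohort.participants.itertuples():
            mu, sd = spec.means[row.diet], spec.sds[row.diet]
            draw = rng.normal(mu, sd)
            value = math.exp(draw) if spec.dist == "lognormal" else max(draw, 0.0)
            censored = value > spec.censor_limit
            if censored:
                value = spec.censor_limit
            rows.append(
                {"id": row.id, "analyte": analyte, "value": value,
                 "unit": spec.unit, "censored": censored}
            )
    bio = pd.DataFrame(rows, columns=["id", "analyte", "value", "unit", "censored"])
    return Cohort(cohort.participants.copy(), bio)


def attach_compound_mzs(matrix: MetaboliteMatrix, masses) -> None:
    """Overwrite the first ions' m/z with [M-H]- values of given neutral masses."""
    masses = list(masses)
    if len(masses) > len(matrix.ions):
        raise InputError("more masses than ions")
    mz = matrix.ions["mz"].to_numpy(dtype=float).copy()
    mz[: len(masses)] = [m - PROTON_MASS for m in masses]
    matrix.ions["mz"] = mz


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(cohort: Cohort, matrix: MetaboliteMatrix | None, outdir) -> dict:
    """Emit cohort/biomarker CSVs and matrix/ion tables; returns the paths.

    Formats round-trip losslessly through :func:`read_cohort` /
    :func:`dietmetab.metabolomics.read_matrix` (full float precision kept).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": outdir / "cohort.csv",
        "biomarkers": outdir / "biomarkers.csv",
    }
    cohort.participants.to_csv(paths["cohort"], index=False)
    cohort.biomarkers.to_csv(paths["biomarkers"], index=False)
    if matrix is not None:
        paths["matrix"] = outdir / "matrix.tsv"
        paths["ions"] = outdir / "ions.csv"
        write_matrix(matrix, paths["matrix"], paths["ions"])
    return paths


def read_cohort(cohort_path, biomarkers_path=None) -> Cohort:
    parts = pd.read_csv(cohort_path, comment="#", float_precision="round_trip")
    if biomarkers_path is not None:
        bio = pd.read_csv(
            biomarkers_path, comment="#", float_precision="round_trip"
        )
        if bio.empty:
            bio = pd.DataFrame(columns=["id", "analyte", "value", "unit", "censored"])
        else:
            bio["censored"] = bio["censored"].astype(bool)
    else:
        bio = pd.DataFrame(columns=["id", "analyte", "value", "unit", "censored"])
    return Cohort(parts, bio)
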