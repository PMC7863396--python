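"""Untargeted flow-injection TOF-MS data handling.

Flow-injection TOF-MS yields one accurate m/z per ion and semi-quantitative
intensities per participant, with no chromatographic separation. Annotation
is therefore putative: every compound whose [M-H]- m/z lies within an
absolute tolerance (default 0.001 Th) of an observed ion is retained,
isomers included, optionally supported by the presence of a correlated
+1.003355 Th isotopologue partner. Downstream analyses work on log2 fold
changes of each individual against the omnivore group mean.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, InputError
from .stats import bh_adjust, welch_t

#: monoisotopic masses (Da) of the most abundant isotope; extensible
ELEMENT_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.9637064864,
    "Cl": 34.968852682,
}

PROTON_MASS = 1.007276  # Da

#: 13C - 12C monoisotopic mass difference (Da)
C13_SPACING = 1.003355

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class MetaboliteMatrix:
    """Ion x participant intensity matrix with m/z metadata.

    ``intensities`` is indexed by ion id with one column per participant id;
    ``ions`` carries ion_id and mz; ``annotations`` maps ion id to candidate
    (compound_id, mz_delta) pairs sorted by |delta| (isomer ambiguity is kept,
    not resolved).
    """

    ions: pd.DataFrame  # columns: ion_id, mz
    intensities: pd.DataFrame  # index ion_id, columns participant ids
    annotations: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.ions["ion_id"]) != list(self.intensities.index):
            raise InputError("ion table and intensity matrix rows disagree")
        if (self.ions["mz"] <= 0).any():
            raise InputError("all m/z values must be positive")

    @property
    def participants(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def ion_ids(self) -> list[str]:
        return list(self.intensities.index)

    def mz_of(self, ion_id: str) -> float:
        row = self.ions.loc[self.ions["ion_id"] == ion_id, "mz"]
        if row.empty:
            raise InputError(f"unknown ion {ion_id!r}")
        return float(row.iloc[0])


@dataclass(frozen=True)
class CompoundRecord:
    """One entry of the user-supplied compound mass database."""

    compound_id: str
    monoisotopic_mass: float
    formula: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise InputError(f"compound {self.compound_id}: mass must be > 0")
        if self.formula:
            calc = neutral_mass(self.formula)
            if abs(calc - self.monoisotopic_mass) > 1e-4:
                raise InputError(
                    f"compound {self.compound_id}: formula {self.formula} gives "
                    f"{calc:.5f} Da, stated mass {self.monoisotopic_mass:.5f}"
                )


def neutral_mass(formula: str) -> float:
    """Monoisotopic neutral mass (Da) from an elemental formula."""
    if not formula or not formula.strip():
        raise FormatError("empty elemental formula")
    formula = formula.strip()
    pos, total = 0, 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormatError(f"cannot parse formula {formula!r} at {pos}")
        pos = match.end()
        element, count = match.group(1), int(match.group(2) or 1)
        if element not in ELEMENT_MASS:
            raise FormatError(f"unknown element {element!r} in {formula!r}")
        total += ELEMENT_MASS[element] * count
    if pos != len(formula):
        raise FormatError(f"cannot parse formula {formula!r} at {pos}")
    return total


def mz_from_formula(formula: str, mode: str = "negative") -> float:
    """m/z of the deprotonated [M-H]- ion (the acquisition mode modelled)."""
    if mode != "negative":
        raise InputError(f"unsupported ionization mode {mode!r}")
    return neutral_mass(formula) - PROTON_MASS


def load_compounds(path) -> list[CompoundRecord]:
    """Read a compound database CSV: id, formula and/or monoisotopic mass."""
    df = pd.read_csv(path, comment="#")
    records = []
    for row in df.itertuples():
        formula = getattr(row, "formula", None)
        formula = None if (formula is None or pd.isna(formula)) else str(formula)
        mass = getattr(row, "monoisotopic_mass", None)
        if mass is None or pd.isna(mass):
            if formula is None:
                raise InputError(f"compound {row.id}: no formula and no mass")
            mass = neutral_mass(formula)
        records.append(
            CompoundRecord(str(row.id), float(mass), formula, getattr(row, "name_", ""))
        )
    return records


def annotate_peaks(
    matrix: MetaboliteMatrix,
    compounds: list[CompoundRecord],
    tol: float = 0.001,
    mode: str = "negative",
) -> dict[str, list[tuple[str, float]]]:
    """Assign every compound within |Δm/z| <= tol to each ion.

    All matches are kept — isomers share a theoretical mass and are not
    distinguishable by accurate mass alone. Candidate lists are sorted by
    |Δm/z| (ties by compound id). The result is also stored on the matrix.
    """
    if tol <= 0:
        raise InputError("tol must be > 0")
    theo = np.array([c.monoisotopic_mass - PROTON_MASS for c in compounds])
    ids = np.array([c.compound_id for c in compounds])
    order = np.argsort(theo, kind="stable")
    theo, ids = theo[order], ids[order]
    annotations: dict[str, list[tuple[str, float]]] = {}
    obs = matrix.ions["mz"].to_numpy(dtype=float)
    # 1e-9 Th slack absorbs float rounding at the tolerance boundary, far
    # below any real mass accuracy
    eps = 1e-9
    lo = np.searchsorted(theo, obs - tol - eps, side="left")
    hi = np.searchsorted(theo, obs + tol + eps, side="right")
    for ion_id, mz, a, b in zip(matrix.ions["ion_id"], obs, lo, hi):
        cand = [
            (str(cid), float(mz - t))
            for cid, t in zip(ids[a:b], theo[a:b])
            if abs(mz - t) <= tol + eps
        ]
        cand.sort(key=lambda item: (abs(item[1]), item[0]))
        if cand:
            annotations[str(ion_id)] = cand
    matrix.annotations = annotations
    return annotations


def isotope_correlation_support(
    matrix: MetaboliteMatrix,
    ion_id: str,
    delta: float = C13_SPACING,
    tol: float = 0.001,
    r_min: float = 0.7,
) -> bool:
    """True iff a +delta partner ion exists whose intensities correlate.

    Heavier isotopologues of the same compound co-vary across samples, so a
    peak at m/z + 1.003355 with Pearson r >= r_min supports the annotation.
    """
    if len(matrix.participants) < 3:
        raise InputError("isotope support requires >= 3 participants")
    target = matrix.mz_of(ion_id) + delta
    base = matrix.intensities.loc[ion_id].to_numpy(dtype=float)
    for other in matrix.ions.itertuples():
        if other.ion_id == ion_id or abs(other.mz - target) > tol:
            continue
        partner = matrix.intensities.loc[other.ion_id].to_numpy(dtype=float)
        if np.std(base) == 0 or np.std(partner) == 0:
            continue
        if np.corrcoef(base, partner)[0, 1] >= r_min:
            return True
    return False


def handle_zeros(matrix: MetaboliteMatrix, strategy: str = "half_min") -> MetaboliteMatrix:
    """Replace zeros/missing by half the ion's smallest positive intensity."""
    if strategy != "half_min":
        raise InputError(f"unknown zero-handling strategy {strategy!r}")
    values = matrix.intensities.to_numpy(dtype=float).copy()
    bad = ~(values > 0)
    if bad.any():
        for i in np.flatnonzero(bad.any(axis=1)):
            positive = values[i][values[i] > 0]
            if positive.size == 0:
                raise DataError(
                    f"ion {matrix.intensities.index[i]!r} has no positive intensity"
                )
            values[i][bad[i]] = positive.min() / 2.0
    filled = pd.DataFrame(
        values, index=matrix.intensities.index, columns=matrix.intensities.columns
    )
    return MetaboliteMatrix(matrix.ions.copy(), filled, dict(matrix.annotations))


def log2_fold_changes(
    matrix: MetaboliteMatrix, cohort, reference: str = "OMN"
) -> pd.DataFrame:
    """Per-ion, per-individual log2 fold change against the reference mean.

    The zero level is the arithmetic mean intensity of the reference diet
    group for that ion, so a participant at exactly the omnivore mean maps
    to 0 and one at twice the mean to +1.
    """
    ref_ids = cohort.ids_in_group(reference)
    if not ref_ids:
        raise InputError(f"reference group {reference!r} is empty")
    inten = matrix.intensities
    if (inten.to_numpy() <= 0).any():
        raise DataError("nonpositive intensities; run handle_zeros first")
    ref_mean = inten[ref_ids].mean(axis=1)
    return np.log2(inten.div(ref_mean, axis=0))


def pooled_class_comparison(
    fc_table: pd.DataFrame,
    ion_groups: dict[str, list[str]],
    cohort,
    pairs: tuple[tuple[str, str], ...] = (("VGN", "OMN"), ("VGTR", "OMN")),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box-plot summaries of pooled metabolite classes plus per-member tests.

    Member-ion fold changes are pooled within each diet group (a class of 3
    ions over 24 omnivores pools to n = 72), described by median, quartiles,
    and range. No single test is run on the pooled values — they are
    dependent across members — instead each member ion gets its own Welch
    test per group pair with Benjamini-Hochberg correction across members.
    """
    box_rows, test_rows = [], []
    for cls, members in ion_groups.items():
        if not members:
            raise InputError(f"class {cls!r} has no member ions")
        missing = [m for m in members if m not in fc_table.index]
        if missing:
            raise InputError(f"class {cls!r} references unknown ions {missing}")
        for group in cohort.groups:
            ids = cohort.ids_in_group(group)
            pooled = fc_table.loc[members, ids].to_numpy().ravel()
            q1, med, q3 = np.percentile(pooled, [25, 50, 75])
            box_rows.append(
                {
                    "class": cls,
                    "diet": group,
                    "n": pooled.size,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "min": pooled.min(),
                    "max": pooled.max(),
                }
            )
        for a, b in pairs:
            ids_a, ids_b = cohort.ids_in_group(a), cohort.ids_in_group(b)
            pvals, stats_ = [], []
            for m in members:
                t, _, p = welch_t(
                    fc_table.loc[m, ids_a].to_numpy(),
                    fc_table.loc[m, ids_b].to_numpy(),
                )
                stats_.append(t)
                pvals.append(p)
            qvals = bh_adjust(pvals)
            for m, t, p, q in zip(members, stats_, pvals, qvals):
                test_rows.append(
                    {"class": cls, "ion_id": m, "pair": f"{a}-{b}",
                     "t": t, "p": p, "q": q}
                )
    return pd.DataFrame(box_rows), pd.DataFrame(test_rows)


def read_matrix(matrix_path, ions_path) -> MetaboliteMatrix:
    """Load intensity TSV (first column ion_id) and ion table CSV."""
    inten = pd.read_csv(
        matrix_path, sep="\t", comment="#", float_precision="round_trip"
    ).set_index("ion_id")
    ions = pd.read_csv(ions_path, comment="#", float_precision="round_trip")
    return MetaboliteMatrix(ions[["ion_id", "mz"]], inten)


def write_matrix(matrix: MetaboliteMatrix, matrix_path, ions_path) -> None:
    matrix.intensities.reset_index().rename(
        columns={"index": "ion_id"}
    ).to_csv(matrix_path, sep="\t", index=False)
    ions = matrix.ions.copy()
    ions["annotation"] = [
        ";".join(c for c, _ in matrix.annotations.get(i, []))
        for i in ions["ion_id"]
    ]
    ions.to_csv(ions_path, index=False)
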